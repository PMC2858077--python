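# bicoid2d

A 2-D reaction–diffusion simulator of Bicoid (Bcd) morphogen gradient
formation in the early *Drosophila* embryo, together with the analysis
battery used to judge whether a simulated gradient behaves like the real
one.

Bicoid is the maternal transcription factor that patterns the
anterior–posterior (A–P) axis of the fly embryo. Its protein gradient
forms by localized production from maternally deposited *bcd* mRNA,
embryo-wide diffusion, and degradation (the synthesis–diffusion–
degradation picture), shaped by the changing diffusion medium of the
syncytial blastoderm: from nuclear cycle 10 the nuclei occupy a thin
cortical shell, and Bcd binding to the vast excess of non-specific,
low-affinity DNA sites inside those nuclei retards its effective
diffusion and traps it in the cortex. This package is for quantitative
developmental biologists and modellers who want to simulate that system,
explore its parameter space, and reproduce its characteristic statistics.

## Model

The simulated domain is the mid-coronal slice of the embryo: an ellipse
with major axis *L* (A–P length, 550 µm by default) and aspect ratio 1/3,
meshed into uniform cubes of edge Δx (5 µm). The state variable is the
total Bcd concentration B(x, y, t) per cube. Free and DNA-bound Bcd are
in local equilibrium with bound/free ratio

    K_A · S(c),

where K_A is the association constant for non-specific DNA binding and
S(c) the site concentration in the cortical layer at nuclear cycle c
(S doubles at every division as the nuclei double). Only free molecules
diffuse, so the total pool moves with the effective constant

    D_eff = D / (1 + K_A · S),

and the governing equation is

    ∂B/∂t = ∇·( D ∇(φ B) ) + k(x) J/υ − ω B,      φ = 1/(1 + K_A·S(x,c)),

integrated by forward Euler (Δt = 0.2 s) on a five-point stencil with
no-flux boundaries. φ = 1 in the nucleus-free inner region (yolk) and
before cycle 10. Production is confined to mRNA-containing cubes: a
uniform disc (radius 45 µm, centered 75 µm from the anterior pole) by
default; a single anterior-tip cube or a cortical mRNA gradient
(emulating the reported *bcd* mRNA redistribution) as variants.

Three criteria quantify a simulated gradient:

* **stability** g — mean relative change of the nuclear concentration
  profile B_n ∝ B_bound/nuclei between successive cycles 10–14
  (stable if |g| < 0.1);
* **cortical enrichment** — Ratio of total Bcd in the cortical layer to
  the inner region at cycle 14 (enriched if > 1.5);
* **shape** — length constant λ of the exponential fit A·e^(−x/λ)
  (properly shaped if 0.15 ≤ λ/L ≤ 0.2).

## Worked example

```python
import json
import bicoid2d as b

snaps = b.run(b.preset("main"))          # wild-type embryo to 154 min
report = b.evaluate_criteria(snaps)
print(json.dumps(report.to_dict(), indent=2))
```

prints

```json
{
  "g": 0.07575792776038826,
  "ratio": 2.255425071985944,
  "lambda_um": 94.89112017875571,
  "lambda_over_L": 0.17252930941591949,
  "adj_r2": 0.9996171388230067,
  "adj_r2_full": 0.9027458468621041,
  "pass_g": true,
  "pass_ratio": true,
  "pass_lambda": true,
  "passes_all": true
}
```

Reading: nuclear Bcd concentrations change by ~7.6% per cycle on average
(stable), the cortical layer holds 2.26× more Bcd than the yolk at cycle
14 (enriched), and the cortical bound-Bcd profile is exponential with
λ ≈ 95 µm, i.e. λ/L ≈ 0.17 (properly shaped). The two Adjusted R² values
are the exponential fit quality on x/L 0.2–0.7 and 0–0.7; the drop in
the second reflects the anterior "deviation" produced by the extended
mRNA disc — a point source shows no such deviation.

The same run from the shell:

```
bicoid2d preset-list
bicoid2d simulate --preset main --out out/main
bicoid2d analyze  --run-dir out/main
bicoid2d sweep    --preset main --ka-values 1e4,5e5,1e7 --out out/ka.csv
bicoid2d ensemble --preset main --n 50 --seed 1 --out out/noise.csv
```

`simulate` writes per-cycle profiles (CSV), the criteria report (JSON)
and the concentration rasters; `ensemble` simulates embryos with lengths
drawn from Normal(550, 20²) µm and writes the positional noise of the
cortical profile against absolute (x) and fractional (x/L) position —
with the mRNA amount scaling with embryo volume, noise is lower in x/L
(the gradient scales); without it, the ordering reverses.

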