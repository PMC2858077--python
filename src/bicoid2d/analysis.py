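"""Profile extraction and the quantitative gradient criteria.

Three criteria summarise whether a simulated gradient behaves like the
experimentally observed one:

* **stability** ``g`` — the mean, over A-P positions and successive
  nuclear-cycle pairs in 10-14, of the relative change of the nuclear
  concentration profile; stable if ``|g| < 0.1``;
* **cortical enrichment** ``Ratio`` — total Bicoid in the cortical layer
  over total in the inner (yolk) region at cycle 14; enriched if > 1.5;
* **shape** — the length constant ``lambda`` of the exponential fit
  ``A * exp(-x/lambda)``; properly shaped if ``0.15 <= lambda/L <= 0.2``.

Profiles are means over cortical cubes per A-P grid column.  The nuclear
concentration is the bound pool divided by the nuclei count, with optional
corrections for per-cycle nuclear volume and cortical-layer volume when
those vary between cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import CORTICAL, INNER, EmbryoGeometry, region_status
from .kinetics import ModelParams, bound_free_ratio
from .schedule import DevelopmentalSchedule
from .simulate import ConcentrationField, SnapshotSet

__all__ = [
    "APProfile",
    "FitResult",
    "CriteriaReport",
    "extract_profile",
    "fit_exponential",
    "stability_g",
    "cortical_ratio",
    "ensemble_noise",
    "evaluate_criteria",
    "DEFAULT_FIT_REGION",
]

#: default x/L window for exponential fits (excludes the anterior deviation)
DEFAULT_FIT_REGION: tuple[float, float] = (0.2, 0.7)


@dataclass
class APProfile:
    """Mean cortical concentration versus A-P position."""

    x: np.ndarray  # µm, cube-center column positions
    xfrac: np.ndarray  # x / L
    value: np.ndarray  # mean concentration over cortical cubes in the column
    cycle: int
    t_s: float
    pool: str = "bound"

    def __post_init__(self):
        if np.any(self.value < 0):
            raise ValueError("profile values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x,
                "x_frac": self.xfrac,
                "value": self.value,
                "cycle": self.cycle,
                "t_min": self.t_s / 60.0,
                "pool": self.pool,
            }
        )


@dataclass
class FitResult:
    """Exponential-fit summary: ``value ~ amplitude * exp(-x/lam)``."""

    lam: float  # length constant, µm
    amplitude: float
    adj_r2: float
    region: tuple[float, float]
    n_points: int


@dataclass
class CriteriaReport:
    g: float
    ratio: float
    lam: float
    lam_over_L: float
    adj_r2: float
    adj_r2_full: float  # fit region extended to the anterior pole
    pass_g: bool
    pass_ratio: bool
    pass_lambda: bool

    @property
    def passes_all(self) -> bool:
        return self.pass_g and self.pass_ratio and self.pass_lambda

    def to_dict(self) -> dict:
        return {
            "g": self.g,
            "ratio": self.ratio,
            "lambda_um": self.lam,
            "lambda_over_L": self.lam_over_L,
            "adj_r2": self.adj_r2,
            "adj_r2_full": self.adj_r2_full,
            "pass_g": self.pass_g,
            "pass_ratio": self.pass_ratio,
            "pass_lambda": self.pass_lambda,
            "passes_all": self.passes_all,
        }


def extract_profile(
    field: ConcentrationField,
    geom: EmbryoGeometry,
    sched: DevelopmentalSchedule,
    params: ModelParams,
    pool: str = "bound",
) -> APProfile:
    """A-P profile of the requested pool, averaged over cortical cubes.

    ``pool`` is one of ``total`` (B_tot as simulated), ``bound`` (the
    DNA-bound fraction of B_tot) or ``nuclear`` (bound pool per nucleus).
    For the nuclear pool the bound concentration is converted via

        B_n(c) ∝ B_bound(c) * V_cortex(c) / (nuclei(c) * v_nuc(c)),

    normalised so that at cycle 14 (constant-size convention, v_nuc = 1)
    it reduces to ``B_bound / nuclei``.
    """
    if pool not in ("total", "bound", "nuclear"):
        raise ValueError(f"unknown pool {pool!r}")
    c = field.cycle
    status = region_status(geom, c, sched.cortical_thickness(c))
    cort = status == CORTICAL
    if not cort.any():
        raise ValueError(f"no cortical layer at nuclear cycle {c}")
    counts = cort.sum(axis=0)
    cols = counts > 0
    sums = np.where(cort, field.B_tot, 0.0).sum(axis=0)
    mean_tot = sums[cols] / counts[cols]

    if pool == "total":
        value = mean_tot
    else:
        S = sched.dna_site_concentration(c)
        r = bound_free_ratio(params.K_A, S)
        bound = mean_tot * r / (1.0 + r)
        if pool == "bound":
            value = bound
        else:
            v_cortex = cort.sum() * geom.cube_volume
            status14 = region_status(geom, 14, sched.cortical_thickness(14))
            v_cortex14 = (status14 == CORTICAL).sum() * geom.cube_volume
            value = bound * (v_cortex / v_cortex14) / (
                sched.nuclei_count(c) * sched.nuclear_volume_rel(c)
            )
    x = geom.xc[cols]
    return APProfile(
        x=x, xfrac=x / geom.L, value=value, cycle=c, t_s=field.t_s, pool=pool
    )


def _adjusted_r2(y, y_hat, p: int) -> float:
    n = len(y)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_exponential(
    profile: APProfile, region: tuple[float, float] = DEFAULT_FIT_REGION
) -> FitResult:
    """Nonlinear least-squares fit of ``A * exp(-x/lam)`` on an x/L window.

    x is in µm, so ``lam`` comes out in µm.  The fit is seeded from a
    log-linear regression; if the nonlinear solver fails the seed itself
    is reported.  Adjusted R² uses p = 2 fitted parameters.
    """
    lo, hi = region
    sel = (profile.xfrac >= lo - 1e-12) & (profile.xfrac <= hi + 1e-12)
    x = profile.x[sel]
    y = profile.value[sel]
    if len(x) < 5:
        raise ValueError(f"need at least 5 points in region {region}, got {len(x)}")
    if np.all(y == 0):
        raise ValueError("profile is identically zero in the fit region")

    pos = y > 0
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    lam0 = -1.0 / slope if slope < 0 else profile.x.max()
    A0 = float(np.exp(intercept))

    def model(x, A, lam):
        return A * np.exp(-x / lam)

    try:
        popt, _ = curve_fit(model, x, y, p0=(A0, lam0), maxfev=10000)
        A, lam = float(popt[0]), float(popt[1])
    except RuntimeError:
        A, lam = A0, lam0
    adj = _adjusted_r2(y, model(x, A, lam), p=2)
    return FitResult(lam=lam, amplitude=A, adj_r2=adj, region=region, n_points=len(x))


def stability_g(
    profiles: dict[int, APProfile], denom_floor_rel: float = 1e-12
) -> float:
    """Signed cycle-to-cycle stability statistic of nuclear profiles.

    ``g`` is the mean over successive-cycle pairs and A-P positions of
    ``(B_n,c(x) - B_n,c-1(x)) / B_n,c-1(x)``.  Positions where the
    denominator falls below ``denom_floor_rel`` of that profile's maximum
    are excluded.  Requires profiles on a common x grid.
    """
    cycles = sorted(profiles)
    if len(cycles) < 2:
        raise ValueError("stability needs profiles from at least two cycles")
    diffs = []
    for prev_c, cur_c in zip(cycles[:-1], cycles[1:]):
        prev, cur = profiles[prev_c], profiles[cur_c]
        if len(prev.x) != len(cur.x) or not np.allclose(prev.x, cur.x):
            raise ValueError("profiles must share a common x grid")
        floor = denom_floor_rel * prev.value.max()
        ok = prev.value > floor
        diffs.append((cur.value[ok] - prev.value[ok]) / prev.value[ok])
    return float(np.mean(np.concatenate(diffs)))


def cortical_ratio(
    field: ConcentrationField, geom: EmbryoGeometry, sched: DevelopmentalSchedule
) -> float:
    """Total cortical-layer Bicoid over total inner-region Bicoid.

    Cube volumes are uniform, so the molecule ratio reduces to the ratio
    of summed concentrations.  Returns ``inf`` when the inner region holds
    no Bicoid.
    """
    c = field.cycle
    if c < 10:
        raise ValueError("cortical enrichment is defined from nuclear cycle 10")
    status = region_status(geom, c, sched.cortical_thickness(c))
    cort = float(field.B_tot[status == CORTICAL].sum())
    inner = float(field.B_tot[status == INNER].sum())
    if inner == 0:
        return np.inf
    return cort / inner


def ensemble_noise(
    profiles: list[APProfile],
    axis: str = "xfrac",
    n_knots: int = 100,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Across-embryo noise (SD/mean) of a profile ensemble.

    Each profile is linearly interpolated onto ``n_knots`` evenly spaced
    knots along ``axis`` (``x`` in µm or ``xfrac``); knots outside the
    common support of all profiles are dropped.  Bootstrap standard errors
    resample embryos with replacement under ``seed``.
    """
    if axis not in ("x", "xfrac"):
        raise ValueError("axis must be 'x' or 'xfrac'")
    if len(profiles) < 2:
        raise ValueError("noise needs at least two embryos")
    grids = [p.x if axis == "x" else p.xfrac for p in profiles]
    lo = max(g.min() for g in grids)
    hi = min(g.max() for g in grids)
    knots = np.linspace(lo, hi, n_knots)
    values = np.vstack(
        [np.interp(knots, g, p.value) for g, p in zip(grids, profiles)]
    )

    def _noise(mat):
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(mean > 0, sd / mean, np.nan)

    noise = _noise(values)
    rng = np.random.default_rng(seed)
    n = len(profiles)
    boots = np.empty((n_boot, n_knots))
    for b in range(n_boot):
        boots[b] = _noise(values[rng.integers(0, n, size=n)])
    se = np.nanstd(boots, axis=0, ddof=1)
    return pd.DataFrame({axis: knots, "noise": noise, "boot_se": se})


def evaluate_criteria(
    snapshots: SnapshotSet,
    geom: EmbryoGeometry | None = None,
    sched: DevelopmentalSchedule | None = None,
    params: ModelParams | None = None,
    fit_region: tuple[float, float] = DEFAULT_FIT_REGION,
) -> CriteriaReport:
    """Assemble the three-criteria report from cycle 10-14 snapshots.

    ``g`` comes from the nuclear profiles across cycles 10-14, ``Ratio``
    and the exponential fit from the cycle-14 snapshot; the fit is also
    repeated with the window extended to the anterior pole to quantify
    the anterior deviation.
    """
    geom = geom or snapshots.geom
    cfg = snapshots.config
    sched = sched or cfg.schedule
    params = params or cfg.params
    nuclear = {
        c: extract_profile(snapshots.at_cycle(c), geom, sched, params, "nuclear")
        for c in range(10, 15)
    }
    g = stability_g(nuclear)
    field14 = snapshots.at_cycle(14)
    ratio = cortical_ratio(field14, geom, sched)
    bound14 = extract_profile(field14, geom, sched, params, "bound")
    fit = fit_exponential(bound14, fit_region)
    fit_full = fit_exponential(bound14, (0.0, fit_region[1]))
    lam_over_L = fit.lam / geom.L
    return CriteriaReport(
        g=g,
        ratio=ratio,
        lam=fit.lam,
        lam_over_L=lam_over_L,
        adj_r2=fit.adj_r2,
        adj_r2_full=fit_full.adj_r2,
        pass_g=abs(g) < 0.1,
        pass_ratio=ratio > 1.5,
        pass_lambda=0.15 <= lam_over_L <= 0.2,
    )
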