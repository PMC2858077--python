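"""Forward-Euler integration of the synthesis-diffusion-degradation model.

The state variable is the total (free + bound) Bicoid concentration per
cube.  Each explicit Euler step combines diffusive exchange with the four
in-plane neighbours (no-flux at the embryo boundary), constant production
``J/v`` in mRNA-containing cubes, and first-order degradation
``omega * B_tot`` everywhere.

Only the free pool diffuses: the default flux between neighbouring cubes
is ``D * (phi_nb * B_nb - phi * B) / dx²`` with ``phi = 1/(1 + K_A*S)``
the local free fraction.  Within a homogeneous region this is identical
to the effective-diffusion form ``D_eff * laplacian(B_tot)``; across the
cortical/inner interface it additionally produces the equilibrium
trapping of Bicoid in the DNA-rich cortical layer.

The integration is piecewise-stationary: the mobility field and the
source map change only at nuclear-cycle boundaries and mitotic-window
edges, so the run is split into segments with frozen coefficients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import EmbryoGeometry, build_geometry, region_status
from .kinetics import ModelParams, diffusion_field, mobility_field
from .schedule import DevelopmentalSchedule
from .source import SourceSpec, build_source

__all__ = ["ConcentrationField", "SnapshotSet", "RunConfig", "step", "run"]


@dataclass
class ConcentrationField:
    """Total Bicoid concentration per cube at one time point."""

    B_tot: np.ndarray
    t_s: float
    cycle: int

    @property
    def t_min(self) -> float:
        return self.t_s / 60.0


@dataclass
class SnapshotSet:
    """Fields captured at the requested sample times, plus run context."""

    snapshots: list[ConcentrationField]
    geom: EmbryoGeometry
    config: "RunConfig"

    def at_cycle(self, c: int) -> ConcentrationField:
        """Latest snapshot taken during nuclear cycle ``c``."""
        hits = [s for s in self.snapshots if s.cycle == c]
        if not hits:
            raise KeyError(f"no snapshot recorded during nuclear cycle {c}")
        return hits[-1]

    @property
    def cycles(self) -> list[int]:
        return sorted({s.cycle for s in self.snapshots})


@dataclass(frozen=True)
class RunConfig:
    """Complete, deterministic description of one simulation run."""

    L: float = 550.0
    aspect: float = 1.0 / 3.0
    params: ModelParams = field(default_factory=ModelParams)
    schedule: DevelopmentalSchedule = field(default_factory=DevelopmentalSchedule)
    source: SourceSpec = field(default_factory=SourceSpec)
    snapshot_times_min: tuple[float, ...] | None = None

    def resolved_snapshot_times_min(self) -> tuple[float, ...]:
        if self.snapshot_times_min is not None:
            return tuple(self.snapshot_times_min)
        return tuple(self.schedule.sample_times_min)

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("cortical_thickness_um", "dna_sites_by_cycle",
                    "relative_nuclear_volume"):
            v = d["schedule"][key]
            if isinstance(v, Mapping):
                d["schedule"][key] = {str(k): val for k, val in v.items()}
        # plain JSON/YAML-safe types only (tuples -> lists)
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sched = dict(d.pop("schedule", {}))
        for key in ("cortical_thickness_um", "dna_sites_by_cycle",
                    "relative_nuclear_volume"):
            v = sched.get(key)
            if isinstance(v, Mapping):
                sched[key] = {int(k): float(val) for k, val in v.items()}
        for key in ("cycle_starts_min", "sample_times_min", "mitosis_cycles"):
            if key in sched and sched[key] is not None:
                sched[key] = tuple(sched[key])
        params = dict(d.pop("params", {}))
        src = dict(d.pop("source", {}))
        if "gradient_knots" in src:
            src["gradient_knots"] = tuple(tuple(k) for k in src["gradient_knots"])
        if "disc_center" in src:
            src["disc_center"] = tuple(src["disc_center"])
        if d.get("snapshot_times_min") is not None:
            d["snapshot_times_min"] = tuple(d["snapshot_times_min"])
        return cls(
            params=ModelParams(**params),
            schedule=DevelopmentalSchedule(**sched),
            source=SourceSpec(**src),
            **d,
        )


def _segment_coeffs(
    geom: EmbryoGeometry,
    sched: DevelopmentalSchedule,
    params: ModelParams,
    t_s: float,
):
    """Face diffusion coefficients and per-cube mobility for one segment.

    Returns ``(Ex, Ey, phi)`` such that the flux across a face is
    ``E * (phi_nb * B_nb - phi * B) / dx²``; coefficients vanish across
    the embryo boundary (no-flux).
    """
    mask = geom.mask
    if params.flux_scheme == "free_pool":
        phi = mobility_field(geom, sched, params, t_s)
        Ex = params.D * (mask[:, :-1] & mask[:, 1:])
        Ey = params.D * (mask[:-1, :] & mask[1:, :])
    else:  # total_pool: arithmetic-mean D_eff acting on B_tot
        phi = np.ones(geom.shape)
        Deff = diffusion_field(geom, sched, params, t_s)
        Ex = 0.5 * (Deff[:, :-1] + Deff[:, 1:]) * (mask[:, :-1] & mask[:, 1:])
        Ey = 0.5 * (Deff[:-1, :] + Deff[1:, :]) * (mask[:-1, :] & mask[1:, :])
    return Ex, Ey, phi


def _euler_steps(B, n, Ex, Ey, phi, src, omega, dt, dx2):
    """Advance ``n`` explicit steps with frozen coefficients (in place)."""
    decay = 1.0 - omega * dt
    r = dt / dx2
    dB = np.empty_like(B)
    for _ in range(n):
        C = phi * B
        dB[:] = 0.0
        fx = Ex * (C[:, 1:] - C[:, :-1])
        dB[:, :-1] += fx
        dB[:, 1:] -= fx
        fy = Ey * (C[1:, :] - C[:-1, :])
        dB[:-1, :] += fy
        dB[1:, :] -= fy
        B *= decay
        B += r * dB
        B += dt * src
    return B


def step(
    field_: ConcentrationField,
    geom: EmbryoGeometry,
    sched: DevelopmentalSchedule,
    params: ModelParams,
    source_map: np.ndarray,
    t_s: float | None = None,
) -> ConcentrationField:
    """Advance one Euler step from the state at ``t_s`` (defaults to field time)."""
    t = field_.t_s if t_s is None else t_s
    Ex, Ey, phi = _segment_coeffs(geom, sched, params, t)
    src = source_map / geom.cube_volume
    B = field_.B_tot.copy()
    _euler_steps(B, 1, Ex, Ey, phi, src, params.omega, params.dt, params.dx**2)
    t_next = t + params.dt
    return ConcentrationField(B_tot=B, t_s=t_next, cycle=sched.cycle_at(t_next))


def run(config: RunConfig) -> SnapshotSet:
    """Integrate the model from egg deposition to the end of the schedule.

    Starts from a protein-free embryo and records snapshots at the
    configured sample times.  Coefficients are refreshed at every
    nuclear-cycle boundary and at mitotic-window edges; production
    continues through mitosis (only diffusion changes there).
    """
    params, sched, spec = config.params, config.schedule, config.source
    geom = build_geometry(config.L, config.aspect, params.dx)
    dt = params.dt
    t_end = sched.t_end_s

    snap_times = np.asarray(config.resolved_snapshot_times_min(), float) * 60.0
    if np.any(snap_times > t_end) or np.any(snap_times < 0):
        raise ValueError("snapshot times must lie within the schedule")
    snap_steps = {int(round(t / dt)) for t in snap_times}
    for t in snap_times:
        if abs(round(t / dt) * dt - t) > 1e-9:
            raise ValueError(f"snapshot time {t} s is not a multiple of dt={dt}")

    events = {0.0, t_end, *sched.cycle_starts_s}
    for lo, hi in sched.mitosis_windows_s():
        events.update((lo, hi))
    events.update(snap_times)
    event_steps = sorted({int(round(t / dt)) for t in events if 0 <= t <= t_end})

    B = np.zeros(geom.shape)
    snapshots: list[ConcentrationField] = []
    dx2 = params.dx**2

    for k0, k1 in zip(event_steps[:-1], event_steps[1:]):
        t0 = k0 * dt
        if k0 in snap_steps:
            snapshots.append(
                ConcentrationField(B_tot=B.copy(), t_s=t0, cycle=sched.cycle_at(t0))
            )
        cycle = sched.cycle_at(t0)
        Ex, Ey, phi = _segment_coeffs(geom, sched, params, t0)
        status = region_status(geom, cycle, sched.cortical_thickness(cycle))
        src = build_source(geom, spec, cycle, status) / geom.cube_volume
        _euler_steps(B, k1 - k0, Ex, Ey, phi, src, params.omega, dt, dx2)
        if not np.all(np.isfinite(B)):
            bad = np.argwhere(~np.isfinite(B))[0]
            raise RuntimeError(
                f"non-finite concentration at t={k1 * dt:.1f} s, cube "
                f"(row {bad[0]}, col {bad[1]}); check the stability condition"
            )

    t_last = event_steps[-1] * dt
    if event_steps[-1] in snap_steps:
        snapshots.append(
            ConcentrationField(B_tot=B.copy(), t_s=t_last, cycle=sched.cycle_at(t_last))
        )
    return SnapshotSet(snapshots=snapshots, geom=geom, config=config)
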