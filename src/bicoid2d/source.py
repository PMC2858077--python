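"""Per-cube Bicoid production maps for the supported bcd mRNA distributions.

Maternal *bcd* mRNA is not a point source: in the early embryo it forms a
cloud near the anterior pole.  The main model projects that cloud onto the
coronal plane as a uniform disc (radius 45 µm centered 75 µm from the
pole).  Two alternatives are supported: a single-cube source at the
anterior tip (the classical point-source idealisation) and a cortical
gradient that emulates the reported redistribution of the mRNA along the
cortex from nuclear cycle 10 onward, with relative concentration falling
linearly from 1 at the pole to 0.15 at x/L = 0.3 and then to 0 at the
posterior pole.

Each cube holding mRNA produces protein at a constant rate; the rates sum
to ``aggregate_J``, whose absolute value is arbitrary (the reported
criteria are invariant to it) but whose scaling with embryo volume drives
the gradient's scaling behaviour across embryos of different length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CORTICAL, EmbryoGeometry

__all__ = [
    "SourceSpec",
    "DEFAULT_GRADIENT_KNOTS",
    "gradient_value",
    "build_source",
    "scale_aggregate_J",
]

#: (x/L, relative concentration) knots of the redistributed-mRNA profile
DEFAULT_GRADIENT_KNOTS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0),
    (0.3, 0.15),
    (1.0, 0.0),
)


@dataclass(frozen=True)
class SourceSpec:
    """Geometry and amplitude of the Bicoid production term.

    ``kind`` selects the mRNA distribution: a uniform ``disc``, a single
    ``tip`` cube at the anterior pole, or a ``cortical_gradient`` along the
    cortex.  When ``switch_cycle`` is set, the distribution given by
    ``kind`` applies before that cycle and switches instantaneously to the
    cortical gradient at its onset (the redistribution scenario).
    """

    kind: str = "disc"
    disc_radius: float = 45.0
    disc_center: tuple[float, float] = (75.0, 0.0)
    gradient_knots: tuple[tuple[float, float], ...] = DEFAULT_GRADIENT_KNOTS
    aggregate_J: float = 1.0
    scale_with_volume: bool = False
    switch_cycle: int | None = None

    def __post_init__(self):
        if self.kind not in ("disc", "tip", "cortical_gradient"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.aggregate_J < 0:
            raise ValueError("aggregate_J must be nonnegative")
        xs = [k[0] for k in self.gradient_knots]
        ys = [k[1] for k in self.gradient_knots]
        if sorted(xs) != list(xs) or not all(0 <= y <= 1 for y in ys):
            raise ValueError("gradient knots must have increasing x/L and values in [0,1]")

    def effective_kind(self, cycle: int) -> str:
        if self.switch_cycle is not None and cycle >= self.switch_cycle:
            return "cortical_gradient"
        return self.kind


def gradient_value(xfrac, knots=DEFAULT_GRADIENT_KNOTS):
    """Relative mRNA concentration at fractional A-P position ``xfrac``.

    Piecewise-linear interpolation through the knots; rejects positions
    outside [0, 1].  Accepts scalars or arrays.
    """
    x = np.asarray(xfrac, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x/L must lie in [0, 1]")
    kx = np.array([k[0] for k in knots])
    ky = np.array([k[1] for k in knots])
    out = np.interp(x, kx, ky)
    return float(out) if np.isscalar(xfrac) else out


def build_source(
    geom: EmbryoGeometry,
    spec: SourceSpec,
    cycle: int,
    status: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cube production-rate map summing to ``aggregate_J``.

    ``status`` (a region raster) is required for the cortical-gradient
    distribution, whose mRNA sits in the cortical layer only.
    """
    kind = spec.effective_kind(cycle)
    J = np.zeros(geom.shape)
    X, Y = np.meshgrid(geom.xc, geom.yc)
    if kind == "disc":
        cx, cy = spec.disc_center
        members = geom.mask & ((X - cx) ** 2 + (Y - cy) ** 2 <= spec.disc_radius**2)
        n = int(members.sum())
        if n == 0:
            raise ValueError("disc source contains no cubes inside the embryo")
        J[members] = spec.aggregate_J / n
    elif kind == "tip":
        # the single inside cube nearest the anterior pole (0, 0)
        d2 = np.where(geom.mask, X**2 + Y**2, np.inf)
        j, i = np.unravel_index(np.argmin(d2), d2.shape)
        if not np.isfinite(d2[j, i]):
            raise ValueError("no inside cube available for the tip source")
        J[j, i] = spec.aggregate_J
    else:  # cortical_gradient
        if status is None:
            raise ValueError("cortical_gradient source needs a region-status raster")
        cort = status == CORTICAL
        if not cort.any():
            raise ValueError("cortical_gradient source requires a cortical layer")
        w = np.zeros(geom.shape)
        w[cort] = gradient_value(X[cort] / geom.L, spec.gradient_knots)
        total = w.sum()
        if total == 0:
            raise ValueError("cortical gradient weights sum to zero")
        J = w * (spec.aggregate_J / total)
    return J


def scale_aggregate_J(
    base_J: float, L: float, L_ref: float, scale_with_volume: bool = True
) -> float:
    """Scale the total production with embryo volume.

    At fixed aspect ratio the embryo volume goes as ``L**3``, so a
    maternally deposited mRNA amount proportional to egg volume gives
    ``J ∝ (L/L_ref)**3``.  With ``scale_with_volume=False`` the amount is
    size-independent (the non-scaling control).
    """
    if L <= 0 or L_ref <= 0:
        raise ValueError("lengths must be positive")
    if not scale_with_volume:
        return base_J
    return base_J * (L / L_ref) ** 3
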