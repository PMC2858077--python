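"""Elliptical embryo slice on a uniform 2-D mesh.

The simulated domain is the mid-coronal section of a syncytial *Drosophila*
embryo, represented as an ellipse with major axis ``L`` along the
anterior-posterior (A-P) axis and minor axis ``aspect * L``.  The slice is
divided into uniform cubes of edge ``dx``; a cube belongs to the embryo when
its *center* lies inside the ellipse (boundary cubes whose centers fall
outside are excluded).  The anterior pole sits at ``x = 0`` and the midline
at ``y = 0``.

From nuclear cycle 10 onward the nuclei occupy a peripheral shell (the
cortical layer).  Here that shell is the set of inside cubes whose centers
lie outside a concentric ellipse shrunk by the cortical thickness on both
semi-axes; the remaining inside cubes form the nucleus-free inner region
(the yolk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OUTSIDE",
    "CORTICAL",
    "INNER",
    "EmbryoGeometry",
    "build_geometry",
    "region_status",
    "geometry_descriptor",
    "save_status_raster",
]

#: integer region-status codes used throughout the package
OUTSIDE: int = 0
CORTICAL: int = 1
INNER: int = 2


@dataclass(frozen=True)
class EmbryoGeometry:
    """Uniform-mesh discretisation of the elliptical embryo slice.

    Attributes
    ----------
    L : float
        Embryo length along the A-P axis in µm (the major axis).
    aspect : float
        Minor/major axis ratio (dimensionless).
    dx : float
        Cube edge in µm.
    xc, yc : ndarray
        Cube-center coordinates along x (shape ``(nx,)``) and y
        (shape ``(ny,)``) in µm.
    mask : ndarray of bool, shape ``(ny, nx)``
        True where the cube center lies inside the ellipse.
    """

    L: float
    aspect: float
    dx: float
    xc: np.ndarray = field(repr=False)
    yc: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    @property
    def a_major(self) -> float:
        """Semi-major axis in µm."""
        return self.L / 2.0

    @property
    def b_minor(self) -> float:
        """Semi-minor axis in µm."""
        return self.aspect * self.L / 2.0

    @property
    def cube_volume(self) -> float:
        """Volume of one cube, ``dx**3`` µm³ (third dimension implicit)."""
        return self.dx**3

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())


def build_geometry(L: float, aspect: float, dx: float) -> EmbryoGeometry:
    """Build the elliptical slice mesh.

    Parameters
    ----------
    L : float
        Embryo length (major axis) in µm, > 0.
    aspect : float
        Minor/major ratio in (0, 1].
    dx : float
        Cube edge in µm; must be smaller than the semi-minor axis.
    """
    if L <= 0:
        raise ValueError(f"embryo length must be positive, got {L}")
    if not 0 < aspect <= 1:
        raise ValueError(f"aspect ratio must be in (0, 1], got {aspect}")
    b = aspect * L / 2.0
    if not 0 < dx < b:
        raise ValueError(f"dx must satisfy 0 < dx < b_minor={b}, got {dx}")
    a = L / 2.0
    nx = int(np.ceil(L / dx))
    ny = int(np.ceil(2 * b / dx))
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx - b
    X, Y = np.meshgrid(xc, yc)
    mask = ((X - a) / a) ** 2 + (Y / b) ** 2 <= 1.0
    return EmbryoGeometry(L=L, aspect=aspect, dx=dx, xc=xc, yc=yc, mask=mask)


def region_status(
    geom: EmbryoGeometry, cycle: int, cortical_thickness: float
) -> np.ndarray:
    """Per-cube region status for a given nuclear cycle.

    During cycles 1-9 all nuclei are deep in the interior and the whole
    embryo behaves as one homogeneous medium: every inside cube is INNER.
    From cycle 10 onward the cubes within ``cortical_thickness`` of the
    boundary (concentric shrunk-ellipse rule) are CORTICAL.

    Returns an int8 array of OUTSIDE / CORTICAL / INNER codes.
    """
    if not 1 <= cycle <= 14:
        raise ValueError(f"nuclear cycle must be in 1..14, got {cycle}")
    if cortical_thickness < 0:
        raise ValueError("cortical thickness must be nonnegative")
    status = np.where(geom.mask, INNER, OUTSIDE).astype(np.int8)
    if cycle <= 9 or cortical_thickness == 0:
        return status
    a, b = geom.a_major, geom.b_minor
    T = cortical_thickness
    if T >= b:
        raise ValueError(
            f"cortical thickness {T} µm leaves no inner region (b_minor={b} µm)"
        )
    X, Y = np.meshgrid(geom.xc, geom.yc)
    deep = ((X - a) / (a - T)) ** 2 + (Y / (b - T)) ** 2 <= 1.0
    status[geom.mask & ~deep] = CORTICAL
    return status


def geometry_descriptor(geom: EmbryoGeometry) -> dict:
    """JSON-serialisable descriptor (without the raster)."""
    return {
        "L": geom.L,
        "aspect": geom.aspect,
        "dx": geom.dx,
        "nx": len(geom.xc),
        "ny": len(geom.yc),
        "n_inside": geom.n_inside,
    }


def save_status_raster(status: np.ndarray, path) -> None:
    """Dump a status (or any small integer) raster as row-major text."""
    np.savetxt(path, status, fmt="%d")


def save_geometry(geom: EmbryoGeometry, path) -> None:
    """Write the JSON descriptor; the raster can be rebuilt deterministically."""
    with open(path, "w") as fh:
        json.dump(geometry_descriptor(geom), fh, indent=2)
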