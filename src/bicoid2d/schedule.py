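"""Developmental clock of the syncytial blastoderm.

Times are counted from egg deposition.  Nuclear cycles 10-14 begin at 81,
95, 110, 125 and 140 minutes; the simulation ends 15 minutes into cycle 14.
Everything before 81 minutes (cycles 1-9) is treated as a single
"pre-cortical" epoch during which nuclei are too few to matter for
diffusion.  At each division the nuclei double, and with them the
concentration of low-affinity (non-specific) DNA binding sites smeared over
the cortical layer.

All internal times are seconds; configuration values are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "DevelopmentalSchedule",
    "estimate_dna_sites_10",
    "PRE_CORTICAL",
]

#: pooled pseudo-cycle index returned before the cortical layer forms
PRE_CORTICAL: int = 9

_MIN = 60.0  # seconds per minute


@dataclass(frozen=True)
class DevelopmentalSchedule:
    """Cycle boundaries, nuclei counts and per-cycle cortical properties.

    Parameters
    ----------
    cycle_starts_min : tuple of float
        Start times of nuclear cycles 10..14, minutes after egg deposition.
    t_end_min : float
        End of the simulation (default: 15 min into cycle 14).
    sample_times_min : tuple of float
        Default profile sampling times, one per cycle 10..14.
    nuclei_at_10 : int
        Nuclei count at the onset of cycle 10; doubles each cycle.
    dna_sites_10 : float
        Concentration of low-affinity DNA sites in the cortical layer at
        cycle 10, mol/L; doubles each cycle unless overridden.
    cortical_thickness_um : float or mapping {cycle: µm}
        Thickness of the cortical layer; a mapping gives per-cycle values.
    dna_sites_by_cycle : mapping {cycle: mol/L}, optional
        Per-cycle override of the DNA-site concentration.
    relative_nuclear_volume : mapping {cycle: float}, optional
        Relative volume of a single nucleus per cycle (1.0 when absent);
        used when converting bound to nuclear concentration.
    mitosis_enabled : bool
        When True, a free-diffusion mitotic window precedes each division
        of ``mitosis_cycles``.
    mitosis_window_min : float
        Length of each mitotic window in minutes.
    mitosis_cycles : tuple of int
        Cycles whose terminal division is modelled as a mitotic window.
    """

    cycle_starts_min: tuple[float, ...] = (81.0, 95.0, 110.0, 125.0, 140.0)
    t_end_min: float = 155.0
    sample_times_min: tuple[float, ...] = (94.0, 109.0, 124.0, 139.0, 154.0)
    nuclei_at_10: int = 512
    dna_sites_10: float = 3e-7
    cortical_thickness_um: float | Mapping[int, float] = 30.0
    dna_sites_by_cycle: Mapping[int, float] | None = None
    relative_nuclear_volume: Mapping[int, float] | None = None
    mitosis_enabled: bool = False
    mitosis_window_min: float = 3.0
    mitosis_cycles: tuple[int, ...] = (10, 11, 12, 13)

    def __post_init__(self):
        starts = np.asarray(self.cycle_starts_min, dtype=float)
        if len(starts) != 5 or np.any(np.diff(starts) <= 0):
            raise ValueError("cycle_starts_min must be 5 strictly increasing times")
        if self.t_end_min <= starts[-1]:
            raise ValueError("t_end_min must lie beyond the start of cycle 14")
        for t, c in zip(self.sample_times_min, range(10, 15)):
            if self.cycle_at(t * _MIN) != c:
                raise ValueError(
                    f"sample time {t} min does not fall within nuclear cycle {c}"
                )

    # ---- clock ---------------------------------------------------------

    @property
    def t_end_s(self) -> float:
        return self.t_end_min * _MIN

    @property
    def cycle_starts_s(self) -> np.ndarray:
        return np.asarray(self.cycle_starts_min, dtype=float) * _MIN

    @property
    def sample_times_s(self) -> np.ndarray:
        return np.asarray(self.sample_times_min, dtype=float) * _MIN

    def cycle_at(self, t_s: float) -> int:
        """Nuclear cycle index at time ``t_s`` (s); cycles 1-9 pooled as 9."""
        if t_s < 0 or t_s > self.t_end_s:
            raise ValueError(f"time {t_s} s outside [0, {self.t_end_s}]")
        idx = int(np.searchsorted(self.cycle_starts_s, t_s, side="right"))
        return PRE_CORTICAL if idx == 0 else 9 + idx

    # ---- per-cycle quantities -----------------------------------------

    def nuclei_count(self, c: int) -> int:
        """Nuclei at cycle ``c``; doubles each division from cycle 10."""
        if 10 <= c <= 14:
            return self.nuclei_at_10 * 2 ** (c - 10)
        if 1 <= c <= 9:
            # reporting only; never enters the diffusion model
            return 2 ** (c - 1)
        raise ValueError(f"nuclear cycle must be in 1..14, got {c}")

    def dna_site_concentration(self, c: int) -> float:
        """Low-affinity DNA-site concentration in the cortical layer (mol/L).

        The base concentration doubles at every division (nuclei double,
        cortical volume is per-cycle).  A ``dna_sites_by_cycle`` override
        replaces the *base* (cycle-10-equivalent) value for cycle ``c``;
        the doubling always applies.  This matches the per-cycle estimates
        of the variable nuclear-size scenario, whose quoted values equal
        sites-per-nucleus x nuclei(c) / (N_A x V_cortex(c) x 2^(c-10)).
        """
        if not 10 <= c <= 14:
            raise ValueError(f"nuclear cycle must be in 10..14, got {c}")
        base = self.dna_sites_10
        if self.dna_sites_by_cycle is not None and c in self.dna_sites_by_cycle:
            base = float(self.dna_sites_by_cycle[c])
        return base * 2 ** (c - 10)

    def cortical_thickness(self, c: int) -> float:
        """Cortical-layer thickness (µm) at cycle ``c``; 0 before cycle 10."""
        if c < 10:
            return 0.0
        if isinstance(self.cortical_thickness_um, Mapping):
            return float(self.cortical_thickness_um[c])
        return float(self.cortical_thickness_um)

    def nuclear_volume_rel(self, c: int) -> float:
        if self.relative_nuclear_volume is not None and c in self.relative_nuclear_volume:
            return float(self.relative_nuclear_volume[c])
        return 1.0

    # ---- mitosis -------------------------------------------------------

    def mitosis_windows_s(self) -> list[tuple[float, float]]:
        """Half-open [start, end) free-diffusion windows in seconds.

        The mitosis terminating cycle ``c`` is placed in the first
        ``mitosis_window_min`` minutes of cycle ``c+1``, so that the
        standard mid-cycle sampling times (13-14 minutes into each
        cycle) never fall inside a window — a sample taken during
        mitosis would see no DNA-bound Bicoid at all.
        """
        if not self.mitosis_enabled:
            return []
        windows = []
        starts = self.cycle_starts_s
        for c in self.mitosis_cycles:
            if not 10 <= c <= 13:
                raise ValueError("mitotic windows are defined for cycles 10-13")
            begin = starts[c - 9]  # start of cycle c+1
            windows.append((begin, begin + self.mitosis_window_min * _MIN))
        return windows

    def in_mitosis(self, t_s: float) -> bool:
        """True iff ``t_s`` falls inside a mitotic free-diffusion window."""
        return any(lo <= t_s < hi for lo, hi in self.mitosis_windows_s())


def estimate_dna_sites_10(
    n_nuclei: float, sites_per_nucleus: float, cortical_volume_l: float
) -> float:
    """Estimate the cycle-10 DNA-site concentration (mol/L).

    ``n_nuclei`` nuclei each carrying ``sites_per_nucleus`` low-affinity
    sites, smeared homogeneously over a cortical layer of
    ``cortical_volume_l`` litres.  With 512 nuclei, ~2e6 TAAT sites per
    diploid nucleus and a ~5.8 nl cortical layer this gives ~3e-7 M.
    """
    if cortical_volume_l <= 0:
        raise ValueError("cortical volume must be positive")
    if n_nuclei < 0 or sites_per_nucleus < 0:
        raise ValueError("counts must be nonnegative")
    return n_nuclei * sites_per_nucleus / (Avogadro * cortical_volume_l)
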