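"""Named run configurations for the documented simulation scenarios."""

from __future__ import annotations

from .kinetics import ModelParams
from .schedule import DevelopmentalSchedule
from .simulate import RunConfig
from .source import SourceSpec

__all__ = ["preset", "list_presets"]


def _main() -> RunConfig:
    """Wild-type reference: disc mRNA source, constant nuclear size."""
    return RunConfig()


def _high_affinity() -> RunConfig:
    """K_A raised to 1e7 1/M: binding too tight, nuclear profiles destabilise."""
    return RunConfig(params=ModelParams(K_A=1e7))


def _low_affinity() -> RunConfig:
    """K_A lowered to 1e4 1/M: binding too weak, no cortical enrichment."""
    return RunConfig(params=ModelParams(K_A=1e4))


def _mitosis() -> RunConfig:
    """Main model plus 3-minute free-diffusion windows at divisions 10-13."""
    return RunConfig(schedule=DevelopmentalSchedule(mitosis_enabled=True))


def _mrna_redistribution() -> RunConfig:
    """Disc source through cycle 9, then a cortical mRNA gradient.

    The relative mRNA concentration falls linearly from 1 at the anterior
    pole to 0.15 at x/L = 0.3 and to 0 at the posterior pole; total
    production is conserved across the switch.
    """
    return RunConfig(
        params=ModelParams(D=2.0, omega=5e-4, K_A=2e5),
        source=SourceSpec(kind="disc", switch_cycle=10),
    )


def _tip_source() -> RunConfig:
    """Point-source idealisation: all mRNA in one cube at the anterior tip."""
    return RunConfig(source=SourceSpec(kind="tip"))


def _shifted_source() -> RunConfig:
    """Disc source moved to (50 µm, 0), closer to the anterior pole."""
    return RunConfig(source=SourceSpec(kind="disc", disc_center=(50.0, 0.0)))


def _nuclear_size() -> RunConfig:
    """Per-cycle cortical thickness, DNA-site levels and nuclear volumes.

    Cortical thickness grows from 15 to 25 µm over cycles 10-14 while the
    nuclei shrink; the DNA-site concentrations are re-estimated per cycle
    rather than doubling.  Cycle 14 is sampled 5 minutes in.
    """
    return RunConfig(
        params=ModelParams(D=6.0, omega=4e-4, K_A=2.4e6),
        schedule=DevelopmentalSchedule(
            sample_times_min=(94.0, 109.0, 124.0, 139.0, 145.0),
            cortical_thickness_um={10: 15.0, 11: 20.0, 12: 20.0, 13: 23.0, 14: 25.0},
            dna_sites_by_cycle={10: 5e-7, 11: 4e-7, 12: 4e-7, 13: 3.6e-7, 14: 3.4e-7},
            relative_nuclear_volume={10: 3.64, 11: 4.21, 12: 2.83, 13: 2.0, 14: 1.0},
        ),
    )


_PRESETS = {
    "main": _main,
    "high_affinity": _high_affinity,
    "low_affinity": _low_affinity,
    "mitosis": _mitosis,
    "mrna_redistribution": _mrna_redistribution,
    "tip_source": _tip_source,
    "shifted_source": _shifted_source,
    "nuclear_size": _nuclear_size,
}


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> RunConfig:
    """Return a fully populated :class:`RunConfig` for a named scenario."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(list_presets())}"
        ) from None
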