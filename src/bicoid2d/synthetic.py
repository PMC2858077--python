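"""Synthetic exponential profiles for exercising the analysis machinery."""

from __future__ import annotations

import numpy as np

from .analysis import APProfile

__all__ = ["synthetic_profile"]


def synthetic_profile(
    lam: float,
    amplitude: float = 7.0,
    noise_sd: float = 0.0,
    n_points: int = 100,
    seed: int | None = None,
    L: float = 550.0,
    cycle: int = 14,
) -> APProfile:
    """Exponential profile ``A * exp(-x/lam)`` with optional Gaussian noise.

    Points sit on an even grid spanning the embryo; negative noisy values
    are clipped at zero so the result remains a valid concentration
    profile.
    """
    if lam <= 0:
        raise ValueError("length constant must be positive")
    x = np.linspace(0.0, L, n_points)
    y = amplitude * np.exp(-x / lam)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, n_points), 0.0, None)
    return APProfile(x=x, xfrac=x / L, value=y, cycle=cycle, t_s=0.0, pool="bound")
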