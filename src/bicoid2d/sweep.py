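"""Systematic parameter sampling against the three gradient criteria.

Scans (D, omega, K_A) either as a full factorial grid or one axis at a
time with the other parameters held at the base configuration's values,
evaluating the stability, enrichment and shape criteria for each
combination.  Combinations violating the explicit-scheme stability bound
are skipped and flagged rather than silently adjusted.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import evaluate_criteria
from .simulate import RunConfig, run

__all__ = ["SweepSpec", "run_sweep", "operating_range", "DEFAULT_AXES"]

_AXIS_NAMES = ("D", "omega", "K_A")

#: reconstruction of plausible scan ranges (the study conditions print no
#: exact increments); override per use
DEFAULT_AXES: dict[str, tuple[float, ...]] = {
    "D": (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    "omega": (1e-5, 5e-5, 1e-4, 5e-4, 1e-3),
    "K_A": tuple(np.logspace(4, 7, 13)),
}


@dataclass(frozen=True)
class SweepSpec:
    """Axes (parameter value lists) and sampling mode for a sweep."""

    axes: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AXES)
    )
    mode: str = "one_at_a_time"  # or "grid"

    def __post_init__(self):
        if self.mode not in ("grid", "one_at_a_time"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if not self.axes:
            raise ValueError("sweep needs at least one axis")
        for name, values in self.axes.items():
            if name not in _AXIS_NAMES:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(values) == 0 or any(v <= 0 for v in values):
                raise ValueError(f"axis {name!r} needs positive values")


def _evaluate_point(base: RunConfig, point: dict[str, float]) -> dict:
    row = {name: point.get(name, getattr(base.params, name)) for name in _AXIS_NAMES}
    try:
        params = dataclasses.replace(base.params, **point)
    except ValueError as err:  # stability bound violated for this combination
        row.update(
            cfl_ok=False, error=str(err), g=np.nan, ratio=np.nan, lam=np.nan,
            lam_over_L=np.nan, adj_r2=np.nan,
            pass_g=False, pass_ratio=False, pass_lambda=False, passes_all=False,
        )
        return row
    cfg = dataclasses.replace(base, params=params)
    rep = evaluate_criteria(run(cfg))
    row.update(
        cfl_ok=True, error="", g=rep.g, ratio=rep.ratio, lam=rep.lam,
        lam_over_L=rep.lam_over_L, adj_r2=rep.adj_r2,
        pass_g=rep.pass_g, pass_ratio=rep.pass_ratio,
        pass_lambda=rep.pass_lambda, passes_all=rep.passes_all,
    )
    return row


def run_sweep(spec: SweepSpec, base: RunConfig) -> pd.DataFrame:
    """Evaluate the criteria at each sampled parameter combination.

    Rows are ordered deterministically by axis order and value order; in
    one-at-a-time mode a ``varied`` column names the scanned axis.
    """
    rows = []
    if spec.mode == "grid":
        names = [n for n in _AXIS_NAMES if n in spec.axes]
        for combo in itertools.product(*(spec.axes[n] for n in names)):
            rows.append(_evaluate_point(base, dict(zip(names, combo))))
    else:
        for name in _AXIS_NAMES:
            if name not in spec.axes:
                continue
            for v in spec.axes[name]:
                row = _evaluate_point(base, {name: float(v)})
                row["varied"] = name
                rows.append(row)
    return pd.DataFrame(rows)


def operating_range(
    result: pd.DataFrame, axis: str, criterion: str = "passes_all"
) -> list[tuple[float, float]]:
    """Maximal contiguous runs of passing values along a one-at-a-time axis.

    Returns a list of (lo, hi) value intervals of the scanned axis where
    ``criterion`` (a boolean column of the sweep result) holds; empty when
    no value passes.
    """
    if "varied" not in result.columns:
        raise ValueError("operating_range needs a one-at-a-time sweep result")
    sub = result[result["varied"] == axis].sort_values(axis)
    values = sub[axis].to_numpy()
    passing = sub[criterion].to_numpy(dtype=bool)
    intervals = []
    start = None
    for i, ok in enumerate(passing):
        if ok and start is None:
            start = values[i]
        elif not ok and start is not None:
            intervals.append((start, values[i - 1]))
            start = None
    if start is not None:
        intervals.append((start, values[-1]))
    return intervals
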