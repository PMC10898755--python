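"""Decadal-change statistics from paired posterior-predictive draws.

Given predictive concentration draws for two years on the same grid, paired
by draw index, this module computes per-grid-point percent change and
probability of decrease, per-stratum average-concentration draws

    bhat_{year,t}^(k) = (1 / m_t) * sum_{l in stratum t} yhat_{year,l}^(k),

and the stratum change tables (per-year summaries, average change, percent
change, probability of decrease) in the layout used for reporting, for the
whole grid and separately per side of the road.

All percent-change and probability statistics are computed draw-wise and only
then summarized: summary-of-ratio, never ratio-of-summaries.
Quantiles use linear interpolation of order statistics (type-7 rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import PredictiveDrawSet
from .synthetic import GridPoint

__all__ = [
    "PairedYearDraws",
    "pointwise_percent_change",
    "probability_of_decrease",
    "stratum_average_draws",
    "stratum_change_table",
    "paired_change_tables",
]

REGIONS = ("all", "north", "south")


@dataclass
class PairedYearDraws:
    """Predictive draw sets for two years of one element, paired by index."""

    draws_first: PredictiveDrawSet
    draws_second: PredictiveDrawSet

    def __post_init__(self) -> None:
        a, b = self.draws_first, self.draws_second
        if a.values.shape != b.values.shape:
            raise ValueError("paired draw sets must share K and grid size")
        if a.grid_ids != b.grid_ids:
            raise ValueError("paired draw sets must be on the same grid")
        if a.element is not None and b.element is not None and a.element != b.element:
            raise ValueError("paired draw sets must be for the same element")


def _summarize(draws: np.ndarray, axis: int = 0) -> dict[str, np.ndarray]:
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=axis, method="linear")
    return {"mean": draws.mean(axis=axis), "sd": draws.std(axis=axis, ddof=1),
            "lower": lo, "upper": hi}


def pointwise_percent_change(paired: PairedYearDraws) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-point percent-change draws 100 * (y2 - y1) / y1 and their summaries."""
    y1 = paired.draws_first.values
    y2 = paired.draws_second.values
    assert np.all(y1 > 0), "first-year draws must be positive"
    pct = 100.0 * (y2 - y1) / y1
    s = _summarize(pct)
    prob_dec = (y1 > y2).mean(axis=0)
    summary = pd.DataFrame({"grid_id": paired.draws_first.grid_ids, **s,
                            "prob_decrease": prob_dec})
    return pct, summary


def probability_of_decrease(draws_first: np.ndarray, draws_second: np.ndarray) -> float:
    """Proportion of paired draws where the first (earlier) value exceeds the
    second (strict inequality; ties count as no decrease)."""
    a = np.asarray(draws_first, dtype=float)
    b = np.asarray(draws_second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need equal-length non-empty draw vectors")
    return float(np.mean(a > b))


def stratum_average_draws(
    predictive: PredictiveDrawSet,
    grid: list[GridPoint],
    region: str = "all",
) -> dict[int, np.ndarray | None]:
    """Per-stratum, per-draw average concentration.

    Returns a mapping stratum -> (K,) array of bhat draws, with ``None`` for
    a stratum empty in the requested region (stratum 5 has no north points by
    construction; that absence is flagged, not an error).
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    if len(grid) != predictive.values.shape[1]:
        raise ValueError("grid does not match the predictive draw set")
    strata = sorted({g.stratum for g in grid})
    out: dict[int, np.ndarray | None] = {}
    for t in strata:
        cols = [i for i, g in enumerate(grid)
                if g.stratum == t and (region == "all" or g.side == region)]
        out[t] = predictive.values[:, cols].mean(axis=1) if cols else None
    return out


def stratum_change_table(
    b_first: dict[int, np.ndarray | None],
    b_second: dict[int, np.ndarray | None],
    counts: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Change table over strata from paired average-concentration draws.

    Columns follow the reporting layout: N, first-year mean/SD/lower/upper,
    second-year mean/SD/lower/upper, average change, percent change (each
    mean/SD/lower/upper) and probability of decrease in percent.  Change and
    percent change are computed draw-wise, so the mean change equals the
    difference of the per-year means exactly.
    """
    if set(b_first) != set(b_second):
        raise ValueError("the two years cover different strata")
    rows = []
    for t in sorted(b_first):
        a, b = b_first[t], b_second[t]
        if (a is None) != (b is None):
            raise ValueError(f"stratum {t} present in only one year")
        if a is None:
            continue  # structurally empty stratum-region: flagged by absence
        if a.shape != b.shape:
            raise ValueError(f"stratum {t}: paired draws have mismatched length")
        change = b - a
        pct = 100.0 * change / a
        row: dict = {"stratum": t, "n": counts.get(t) if counts else len(a)}
        for prefix, draws in (("first", a), ("second", b),
                              ("change", change), ("pct_change", pct)):
            s = _summarize(draws)
            row.update({f"{prefix}_{k}": float(v) for k, v in s.items()})
        row["prob_decrease_pct"] = 100.0 * probability_of_decrease(a, b)
        rows.append(row)
    return pd.DataFrame(rows)


def paired_change_tables(
    paired: PairedYearDraws,
    grid: list[GridPoint],
) -> pd.DataFrame:
    """Stratum change tables for the whole grid and per side, stacked with a
    ``region`` column; N is the number of grid points per stratum-region."""
    frames = []
    for region in REGIONS:
        b1 = stratum_average_draws(paired.draws_first, grid, region)
        b2 = stratum_average_draws(paired.draws_second, grid, region)
        counts = {t: sum(1 for g in grid if g.stratum == t
                         and (region == "all" or g.side == region))
                  for t in b1}
        tab = stratum_change_table(b1, b2, counts)
        tab.insert(0, "region", region)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
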