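"""Direction classification and per-disperser summaries.

A seed is classified *downhill* when the entire 95% credible interval of
its dispersal distance lies below zero, *uphill* when it lies above zero,
and *neither* otherwise; an interval endpoint exactly at zero is
conservatively *neither*.  Species-level summaries report mean ± SE of
the per-seed posterior-mean distances plus the three direction
proportions.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import DispersalEstimate

__all__ = [
    "Direction",
    "DisperserSummary",
    "classify_direction",
    "disperser_summary",
    "direction_proportion_table",
    "format_report",
]


class Direction(str, enum.Enum):
    DOWNHILL = "downhill"
    UPHILL = "uphill"
    NEITHER = "neither"


@dataclass(frozen=True)
class DisperserSummary:
    """Per-species dispersal summary over seeds.

    ``mean_distance``/``se_distance`` are the mean and standard error of
    the per-seed posterior-mean distances (m); ``se_distance`` is NaN for
    a single seed.  Proportions are fractions in [0, 1] summing to 1.
    """

    species: str
    n_seeds: int
    mean_distance: float
    se_distance: float
    prop_downhill: float
    prop_uphill: float
    prop_neither: float

    def __post_init__(self) -> None:
        total = self.prop_downhill + self.prop_uphill + self.prop_neither
        if abs(total - 1.0) > 1e-9:
            raise ValueError("direction proportions must sum to 1")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def classify_direction(est: DispersalEstimate) -> Direction:
    """Direction class from the 95% credible interval of distance."""
    lo, hi = est.ci95
    if lo > hi:
        raise ValueError("credible interval bounds out of order")
    if hi < 0:
        return Direction.DOWNHILL
    if lo > 0:
        return Direction.UPHILL
    return Direction.NEITHER


def disperser_summary(
    estimates: Sequence[DispersalEstimate], species: str
) -> DisperserSummary:
    """Summarise one species' seeds: mean ± SE distance and direction mix."""
    group = [e for e in estimates if e.species == species]
    if not group:
        raise ValueError(f"no estimates for species {species!r}")
    dist = np.array([e.post_mean_distance for e in group])
    n = len(group)
    if n == 1:
        warnings.warn(f"single seed for {species!r}: standard error undefined")
        se = float("nan")
    else:
        se = float(dist.std(ddof=1) / math.sqrt(n))
    classes = [classify_direction(e) for e in group]
    return DisperserSummary(
        species=species,
        n_seeds=n,
        mean_distance=float(dist.mean()),
        se_distance=se,
        prop_downhill=classes.count(Direction.DOWNHILL) / n,
        prop_uphill=classes.count(Direction.UPHILL) / n,
        prop_neither=classes.count(Direction.NEITHER) / n,
    )


def direction_proportion_table(summaries: Iterable[DisperserSummary]) -> pd.DataFrame:
    """Species × direction table in percent (rows sum to 100)."""
    rows = [
        {
            "species": s.species,
            "n_seeds": s.n_seeds,
            "downhill_pct": 100.0 * s.prop_downhill,
            "uphill_pct": 100.0 * s.prop_uphill,
            "neither_pct": 100.0 * s.prop_neither,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["species", "n_seeds", "downhill_pct", "uphill_pct", "neither_pct"])


def format_report(summaries: Sequence[DisperserSummary]) -> str:
    """Human-readable paragraph mirroring the summary-table content.

    Sign convention: positive = toward the mountain top, negative =
    toward the foot.
    """
    lines = [
        "Vertical seed dispersal summary "
        "(negative = toward the mountain foot, positive = toward the top):"
    ]
    for s in summaries:
        se = f"{s.se_distance:.1f}" if math.isfinite(s.se_distance) else "NA"
        lines.append(
            f"  {s.species}: mean {s.mean_distance:+.1f} ± {se} m SE over "
            f"{s.n_seeds} seeds; {100 * s.prop_downhill:.0f}% downhill, "
            f"{100 * s.prop_uphill:.0f}% uphill, {100 * s.prop_neither:.0f}% neither "
            "(by 95% credible intervals)."
        )
    return "\n".join(lines)
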