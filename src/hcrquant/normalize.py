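"""Ratio normalization of RFP by GFP expression and scaling to the control maximum.

GFP expression (constitutive reporter) normalizes RFP expression (damage-carrying
reporter) for transfection efficiency. Because per-measurement GFP follows a gamma
distribution with shape below 2, the inverse 1/GFP is heavy-tailed and simple
per-measurement ratios RFP/GFP have an ill-behaved error distribution at small n.
The normalization therefore uses *data combinations*: for every unordered pair of
measurements {i, j} within a condition the ratio

    (R_i + R_j) / (G_i + G_j)

is formed. Pair sums of gamma variates have shape 2k > 2, so the inverse of the
denominator has finite variance and the resulting error distribution is unimodal.

Time courses are scaled within each cell line so that 100% is the maximum over
time of the undamaged control's mean combination ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementPair",
    "ConditionGroup",
    "CombinationRatios",
    "ScaledTimecourse",
    "combination_ratios",
    "scale_to_control_max",
    "summarize_timecourse",
]


class MeasurementPair(NamedTuple):
    """One experimental measurement: an (RFP, GFP) expression-value pair."""

    rfp: float
    gfp: float


@dataclass
class ConditionGroup:
    """The n replicate (RFP, GFP) pairs for one cell line x vector x time point."""

    cell_line: str
    vector: str
    time_h: float
    pairs: list[MeasurementPair]

    def __post_init__(self):
        self.pairs = [MeasurementPair(float(r), float(g)) for r, g in self.pairs]
        for p in self.pairs:
            if not (p.rfp > 0 and p.gfp > 0):
                raise ValueError(
                    f"{self.cell_line}/{self.vector}@{self.time_h}h: expression "
                    f"values must be positive, got {p}"
                )

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass
class CombinationRatios:
    """All C(n, 2) pairwise-combination ratios for one condition group."""

    cell_line: str
    vector: str
    time_h: float
    n_measurements: int
    ratios: np.ndarray

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)


def combination_ratios(group: ConditionGroup) -> CombinationRatios:
    """Pairwise-combination ratios (R_i + R_j)/(G_i + G_j) over all unordered pairs.

    The order of the returned ratios is lexicographic in the index pair (i, j),
    i < j, so output is deterministic. Requires n >= 2 positive pairs.
    """
    if group.n < 2:
        raise ValueError(
            f"{group.cell_line}/{group.vector}@{group.time_h}h: need at least 2 "
            f"measurements to form combinations, got {group.n}"
        )
    ratios = [
        (a.rfp + b.rfp) / (a.gfp + b.gfp)
        for a, b in combinations(group.pairs, 2)
    ]
    return CombinationRatios(
        cell_line=group.cell_line,
        vector=group.vector,
        time_h=group.time_h,
        n_measurements=group.n,
        ratios=np.asarray(ratios),
    )


@dataclass
class ScaledTimecourse:
    """One vector's combination ratios scaled to percent of the control maximum.

    ``scaled`` maps time point (h) to the array of scaled ratios (percent);
    ``n_measurements`` maps time point to the underlying measurement count n;
    ``reference`` is the raw mean combination ratio that defines 100%.
    """

    cell_line: str
    vector: str
    reference: float
    scaled: dict[float, np.ndarray] = field(default_factory=dict)
    n_measurements: dict[float, int] = field(default_factory=dict)

    @property
    def times(self) -> list[float]:
        return sorted(self.scaled)


def scale_to_control_max(
    groups: list[ConditionGroup], control_vector: str = "control"
) -> dict[str, ScaledTimecourse]:
    """Scale one cell line's time courses to percent of the control maximum.

    100% is the maximum over time points of the undamaged control's mean
    combination ratio, so the control series attains 100% at its peak by
    construction. All groups must belong to the same cell line.

    Returns a mapping vector label -> :class:`ScaledTimecourse`.
    """
    if not groups:
        raise ValueError("no condition groups supplied")
    cell_lines = {g.cell_line for g in groups}
    if len(cell_lines) != 1:
        raise ValueError(f"scaling is within one cell line, got {sorted(cell_lines)}")
    cell_line = cell_lines.pop()

    combos = {(g.vector, g.time_h): combination_ratios(g) for g in groups}
    control_means = [
        float(np.mean(cr.ratios)) for (v, _t), cr in combos.items() if v == control_vector
    ]
    if not control_means:
        raise ValueError(f"control vector {control_vector!r} absent from cell line {cell_line!r}")
    reference = max(control_means)
    if reference <= 0:
        raise ValueError(f"control reference for {cell_line!r} is non-positive")

    out: dict[str, ScaledTimecourse] = {}
    for (vector, time_h), cr in combos.items():
        tc = out.setdefault(
            vector, ScaledTimecourse(cell_line=cell_line, vector=vector, reference=reference)
        )
        tc.scaled[time_h] = 100.0 * cr.ratios / reference
        tc.n_measurements[time_h] = cr.n_measurements
    return out


def summarize_timecourse(scaled: ScaledTimecourse) -> pd.DataFrame:
    """Per-time-point mean percent, standard error, and measurement count.

    The standard error is the SD of the scaled combination ratios divided by the
    square root of the number of *measurements* n (the pair combinations are not
    independent draws, so n — not C(n, 2) — carries the information). With a
    single combination ratio the SE is reported as NaN.
    """
    rows = []
    for t in scaled.times:
        vals = scaled.scaled[t]
        n = scaled.n_measurements[t]
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if len(vals) > 1 else float("nan")
        rows.append(
            {"cell_line": scaled.cell_line, "vector": scaled.vector, "time_h": t,
             "mean_pct": float(np.mean(vals)), "se": se, "n": n}
        )
    return pd.DataFrame(rows, columns=["cell_line", "vector", "time_h", "mean_pct", "se", "n"])
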