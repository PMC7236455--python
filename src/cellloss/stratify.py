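"""Quartile stratification and descriptive statistics.

Patients are split into quartile groups of the baseline cell-loss metric
by rank: sort ascending (ties broken by patient id, so the assignment is
stable and reproducible), then cut the rank order into four contiguous
blocks whose sizes differ by at most one.  For n divisible by 4 this gives
exactly equal groups (104 -> 26/26/26/26), which a cut-point rule cannot
guarantee under ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SummaryStats",
    "QuartileGrouping",
    "assign_quartiles",
    "summarize",
    "group_summaries",
    "summarize_categorical",
    "pooled_mean",
    "QUANTILE_METHOD",
]

# Quantile convention used throughout: linear interpolation at position
# (n-1)*p over 0-indexed order statistics (numpy's "linear" method).
# Centralized so an alternative convention is a one-line change.
QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary of one variable: n, mean, sample std, quartiles."""

    n: int
    mean: float
    std: float
    median: float
    min: float
    max: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "std": self.std,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
        }


@dataclass(frozen=True)
class QuartileGrouping:
    """Rank-based quartile assignment of patients on one variable."""

    labels: dict[str, int]  # patient_id -> 1..4
    boundaries: tuple[float, float, float]
    stratifier: str

    def group_ids(self, g: int) -> list[str]:
        return [pid for pid, lab in self.labels.items() if lab == g]

    def sizes(self) -> list[int]:
        return [sum(1 for v in self.labels.values() if v == g) for g in (1, 2, 3, 4)]


def assign_quartiles(values: dict[str, float], stratifier: str = "value") -> QuartileGrouping:
    """Assign each patient to a quartile group of ``values``.

    Sort ascending with ties broken by patient id; split ranks into four
    contiguous blocks of size ceil(n/4) or floor(n/4), larger blocks first.
    Reported boundaries are midpoints between the straddling values.
    """
    if len(values) < 4:
        raise ValueError(f"need at least 4 values to form quartiles, got {len(values)}")
    for pid, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite value for patient {pid}")

    order = sorted(values, key=lambda pid: (values[pid], pid))
    n = len(order)
    base, extra = divmod(n, 4)
    sizes = [base + (1 if g < extra else 0) for g in range(4)]

    labels: dict[str, int] = {}
    cuts: list[int] = []
    pos = 0
    for g, sz in enumerate(sizes, start=1):
        for pid in order[pos : pos + sz]:
            labels[pid] = g
        pos += sz
        if g < 4:
            cuts.append(pos)
    boundaries = tuple(
        (values[order[c - 1]] + values[order[c]]) / 2.0 for c in cuts
    )
    return QuartileGrouping(labels=labels, boundaries=boundaries, stratifier=stratifier)


def summarize(values) -> SummaryStats:
    """Summary statistics with sample (n-1) std and interpolated quartiles."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty list")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
    return SummaryStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        std=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        min=float(np.min(x)),
        max=float(np.max(x)),
        q1=float(q1),
        q3=float(q3),
    )


def summarize_categorical(values) -> dict[str, dict]:
    """Counts and percentages per level; the denominator is the non-missing n."""
    vals = [v for v in values if v is not None]
    n = len(vals)
    out: dict[str, dict] = {}
    for level in sorted({str(v) for v in vals}):
        cnt = sum(1 for v in vals if str(v) == level)
        out[level] = {"n": cnt, "percent": 100.0 * cnt / n if n else float("nan")}
    return out


def group_summaries(
    variables: dict[str, dict[str, float]],
    grouping: QuartileGrouping,
) -> dict[str, dict[str, SummaryStats]]:
    """Per-quartile and total summaries in the descriptive-table layout.

    ``variables`` maps variable name -> {patient_id -> value}; patients
    missing a variable are dropped from that variable's summaries
    (complete-case per variable).  Every patient carrying a value must be
    covered by the grouping.
    """
    groups = {g: set(grouping.group_ids(g)) for g in (1, 2, 3, 4)}
    covered = set(grouping.labels)
    out: dict[str, dict[str, SummaryStats]] = {}
    for name, mapping in variables.items():
        missing = set(mapping) - covered
        if missing:
            raise ValueError(
                f"grouping does not cover patient(s) {sorted(missing)[:5]} for {name!r}"
            )
        cols: dict[str, SummaryStats] = {}
        all_vals = [v for v in mapping.values() if v is not None]
        if not all_vals:
            raise ValueError(f"variable {name!r} has no values")
        cols["total"] = summarize(all_vals)
        for g in (1, 2, 3, 4):
            vals = [v for pid, v in mapping.items() if pid in groups[g] and v is not None]
            if vals:
                cols[f"q{g}"] = summarize(vals)
        out[name] = cols
    return out


def pooled_mean(ns, means) -> float:
    """Sample-size-weighted mean of subgroup means."""
    ns = list(ns)
    means = list(means)
    if len(ns) != len(means) or not ns:
        raise ValueError("ns and means must be equal-length, non-empty")
    total = sum(ns)
    if total <= 0:
        raise ValueError("total n must be positive")
    return sum(n * m for n, m in zip(ns, means)) / total
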