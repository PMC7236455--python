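"""ROC analysis, cut-off selection and confusion-matrix reconstruction.

The orientation convention throughout: a higher cell-loss metric predicts
a more favourable pathologic response, so the positive class is pCR and a
patient is test-positive when their score is >= the cut-off (inclusive,
so a cut-off placed at an observed value reproduces a step of the
empirical curve).

``reconstruct_confusion`` and ``enumerate_consistent_matrices`` turn
rounded published summary rates back into the integer confusion matrices
they must have come from, making printed sensitivity/specificity/PPV/NPV
figures auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionSummary",
    "RocCurve",
    "roc_curve",
    "evaluate_cutoff",
    "youden_cutoff",
    "reconstruct_confusion",
    "enumerate_consistent_matrices",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (0.5 -> 1), as tables print."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class ConfusionSummary:
    """Integer confusion matrix with its derived rates.

    Rates whose denominator is zero are ``None`` (flagged undefined rather
    than NaN).  ``cutoff`` is absent for matrices reconstructed from
    printed summaries.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float | None = None

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float | None:
        return _safe_ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _safe_ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _safe_ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _safe_ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: (1-specificity, sensitivity) per threshold."""

    points: tuple[tuple[float, float], ...]  # (fpr, tpr), includes (0,0),(1,1)
    thresholds: tuple[float, ...]  # aligned with interior points
    auc: float


def _check_labels(scores: dict[str, float], labels: dict[str, str]):
    if set(scores) != set(labels):
        raise ValueError("scores and labels must cover the same patients")
    pos = [pid for pid, lab in labels.items() if lab == "positive"]
    neg = [pid for pid, lab in labels.items() if lab == "negative"]
    if len(pos) + len(neg) != len(labels):
        bad = set(labels.values()) - {"positive", "negative"}
        raise ValueError(f"labels must be 'positive'/'negative', got {bad}")
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative label")
    return pos, neg


def roc_curve(scores: dict[str, float], labels: dict[str, str]) -> RocCurve:
    """Empirical ROC over all distinct score thresholds (higher = more positive).

    AUC is the trapezoidal area, which with the inclusive >= rule equals
    the tie-corrected rank (Mann–Whitney) statistic.
    """
    pos, neg = _check_labels(scores, labels)
    pos_scores = np.array([scores[p] for p in pos], dtype=float)
    neg_scores = np.array([scores[p] for p in neg], dtype=float)
    thresholds = np.unique(np.concatenate([pos_scores, neg_scores]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(pos_scores >= t))
        fpr = float(np.mean(neg_scores >= t))
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=tuple(pts), thresholds=tuple(float(t) for t in thresholds), auc=auc)


def evaluate_cutoff(
    scores: dict[str, float], labels: dict[str, str], cutoff: float
) -> ConfusionSummary:
    """Confusion summary for the rule test-positive iff score >= cutoff."""
    pos, neg = _check_labels(scores, labels)
    tp = sum(1 for p in pos if scores[p] >= cutoff)
    fp = sum(1 for p in neg if scores[p] >= cutoff)
    return ConfusionSummary(
        tp=tp, fp=fp, fn=len(pos) - tp, tn=len(neg) - fp, cutoff=cutoff
    )


def youden_cutoff(
    scores: dict[str, float], labels: dict[str, str]
) -> tuple[float, ConfusionSummary]:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cut-offs sweep the observed scores; ties in J are broken
    toward higher specificity (i.e. the higher cut-off).  The returned
    cut-off is the midpoint between the adjacent distinct scores so it
    does not sit exactly on a data point.
    """
    pos, neg = _check_labels(scores, labels)
    all_scores = np.unique(list(scores.values()))
    # candidate inclusive thresholds: each observed score, plus one above max
    candidates = list(all_scores) + [all_scores[-1] + 1.0]
    best = None
    for t in candidates:
        cs = evaluate_cutoff(scores, labels, t)
        j = (cs.sensitivity or 0.0) + (cs.specificity or 0.0) - 1.0
        key = (j, cs.specificity or 0.0)
        if best is None or key > best[0]:
            best = (key, t)
    t_best = best[1]
    # report midpoint between t_best and the next lower distinct score
    lower = all_scores[all_scores < t_best]
    if lower.size:
        cut = float((t_best + lower[-1]) / 2.0)
    else:
        cut = float(t_best)
    summary = evaluate_cutoff(scores, labels, cut)
    return cut, summary


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    sensitivity: float,
    one_minus_specificity: float,
) -> ConfusionSummary:
    """Integer confusion matrix implied by rounded printed rates.

    tp = round(sensitivity * n_pos) and fp = round((1-spec) * n_neg),
    rounding half-up; the remaining cells follow from the margins.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("margins must be >= 1")
    if not (0 <= sensitivity <= 1 and 0 <= one_minus_specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tp = int(round_half_up(sensitivity * n_pos))
    fp = int(round_half_up(one_minus_specificity * n_neg))
    if tp > n_pos or fp > n_neg:
        raise ValueError("rounded counts exceed the margins")
    return ConfusionSummary(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)


_RATE_FIELDS = ("sensitivity", "specificity", "ppv", "npv")


def enumerate_consistent_matrices(
    n_pos: int,
    n_neg: int,
    constraints: dict[str, float],
    decimals: int = 1,
) -> list[ConfusionSummary]:
    """All confusion matrices with the given margins matching rounded rates.

    ``constraints`` maps rate names (sensitivity/specificity/ppv/npv) to
    target percentages as printed (e.g. ``{"ppv": 77.8, "npv": 83.3}``); a
    matrix matches when every constrained rate, expressed in percent and
    rounded half-up to ``decimals``, equals its target.  Undefined rates
    never match.  May return an empty list.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("margins must be >= 1")
    unknown = set(constraints) - set(_RATE_FIELDS)
    if unknown:
        raise ValueError(f"unknown rate name(s): {sorted(unknown)}")
    out = []
    for tp in range(n_pos + 1):
        for fp in range(n_neg + 1):
            cs = ConfusionSummary(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)
            ok = True
            for name, target in constraints.items():
                rate = getattr(cs, name)
                if rate is None or round_half_up(100.0 * rate, decimals) != round_half_up(
                    float(target), decimals
                ):
                    ok = False
                    break
            if ok:
                out.append(cs)
    return out
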