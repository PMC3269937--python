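"""Set-overlap metrics, pooled break-even point, correlation and paired
Wilcoxon comparison of runs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import GnbenchError, GoldStandard, SourceRun

__all__ = [
    "OverlapCounts",
    "overlap_counts",
    "precision_recall_f1",
    "breakeven_point",
    "pearson_correlation",
    "wilcoxon_compare",
    "WilcoxonOutcome",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Counts comparing a predicted positive set with a reference set."""

    n_gold: int
    n_pred: int
    n_overlap: int

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_gold, self.n_pred):
            raise GnbenchError(
                f"overlap {self.n_overlap} exceeds min({self.n_gold}, {self.n_pred})"
            )
        if min(self.n_gold, self.n_pred, self.n_overlap) < 0:
            raise GnbenchError("counts must be non-negative")


def overlap_counts(gold: GoldStandard, pred: GoldStandard) -> OverlapCounts:
    """Overlap of two per-document annotation sets as (document, identifier)
    pairs."""
    g, p = gold.pairs(), pred.pairs()
    return OverlapCounts(len(g), len(p), len(g & p))


def precision_recall_f1(counts: OverlapCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from overlap counts; 0/0 ratios are 0."""
    precision = counts.n_overlap / counts.n_pred if counts.n_pred else 0.0
    recall = counts.n_overlap / counts.n_gold if counts.n_gold else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def breakeven_point(run: SourceRun, gold: GoldStandard) -> float:
    """Precision at the pooled rank equal to the number of gold positives
    (R-precision), where precision and recall coincide.

    All predictions are pooled across documents and ordered by descending
    confidence (ties broken by document, submitted rank, identifier).  With
    R gold positives in total, precision at pooled rank R equals recall
    there, giving a single threshold-free operating point.  If the run
    returns fewer than R predictions, the value is TP / R.
    """
    total_gold = gold.n_positives()
    if total_gold == 0:
        raise GnbenchError("gold standard has no positive annotations")
    pooled = [
        (-p.confidence, doc, p.rank, p.identifier)
        for doc, preds in run.predictions.items()
        for p in preds
    ]
    pooled.sort()
    top = pooled[:total_gold]
    tp = sum(
        1
        for _negconf, doc, _rank, ident in top
        if ident in gold.annotations.get(doc, set())
    )
    return tp / total_gold


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 2:
        raise GnbenchError("vectors must have equal length >= 2")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise GnbenchError("correlation undefined for a constant vector")
    return float(np.corrcoef(xs, ys)[0, 1])


@dataclass
class WilcoxonOutcome:
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool  # all paired differences were zero


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonOutcome:
    """Two-sided Wilcoxon signed-rank test on paired per-query scores.

    Zero differences are dropped; with n non-zero pairs the null is exact
    for n <= ``exact_max_n`` (ties permitting), otherwise a normal
    approximation with continuity correction is used.  Identical vectors
    are a degenerate comparison reported with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise GnbenchError("paired vectors must have identical length")
    diff = a - b
    nonzero = diff[diff != 0]
    n = nonzero.size
    if n == 0:
        return WilcoxonOutcome(0.0, 1.0, 0, True)
    method = "exact" if n <= exact_max_n else "approx"
    try:
        res = sps.wilcoxon(
            nonzero, zero_method="wilcox", correction=(method == "approx"),
            alternative="two-sided", method=method,
        )
    except ValueError:
        res = sps.wilcoxon(
            nonzero, zero_method="wilcox", correction=True,
            alternative="two-sided", method="approx",
        )
    return WilcoxonOutcome(float(res.statistic), float(res.pvalue), n, False)
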