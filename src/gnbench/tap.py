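"""Threshold Average Precision (TAP-k) for ranked, confidence-scored retrieval.

Plain average precision ignores the confidence scores a system attaches to
its predictions, and rewards burying extra guesses deep in the list.  TAP-k
instead fixes a global score cutoff x — the largest score at which the
median number of false-positive retrievals per query reaches k, modelling a
curator who stops reading after about k errors — and scores each query by
average precision *with cutoff and terminal penalty*:

    APC_x  = (1/P) * sum of precision at each rank holding a true positive
             with score >= x
    P_x    = precision at the last rank with score >= x
    APCP_x = (P * APC_x + P_x) / (P + 1)

where P is the number of gold positives for the query.  The terminal factor
P_x penalises a cutoff chosen below the last true positive: retrieving a
tail of pure false positives lowers P_x even though APC_x is unchanged.
TAP-k is the mean of APCP_x over queries.  It depends on confidences only
through their order, so any strictly increasing rescaling leaves it fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GnbenchError, GoldStandard, Prediction, SourceRun

__all__ = [
    "RETRIEVE_ALL",
    "QueryEval",
    "TapResult",
    "average_precision",
    "apcp_at_threshold",
    "select_threshold_for_k",
    "tap_k_score",
    "DEFAULT_K",
]

#: Sentinel cutoff meaning "retrieve everything" (no candidate score reaches
#: a median of k false positives).
RETRIEVE_ALL = -math.inf

DEFAULT_K = (5, 10, 20)


@dataclass
class QueryEval:
    """Per-query TAP components at a fixed cutoff."""

    document_id: str
    P: int
    apc: float
    terminal_precision: float
    apcp: float
    n_false_positives_at_x: int


@dataclass
class TapResult:
    k: int
    threshold_x: float
    per_query: list[QueryEval]
    tap: float


def average_precision(ranked: Sequence[Prediction], gold: set[str]) -> float:
    """Uncut average precision: mean over gold items of precision at the
    rank retrieving them (0 contribution for gold items never retrieved)."""
    if not gold:
        raise GnbenchError("average_precision requires a non-empty gold set")
    tp = 0
    total = 0.0
    for rank, pred in enumerate(ranked, start=1):
        if pred.identifier in gold:
            tp += 1
            total += tp / rank
    return total / len(gold)


def apcp_at_threshold(
    ranked: Sequence[Prediction], gold: set[str], x: float, document_id: str = ""
) -> QueryEval:
    """Evaluate one query at score cutoff ``x`` (``RETRIEVE_ALL`` keeps all).

    For a query with no gold positives, APCP is 1 when nothing is retrieved
    at the cutoff and 0 otherwise: a system is rewarded for abstaining on
    documents that have no correct identifiers.
    """
    P = len(gold)
    retrieved = [p for p in ranked if p.confidence >= x]
    if P == 0:
        apcp = 1.0 if not retrieved else 0.0
        return QueryEval(document_id, 0, 0.0, 0.0, apcp, len(retrieved))
    tp = 0
    apc_sum = 0.0
    for rank, pred in enumerate(retrieved, start=1):
        if pred.identifier in gold:
            tp += 1
            apc_sum += tp / rank
    apc = apc_sum / P
    p_x = tp / len(retrieved) if retrieved else 0.0
    apcp = (P * apc + p_x) / (P + 1)
    return QueryEval(document_id, P, apc, p_x, apcp, len(retrieved) - tp)


def _fp_confidences(run: SourceRun, gold: GoldStandard) -> list[np.ndarray]:
    """Per gold document, the sorted (ascending) confidences of its false
    positives; documents missing from the run contribute an empty array."""
    out = []
    for doc in sorted(gold.annotations):
        gold_ids = gold.annotations[doc]
        preds = run.predictions.get(doc, [])
        confs = np.sort([p.confidence for p in preds if p.identifier not in gold_ids])
        out.append(confs)
    return out


def select_threshold_for_k(run: SourceRun, gold: GoldStandard, k: int) -> float:
    """Largest score x at which the median per-query false-positive count
    reaches k; ``RETRIEVE_ALL`` if no submitted score does.

    Candidate cutoffs are the submitted confidences themselves (between two
    adjacent submitted scores the retrieval sets, hence the medians, do not
    change).  The median over an even number of queries is the mean of the
    two central values.
    """
    if k < 1:
        raise GnbenchError(f"k must be >= 1, got {k}")
    if not gold.annotations:
        raise GnbenchError("gold standard has no documents")
    if run.n_predictions() == 0:
        return RETRIEVE_ALL
    fp_confs = _fp_confidences(run, gold)
    candidates = sorted(
        {p.confidence for preds in run.predictions.values() for p in preds},
        reverse=True,
    )
    for x in candidates:
        counts = [len(c) - np.searchsorted(c, x, side="left") for c in fp_confs]
        if float(np.median(counts)) >= k:
            return x
    return RETRIEVE_ALL


def tap_k_score(
    run: SourceRun,
    gold: GoldStandard,
    k: int,
    include_unannotated: bool = True,
) -> TapResult:
    """TAP-k of a run against a gold standard.

    Every gold document is a query; documents the run never mentions are
    evaluated on an empty list.  ``include_unannotated=False`` drops queries
    with zero gold positives from the average instead of applying the
    abstention rule.
    """
    if not gold.annotations:
        raise GnbenchError("gold standard has no documents")
    x = select_threshold_for_k(run, gold, k)
    per_query = []
    for doc in sorted(gold.annotations):
        gold_ids = gold.annotations[doc]
        if not gold_ids and not include_unannotated:
            continue
        qe = apcp_at_threshold(run.predictions.get(doc, []), gold_ids, x, doc)
        per_query.append(qe)
    if not per_query:
        raise GnbenchError("no queries left to average")
    tap = float(np.mean([q.apcp for q in per_query]))
    return TapResult(k, x, per_query, tap)
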