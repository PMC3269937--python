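"""Shared fixtures and the independent brute-force TAP oracle.

The oracle re-derives TAP-k directly from its definition with naive loops:
it enumerates every submitted confidence as a candidate cutoff, counts
false positives per query, takes the median, picks the largest cutoff whose
median reaches k, and recomputes every precision from scratch.  It shares
no code with the implementation under test.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest

from gnbench import GoldStandard, SourceRun, make_run


@pytest.fixture
def toy_gold() -> GoldStandard:
    return GoldStandard({"D1": {"G1", "G2"}, "D2": {"G3"}, "D3": set()})


@pytest.fixture
def toy_run() -> SourceRun:
    return make_run(
        "toy",
        {
            "D1": [("G1", 0.9), ("B1", 0.8), ("G2", 0.7)],
            "D2": [("B2", 0.95), ("G3", 0.5)],
        },
    )


def oracle_tap(run: SourceRun, gold: GoldStandard, k: int) -> tuple[float, float]:
    """(threshold, TAP-k) by exhaustive enumeration. -inf means retrieve all."""
    docs = sorted(gold.annotations)

    def fp_count(doc: str, x: float) -> int:
        gold_ids = gold.annotations[doc]
        return sum(
            1
            for p in run.predictions.get(doc, [])
            if p.confidence >= x and p.identifier not in gold_ids
        )

    candidates = sorted(
        {p.confidence for preds in run.predictions.values() for p in preds},
        reverse=True,
    )
    threshold = -math.inf
    for x in candidates:
        if statistics.median([fp_count(d, x) for d in docs]) >= k:
            threshold = x
            break

    apcps = []
    for doc in docs:
        gold_ids = gold.annotations[doc]
        retrieved = [
            p for p in run.predictions.get(doc, []) if p.confidence >= threshold
        ]
        P = len(gold_ids)
        if P == 0:
            apcps.append(1.0 if not retrieved else 0.0)
            continue
        tp = 0
        apc_sum = 0.0
        for rank, p in enumerate(retrieved, start=1):
            if p.identifier in gold_ids:
                tp += 1
                apc_sum += tp / rank
        apc = apc_sum / P
        p_x = tp / len(retrieved) if retrieved else 0.0
        apcps.append((P * apc + p_x) / (P + 1))
    return threshold, float(np.mean(apcps))


def random_instance(rng: np.random.Generator, max_docs: int = 3, max_preds: int = 5):
    """A small random (run, gold) pair for oracle cross-checks."""
    n_docs = int(rng.integers(1, max_docs + 1))
    idents = [f"G{i}" for i in range(6)]
    gold: dict[str, set[str]] = {}
    entries: dict[str, list[tuple[str, float]]] = {}
    for d in range(n_docs):
        doc = f"D{d}"
        gold[doc] = set(
            rng.choice(idents, size=int(rng.integers(0, 4)), replace=False).tolist()
        )
        n_preds = int(rng.integers(0, max_preds + 1))
        chosen = rng.choice(idents, size=n_preds, replace=False).tolist()
        # confidences from a tiny grid so cross-document ties are common
        confs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n_preds).tolist()
        if n_preds:
            entries[doc] = list(zip(chosen, confs))
    run = make_run("rand", entries)
    return run, GoldStandard(gold)
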