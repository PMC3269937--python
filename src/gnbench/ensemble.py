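"""Composite system combining several submissions with a linear classifier.

Every candidate (document, identifier) pair — the union of what the M
component runs returned for that document — becomes a feature vector: M
binary presence indicators, plus, when confidence stratification is on,
M x N one-hot indicators giving which of N per-source confidence bins the
returning source placed it in (low bin 0 ... high bin N-1).  Bins are
per-source pooled quantiles, because different systems' confidence scales
are not comparable.  A candidate found in the gold annotation of its
document is a positive training instance, otherwise negative.

An L2-regularized linear model with modified-Huber loss is trained under
leave-one-document-out cross-validation; its decision scores become the
confidences of a synthetic "composite" run, which can then be scored with
TAP-k like any submission (TAP only uses score order, so no calibration is
needed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import SGDClassifier

from .core import (
    GnbenchError,
    GoldStandard,
    LabelMatrix,
    LabelObject,
    SourceRun,
    build_label_matrix,
    make_run,
)
from .tap import DEFAULT_K, TapResult, tap_k_score

__all__ = [
    "EnsembleConfig",
    "CandidateFeatures",
    "CompositeRun",
    "stratify_confidences",
    "build_feature_matrix",
    "train_composite_classifier",
    "loocv_composite",
]


@dataclass
class EnsembleConfig:
    """Composite-system settings; feature dimension is M * (1 + n_strata)."""

    n_strata: int = 0
    regularization_strength: float = 1e-4
    seed: int = 0
    max_epochs: int = 200

    def __post_init__(self) -> None:
        if self.n_strata < 0:
            raise GnbenchError("n_strata must be >= 0")
        if self.regularization_strength <= 0:
            raise GnbenchError("regularization_strength must be positive")

    def n_features(self, m_sources: int) -> int:
        return m_sources * (1 + self.n_strata)


@dataclass
class CandidateFeatures:
    object: LabelObject
    vector: np.ndarray  # length M * (1 + N)
    label: int | None  # 1 / 0 when gold is available


@dataclass
class CompositeRun:
    run: SourceRun
    config: EnsembleConfig
    fold_weight_hashes: dict[str, str] = field(default_factory=dict)
    fallback_folds: list[str] = field(default_factory=list)


def stratify_confidences(run: SourceRun, n_strata: int) -> dict[tuple[str, str], int]:
    """Assign each of a run's predictions to one of ``n_strata`` confidence
    bins, pooling the run's confidences over all documents.

    Bin boundaries sit at the i/N quantiles; a value equal to a boundary
    falls in the lower bin.  Degenerate (constant) confidences all land in
    bin 0.
    """
    if n_strata < 1:
        raise GnbenchError("n_strata must be >= 1")
    confs = np.array(
        [p.confidence for preds in run.predictions.values() for p in preds]
    )
    if confs.size == 0:
        raise GnbenchError(f"run {run.run_id} has no predictions")
    boundaries = np.quantile(confs, [i / n_strata for i in range(1, n_strata)])
    out: dict[tuple[str, str], int] = {}
    for doc, preds in run.predictions.items():
        for p in preds:
            out[(doc, p.identifier)] = int(
                np.searchsorted(boundaries, p.confidence, side="left")
            )
    return out


def build_feature_matrix(
    runs: Sequence[SourceRun],
    candidates: LabelMatrix,
    config: EnsembleConfig,
    gold: GoldStandard | None = None,
) -> list[CandidateFeatures]:
    """One feature row per candidate object.

    For source i, column i is the presence bit and columns
    ``M + i*N ... M + (i+1)*N - 1`` are its one-hot stratum indicators
    (all zero when the source did not return the candidate).
    """
    if [r.run_id for r in runs] != candidates.sources:
        raise GnbenchError("runs do not match the candidate matrix's sources")
    m = len(runs)
    n = config.n_strata
    strata = [stratify_confidences(r, n) if n else None for r in runs]
    rows: list[CandidateFeatures] = []
    for j, obj in enumerate(candidates.objects):
        vec = np.zeros(config.n_features(m))
        for i in range(m):
            if candidates.delta[j, i]:
                vec[i] = 1.0
                if n:
                    s = strata[i].get((obj.document_id, obj.identifier))
                    if s is None:
                        raise GnbenchError(
                            f"candidate {obj} flagged for {runs[i].run_id} "
                            "but absent from its predictions"
                        )
                    vec[m + i * n + s] = 1.0
        label = None
        if gold is not None:
            label = int(obj.identifier in gold.annotations.get(obj.document_id, set()))
        rows.append(CandidateFeatures(obj, vec, label))
    return rows


def train_composite_classifier(
    features: Sequence[CandidateFeatures], config: EnsembleConfig
):
    """Fit the L2-regularized modified-Huber linear model; returns a scoring
    function mapping feature matrices to decision values (higher = more
    likely a correct identifier)."""
    labelled = [f for f in features if f.label is not None]
    if not labelled:
        raise GnbenchError("no labelled candidates to train on")
    y = np.array([f.label for f in labelled])
    if len(np.unique(y)) < 2:
        raise GnbenchError("training data contains a single class")
    X = np.vstack([f.vector for f in labelled])
    clf = SGDClassifier(
        loss="modified_huber",
        penalty="l2",
        alpha=config.regularization_strength,
        max_iter=config.max_epochs,
        tol=1e-6,
        random_state=config.seed,
    )
    clf.fit(X, y)

    def score(mat: np.ndarray) -> np.ndarray:
        return clf.decision_function(np.atleast_2d(mat))

    score.coef_ = clf.coef_.copy()
    score.intercept_ = clf.intercept_.copy()
    return score


def _weights_hash(score_fn) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(score_fn.coef_).tobytes())
    h.update(np.ascontiguousarray(score_fn.intercept_).tobytes())
    return h.hexdigest()


def loocv_composite(
    runs: Sequence[SourceRun],
    gold: GoldStandard,
    config: EnsembleConfig,
    k_values: Sequence[int] = DEFAULT_K,
) -> tuple[CompositeRun, dict[int, TapResult]]:
    """Leave-one-document-out composite: for each annotated document, train
    on every other document's candidates and score the held-out one.

    A fold whose training labels collapse to a single class falls back to
    scoring candidates by their presence-vote count; such folds are listed
    in the result.  The assembled composite run is TAP-scored against the
    same gold standard for each requested k.
    """
    docs = sorted(gold.annotations)
    if len(docs) < 2:
        raise GnbenchError("leave-one-out needs at least two annotated documents")
    candidates = build_label_matrix(list(runs), documents=set(docs))
    features = build_feature_matrix(runs, candidates, config, gold)
    by_doc: dict[str, list[CandidateFeatures]] = {d: [] for d in docs}
    for f in features:
        by_doc[f.object.document_id].append(f)
    m = len(runs)
    doc_entries: dict[str, list[tuple[str, float]]] = {}
    hashes: dict[str, str] = {}
    fallbacks: list[str] = []
    for held in docs:
        test_rows = by_doc[held]
        if not test_rows:
            continue
        train_rows = [f for d in docs if d != held for f in by_doc[d]]
        X_test = np.vstack([f.vector for f in test_rows])
        try:
            score_fn = train_composite_classifier(train_rows, config)
            scores = score_fn(X_test)
            hashes[held] = _weights_hash(score_fn)
        except GnbenchError:
            scores = X_test[:, :m].sum(axis=1)  # vote-count fallback
            fallbacks.append(held)
        doc_entries[held] = [
            (f.object.identifier, float(s)) for f, s in zip(test_rows, scores)
        ]
    composite = make_run("composite", doc_entries)
    taps = {int(k): tap_k_score(composite, gold, int(k)) for k in k_values}
    return CompositeRun(composite, config, hashes, fallbacks), taps
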