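"""Latent-class EM over multiple labelling sources (Hui–Walter / Dawid–Skene
family, two classes, one sensitivity and one specificity per source).

Each of M sources labels each of N (document, identifier) objects "true"
(it returned the identifier for that document) or "false".  Source i has an
unknown sensitivity ``as_i`` (probability of labelling a correct identifier
true) and specificity ``bs_i`` (probability of labelling an incorrect one
false).  Conditional on the object's unknown truth, labels are independent
across sources.  With a fixed prior probability ``pr`` that an object is
correct, EM alternates:

* M-step, Laplace-smoothed (equivalently the MAP update under a Beta(2,2)
  prior on each rate)::

      as_i = (sum_j delta_ij p_j + 1) / (sum_j p_j + 2)
      bs_i = (sum_j (1-delta_ij)(1-p_j) + 1) / (sum_j (1-p_j) + 2)

* E-step, Bayes' theorem with likelihood ratio accumulated in log space::

      p_j = pr A_j / (pr A_j + (1-pr) B_j),
      A_j = prod_i as_i^delta_ij (1-as_i)^(1-delta_ij)
      B_j = prod_i (1-bs_i)^delta_ij bs_i^(1-delta_ij)

starting from p_j = (fraction of the M labels that are true).  Objects with
p_j >= 0.5 at convergence form the consensus ("silver standard") annotation.
The per-object binary entropy of p_j, summed within a document, scores how
contentious the document is; repeatedly re-running the model on one randomly
chosen run per team and keeping the highest-average-entropy documents picks
the evaluation set on which sources disagree most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import GnbenchError, GoldStandard, LabelMatrix, SourceRun, build_label_matrix

__all__ = [
    "SourceProfile",
    "ConsensusResult",
    "SelectionResult",
    "initialize_probabilities",
    "m_step",
    "e_step",
    "penalized_log_posterior",
    "run_em",
    "extract_silver_standard",
    "label_entropy",
    "score_documents",
    "select_documents",
    "majority_vote",
]


@dataclass
class SourceProfile:
    """Estimated quality of one labelling source; Laplace smoothing keeps
    both rates strictly inside (0, 1)."""

    run_id: str
    sensitivity: float
    specificity: float


@dataclass
class ConsensusResult:
    p: np.ndarray
    profiles: list[SourceProfile]
    prior: float
    iterations: int
    converged: bool
    objective_trace: list[float]


@dataclass
class SelectionResult:
    doc_scores: dict[str, float]
    n_trials: int
    chosen: list[str]
    seed: int


def initialize_probabilities(matrix: LabelMatrix) -> np.ndarray:
    """p_j = fraction of the M labels for object j that are "true"."""
    return matrix.delta.mean(axis=1, dtype=float)


def m_step(matrix: LabelMatrix, p: np.ndarray) -> list[SourceProfile]:
    p = np.asarray(p, dtype=float)
    d = matrix.delta.astype(float)
    pos = p.sum()
    neg = (1.0 - p).sum()
    sens = (d.T @ p + 1.0) / (pos + 2.0)
    spec = ((1.0 - d).T @ (1.0 - p) + 1.0) / (neg + 2.0)
    return [
        SourceProfile(rid, float(a), float(b))
        for rid, a, b in zip(matrix.sources, sens, spec)
    ]


def _profile_arrays(profiles: Sequence[SourceProfile]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([pr.sensitivity for pr in profiles]),
        np.array([pr.specificity for pr in profiles]),
    )


def _log_likelihood_ratios(matrix: LabelMatrix, profiles: Sequence[SourceProfile]):
    """(log A_j, log B_j) for all objects, computed in log space."""
    a, b = _profile_arrays(profiles)
    d = matrix.delta.astype(float)
    log_a = d @ np.log(a) + (1.0 - d) @ np.log1p(-a)
    log_b = d @ np.log1p(-b) + (1.0 - d) @ np.log(b)
    return log_a, log_b


def e_step(matrix: LabelMatrix, profiles: Sequence[SourceProfile], prior: float) -> np.ndarray:
    if not 0.0 < prior < 1.0:
        raise GnbenchError(f"prior must lie in (0, 1), got {prior}")
    log_a, log_b = _log_likelihood_ratios(matrix, profiles)
    # p = sigmoid(logit(prior) + log A - log B), stable for extreme ratios
    z = np.log(prior) - np.log1p(-prior) + log_a - log_b
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def penalized_log_posterior(
    matrix: LabelMatrix, profiles: Sequence[SourceProfile], prior: float
) -> float:
    """Marginal log-likelihood plus the Beta(2,2) log-prior on each rate
    (the quantity EM with the smoothed M-step ascends)."""
    log_a, log_b = _log_likelihood_ratios(matrix, profiles)
    m = np.maximum(log_a, log_b)
    ll = np.sum(
        m + np.log(prior * np.exp(log_a - m) + (1.0 - prior) * np.exp(log_b - m))
    )
    a, b = _profile_arrays(profiles)
    penalty = np.sum(np.log(a) + np.log1p(-a) + np.log(b) + np.log1p(-b))
    return float(ll + penalty)


def run_em(
    matrix: LabelMatrix,
    prior: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ConsensusResult:
    """Alternate M- and E-steps until the largest per-object probability
    change drops below ``tol``.  Non-convergence warns and returns the last
    state rather than raising."""
    if not 0.0 < prior < 1.0:
        raise GnbenchError(f"prior must lie in (0, 1), got {prior}")
    p = initialize_probabilities(matrix)
    trace: list[float] = []
    converged = False
    iteration = 0
    profiles = m_step(matrix, p)
    for iteration in range(1, max_iter + 1):
        profiles = m_step(matrix, p)
        trace.append(penalized_log_posterior(matrix, profiles, prior))
        p_new = e_step(matrix, profiles, prior)
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", RuntimeWarning
        )
    return ConsensusResult(p, profiles, prior, iteration, converged, trace)


def extract_silver_standard(
    result: ConsensusResult, matrix: LabelMatrix, threshold: float = 0.5
) -> GoldStandard:
    """Consensus annotation: identifiers whose posterior probability reaches
    the threshold (boundary included).  Every document appearing in the
    matrix is present, possibly with an empty set."""
    if len(result.p) != matrix.n_objects:
        raise GnbenchError(
            f"consensus over {len(result.p)} objects does not align with "
            f"matrix of {matrix.n_objects}"
        )
    annotations: dict[str, set[str]] = {}
    for obj, pj in zip(matrix.objects, result.p):
        annotations.setdefault(obj.document_id, set())
        if pj >= threshold:
            annotations[obj.document_id].add(obj.identifier)
    return GoldStandard(annotations)


def majority_vote(matrix: LabelMatrix) -> GoldStandard:
    """Baseline consensus: accept objects returned by a strict majority of
    sources."""
    counts = matrix.delta.sum(axis=1)
    annotations: dict[str, set[str]] = {}
    for obj, c in zip(matrix.objects, counts):
        annotations.setdefault(obj.document_id, set())
        if 2 * int(c) > matrix.n_sources:
            annotations[obj.document_id].add(obj.identifier)
    return GoldStandard(annotations)


def label_entropy(p: float) -> float:
    """Binary entropy −p ln p − (1−p) ln(1−p) in nats, 0 at the endpoints."""
    if not 0.0 <= p <= 1.0:
        raise GnbenchError(f"probability outside [0, 1]: {p}")
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log(p) - (1.0 - p) * np.log(1.0 - p))


def score_documents(result: ConsensusResult, matrix: LabelMatrix) -> dict[str, float]:
    """Per-document sum of label entropies: high when the document carries
    many identifiers the sources disagree about."""
    if len(result.p) != matrix.n_objects:
        raise GnbenchError("consensus result does not align with matrix")
    p = np.clip(result.p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log1p(-p), 0.0
        )
    scores: dict[str, float] = {}
    for doc, idx in matrix.document_slices().items():
        scores[doc] = float(ent[idx].sum())
    return scores


def select_documents(
    team_runs: Mapping[str, Sequence[SourceRun]],
    n_docs: int = 50,
    n_trials: int = 100,
    prior: float = 0.5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SelectionResult:
    """Pick the documents most contested across teams.

    Each trial samples one run per team uniformly at random (teams visited
    in lexicographic order so the random stream is reproducible), runs EM
    over the pooled label matrix and scores every document by its entropy
    sum.  Scores are averaged over trials and the top ``n_docs`` documents
    are returned, ties broken lexicographically.
    """
    if not team_runs or any(not runs for runs in team_runs.values()):
        raise GnbenchError("every team needs at least one run")
    teams = sorted(team_runs)
    all_docs: set[str] = set()
    for runs in team_runs.values():
        for run in runs:
            all_docs |= run.documents
    if n_docs > len(all_docs):
        raise GnbenchError(
            f"cannot select {n_docs} documents from {len(all_docs)} available"
        )
    rng = np.random.default_rng(seed)
    totals: dict[str, float] = {doc: 0.0 for doc in all_docs}
    for _ in range(n_trials):
        chosen_runs = [
            team_runs[t][int(rng.integers(len(team_runs[t])))] for t in teams
        ]
        matrix = build_label_matrix(chosen_runs)
        result = run_em(matrix, prior=prior, tol=tol, max_iter=max_iter)
        for doc, s in score_documents(result, matrix).items():
            totals[doc] += s
    doc_scores = {doc: total / n_trials for doc, total in totals.items()}
    ranked = sorted(doc_scores, key=lambda d: (-doc_scores[d], d))
    return SelectionResult(doc_scores, n_trials, ranked[:n_docs], seed)
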