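"""Core domain types: submission runs, gold standards and label matrices.

A benchmark *run* is one system submission: for every document it returns a
ranked list of database identifiers, each with a confidence score (higher =
more confident).  A *gold standard* maps documents to the set of identifiers
a human curator marked correct.  For consensus inference each run is treated
as an imperfect binary labeller of (document, identifier) objects, and the
labels of M runs over N objects form a binary N x M *label matrix*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GnbenchError",
    "FormatError",
    "Prediction",
    "SourceRun",
    "GoldStandard",
    "LabelObject",
    "LabelMatrix",
    "build_label_matrix",
]


class GnbenchError(Exception):
    """Base class for domain errors (bad data, inconsistent inputs)."""


class FormatError(GnbenchError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}: "
        if line is not None:
            loc += f"line {line}: "
        super().__init__(loc + message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class Prediction:
    """One returned identifier: rank (1-based) and confidence score."""

    identifier: str
    rank: int
    confidence: float

    def __post_init__(self) -> None:
        if not self.identifier:
            raise GnbenchError("empty identifier")
        if self.rank < 1:
            raise GnbenchError(f"rank must be a positive integer, got {self.rank}")
        if not np.isfinite(self.confidence):
            raise GnbenchError(f"confidence must be finite, got {self.confidence}")


@dataclass
class SourceRun:
    """One submission run: per-document ranked identifier lists.

    Invariants (checked by :meth:`validate`):

    * within a document, ranks are 1, 2, 3, ... with no gaps;
    * no (document, identifier) pair appears twice;
    * rank order agrees with non-increasing confidence.
    """

    run_id: str
    predictions: dict[str, list[Prediction]] = field(default_factory=dict)

    def validate(self) -> "SourceRun":
        for doc, preds in self.predictions.items():
            seen: set[str] = set()
            prev_conf = np.inf
            for pos, p in enumerate(preds, start=1):
                if p.rank != pos:
                    raise GnbenchError(
                        f"run {self.run_id}, document {doc}: expected rank {pos}, got {p.rank}"
                    )
                if p.identifier in seen:
                    raise GnbenchError(
                        f"run {self.run_id}, document {doc}: duplicate identifier {p.identifier}"
                    )
                seen.add(p.identifier)
                if p.confidence > prev_conf:
                    raise GnbenchError(
                        f"run {self.run_id}, document {doc}: confidence increases at rank {p.rank}"
                    )
                prev_conf = p.confidence
        return self

    @property
    def documents(self) -> set[str]:
        return set(self.predictions)

    def n_predictions(self) -> int:
        return sum(len(v) for v in self.predictions.values())

    def pairs(self) -> set[tuple[str, str]]:
        """All (document, identifier) pairs returned by this run."""
        return {
            (doc, p.identifier)
            for doc, preds in self.predictions.items()
            for p in preds
        }

    def transform_confidences(self, fn) -> "SourceRun":
        """Apply a monotone transform to every confidence, keeping ranks."""
        out: dict[str, list[Prediction]] = {}
        for doc, preds in self.predictions.items():
            out[doc] = [
                Prediction(p.identifier, p.rank, float(fn(p.confidence))) for p in preds
            ]
        return SourceRun(self.run_id, out)


def canonical_order(entries: Iterable[tuple[str, int, float]]) -> list[tuple[str, int, float]]:
    """Sort (identifier, submitted_rank, confidence) triples canonically.

    Descending confidence; ties broken by submitted rank, then identifier, so
    downstream results are bit-reproducible.
    """
    return sorted(entries, key=lambda t: (-t[2], t[1], t[0]))


def make_run(run_id: str, doc_entries: Mapping[str, Sequence[tuple[str, float]]]) -> SourceRun:
    """Build a valid run from per-document (identifier, confidence) pairs."""
    preds: dict[str, list[Prediction]] = {}
    for doc, entries in doc_entries.items():
        triples = canonical_order(
            [(ident, i + 1, conf) for i, (ident, conf) in enumerate(entries)]
        )
        preds[doc] = [
            Prediction(ident, pos, conf)
            for pos, (ident, _r, conf) in enumerate(triples, start=1)
        ]
    return SourceRun(run_id, preds).validate()


@dataclass
class GoldStandard:
    """Per-document sets of correct identifiers; empty sets are meaningful
    (a document may legitimately have no annotated genes)."""

    annotations: dict[str, set[str]] = field(default_factory=dict)

    @property
    def documents(self) -> set[str]:
        return set(self.annotations)

    def n_positives(self) -> int:
        return sum(len(v) for v in self.annotations.values())

    def pairs(self) -> set[tuple[str, str]]:
        return {
            (doc, ident)
            for doc, idents in self.annotations.items()
            for ident in idents
        }


@dataclass(frozen=True, order=True)
class LabelObject:
    """A single (document, identifier) pair to be labelled true or false."""

    document_id: str
    identifier: str


@dataclass
class LabelMatrix:
    """Binary labels of N objects by M sources.

    ``delta[j, i]`` is 1 iff source i returned object j.  Objects are the
    union of all pairs returned by the sources, sorted lexicographically by
    (document, identifier); sources keep their input order.
    """

    objects: list[LabelObject]
    sources: list[str]
    delta: np.ndarray  # shape (N, M), dtype uint8

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.uint8)
        n, m = self.delta.shape
        if n != len(self.objects) or m != len(self.sources):
            raise GnbenchError(
                f"delta shape {self.delta.shape} does not match "
                f"{len(self.objects)} objects x {len(self.sources)} sources"
            )
        if not np.isin(self.delta, (0, 1)).all():
            raise GnbenchError("label matrix entries must be 0 or 1")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def density(self) -> float:
        return float(self.delta.mean()) if self.delta.size else 0.0

    def document_slices(self) -> dict[str, np.ndarray]:
        """Object indices grouped by document (objects are doc-sorted)."""
        out: dict[str, list[int]] = {}
        for j, obj in enumerate(self.objects):
            out.setdefault(obj.document_id, []).append(j)
        return {doc: np.asarray(ix) for doc, ix in out.items()}


def build_label_matrix(
    runs: Sequence[SourceRun],
    documents: set[str] | None = None,
) -> LabelMatrix:
    """Construct the label matrix whose objects are the union of all pairs
    returned by *runs*, optionally restricted to *documents*."""
    if not runs:
        raise GnbenchError("at least one run is required")
    pair_set: set[tuple[str, str]] = set()
    for run in runs:
        for pair in run.pairs():
            if documents is None or pair[0] in documents:
                pair_set.add(pair)
    if not pair_set:
        raise GnbenchError("no (document, identifier) objects after restriction")
    objects = [LabelObject(d, g) for d, g in sorted(pair_set)]
    index = {(o.document_id, o.identifier): j for j, o in enumerate(objects)}
    delta = np.zeros((len(objects), len(runs)), dtype=np.uint8)
    for i, run in enumerate(runs):
        for pair in run.pairs():
            j = index.get(pair)
            if j is not None:
                delta[j, i] = 1
    return LabelMatrix(objects, [r.run_id for r in runs], delta)
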