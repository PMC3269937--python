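"""Readers and writers for submission and gold-standard files.

Dialect: UTF-8 tab-separated text, no header; lines starting with ``#`` are
comments.  Submission lines are ``document_id<TAB>identifier<TAB>rank<TAB>
confidence``; gold lines are ``document_id<TAB>identifier``, and a document
id alone on a line declares a document with no annotated identifiers.

This dialect is a stand-in for whatever syntax a particular challenge used;
adapters can convert other layouts into it.
"""

from __future__ import annotations

import math
from pathlib import Path

from .core import (
    FormatError,
    GnbenchError,
    GoldStandard,
    Prediction,
    SourceRun,
    canonical_order,
)

__all__ = ["read_submission", "write_submission", "read_gold", "write_gold"]


def _lines(path: str | Path):
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise GnbenchError(f"cannot read {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        yield lineno, raw


def read_submission(path: str | Path, strict: bool = False, run_id: str | None = None) -> SourceRun:
    """Parse a submission file into a :class:`SourceRun`.

    In strict mode duplicate (document, identifier) pairs and rank gaps are
    errors.  Otherwise duplicates are collapsed keeping the highest
    confidence, and ranks are renumbered canonically (descending confidence,
    ties broken by submitted rank then identifier).
    """
    name = run_id if run_id is not None else Path(path).stem
    # doc -> identifier -> (submitted_rank, confidence)
    by_doc: dict[str, dict[str, tuple[int, float]]] = {}
    last_rank: dict[str, tuple[int, int]] = {}  # doc -> (last rank, lineno)
    for lineno, raw in _lines(path):
        parts = raw.split("\t")
        if len(parts) != 4:
            raise FormatError(
                f"expected 4 tab-separated fields, got {len(parts)}", str(path), lineno
            )
        doc, ident, rank_s, conf_s = (p.strip() for p in parts)
        if not doc or not ident:
            raise FormatError("empty document or identifier field", str(path), lineno)
        try:
            rank = int(rank_s)
        except ValueError:
            raise FormatError(f"non-integer rank {rank_s!r}", str(path), lineno) from None
        try:
            conf = float(conf_s)
        except ValueError:
            raise FormatError(f"non-numeric confidence {conf_s!r}", str(path), lineno) from None
        if rank < 1:
            raise FormatError(f"rank must be >= 1, got {rank}", str(path), lineno)
        if not math.isfinite(conf):
            raise FormatError(f"confidence must be finite, got {conf_s}", str(path), lineno)
        if strict:
            expected = last_rank.get(doc, (0, 0))[0] + 1
            if rank != expected:
                raise FormatError(
                    f"document {doc}: expected rank {expected}, got {rank}",
                    str(path),
                    lineno,
                )
            if ident in by_doc.get(doc, {}):
                raise FormatError(
                    f"duplicate pair ({doc}, {ident})", str(path), lineno
                )
        last_rank[doc] = (rank, lineno)
        entry = by_doc.setdefault(doc, {})
        if ident in entry:
            old_rank, old_conf = entry[ident]
            if conf > old_conf:
                entry[ident] = (rank, conf)
        else:
            entry[ident] = (rank, conf)

    preds: dict[str, list[Prediction]] = {}
    for doc, entry in by_doc.items():
        triples = canonical_order(
            [(ident, rank, conf) for ident, (rank, conf) in entry.items()]
        )
        preds[doc] = [
            Prediction(ident, pos, conf)
            for pos, (ident, _r, conf) in enumerate(triples, start=1)
        ]
    return SourceRun(name, preds).validate()


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e16 else repr(float(x))


def write_submission(run: SourceRun, path: str | Path) -> None:
    """Write a run in the canonical dialect (sorted documents, rank order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in sorted(run.predictions):
            for p in run.predictions[doc]:
                fh.write(f"{doc}\t{p.identifier}\t{p.rank}\t{_fmt(p.confidence)}\n")


def read_gold(path: str | Path) -> GoldStandard:
    """Parse a gold-standard file; duplicate lines collapse silently."""
    annotations: dict[str, set[str]] = {}
    for lineno, raw in _lines(path):
        parts = [p.strip() for p in raw.split("\t")]
        if len(parts) == 1:
            doc = parts[0]
            if not doc:
                raise FormatError("empty document id", str(path), lineno)
            annotations.setdefault(doc, set())
        elif len(parts) == 2:
            doc, ident = parts
            if not doc:
                raise FormatError("empty document id", str(path), lineno)
            if not ident:
                raise FormatError("empty identifier token", str(path), lineno)
            annotations.setdefault(doc, set()).add(ident)
        else:
            raise FormatError(
                f"expected 1 or 2 tab-separated fields, got {len(parts)}",
                str(path),
                lineno,
            )
    return GoldStandard(annotations)


def write_gold(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in sorted(gold.annotations):
            idents = gold.annotations[doc]
            if not idents:
                fh.write(f"{doc}\n")
            for ident in sorted(idents):
                fh.write(f"{doc}\t{ident}\n")
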