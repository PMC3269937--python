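"""Packaged transcriptions of the benchmark's printed run-level score tables.

Three tables ship with the package, keyed ``T3``, ``T4`` and ``T5``:

* ``T3`` — TAP-k of the 36 printed runs against the 50-article gold standard;
* ``T4`` — the same runs against the EM-derived silver standard, both on the
  50 selected articles and on all 507 test articles;
* ``T5`` — the combined (composite) classifier experiments next to the best
  single-run result.

Values are transcribed at 4 decimal places exactly as printed and pinned by
sha256 checksums in a manifest, so any accidental edit fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import GnbenchError

__all__ = ["ScoreTableFixture", "load_fixture_table", "verify_manifest", "TABLE_IDS"]

_FILES = {"T3": "table3.tsv", "T4": "table4.tsv", "T5": "table5.tsv"}
TABLE_IDS = tuple(_FILES)


@dataclass
class ScoreTableFixture:
    """One transcribed score table as a DataFrame indexed by run/system label."""

    table_id: str
    rows: pd.DataFrame

    def value(self, row: str, column: str) -> float:
        try:
            return float(self.rows.loc[row, column])
        except KeyError as exc:
            raise GnbenchError(f"{self.table_id}: no cell ({row}, {column})") from exc


def _read_bytes(fname: str) -> bytes:
    return (resources.files("gnbench") / "data" / fname).read_bytes()


def load_fixture_table(table_id: str) -> ScoreTableFixture:
    if table_id not in _FILES:
        raise GnbenchError(
            f"unknown fixture table {table_id!r}; expected one of {sorted(_FILES)}"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(_read_bytes(_FILES[table_id])), sep="\t", index_col=0)
    return ScoreTableFixture(table_id, df)


def verify_manifest() -> dict[str, bool]:
    """Check every packaged table against its pinned checksum and shape."""
    manifest = json.loads((resources.files("gnbench") / "data" / "manifest.json").read_text())
    ok: dict[str, bool] = {}
    for tid, fname in _FILES.items():
        key = fname.rsplit(".", 1)[0]
        raw = _read_bytes(fname)
        entry = manifest[key]
        fix = load_fixture_table(tid)
        ok[tid] = (
            hashlib.sha256(raw).hexdigest() == entry["sha256"]
            and len(fix.rows) == entry["rows"]
            and len(fix.rows.columns) + 1 == entry["cols"]
        )
    return ok
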