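"""Unblinding and results export.

After scoring, the blinded-ID-keyed notes are joined back to segment
labels and source file names, producing one row per segment with one
column per stage.  Rows are sorted by source file, then by label in
natural well order (letter, then numeric value), so ``A2`` precedes
``A10``.  ``results.csv`` is the canonical, diffable output;
``results.xlsx`` is written alongside with identical cell content.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from blindcut.errors import IncompleteSessionError
from blindcut.session import Session

#: cell marker for unscored segments in a partial export
PENDING = "(pending)"

_LABEL_SPLIT = re.compile(r"^([A-Z]+)(\d+)$")


def label_sort_key(label: str) -> tuple[str, int]:
    """Natural well order: letter part, then numeric value (A2 < A10)."""
    m = _LABEL_SPLIT.match(label)
    if not m:
        return (label, 0)
    return (m.group(1), int(m.group(2)))


def unblind(session: Session, partial: bool = False) -> pd.DataFrame:
    """Join scores back to labels and sources into a results table.

    Requires a complete session unless ``partial=True``, in which case
    unscored segments appear with ``(pending)`` in every stage column.
    Columns: ``label``, ``source_file``, then the stages in definition
    order.  Exactly one row per segment.
    """
    if not session.complete and not partial:
        raise IncompleteSessionError(
            f"session has {session.cursor} of {session.n} segments scored; "
            "export requires completion (or an explicit partial export)"
        )
    rows = []
    for seg, bid in zip(session.segments, session.blinded_ids):
        rec = session.scores.get(bid)
        row = {"label": seg.label, "source_file": seg.source.source_name}
        for stage in session.stage_names:
            row[stage] = rec.notes[stage] if rec is not None else PENDING
        rows.append(row)
    table = pd.DataFrame(rows, columns=["label", "source_file", *session.stage_names])
    table = table.sort_values(
        by=["source_file", "label"],
        key=lambda col: col.map(label_sort_key) if col.name == "label" else col,
        kind="stable",
    ).reset_index(drop=True)
    return table


def write_results(table: pd.DataFrame, out_dir: Path | str) -> tuple[Path, Path]:
    """Write ``results.csv`` and ``results.xlsx`` with identical content.

    The CSV is UTF-8 with a header row (``label, source_file, <stages>``)
    and RFC-4180 quoting, so notes containing commas, quotes or newlines
    round-trip.  Returns the two written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    xlsx_path = out_dir / "results.xlsx"
    table.to_csv(csv_path, index=False, encoding="utf-8")
    table.to_excel(xlsx_path, index=False, engine="openpyxl")
    return csv_path, xlsx_path


def read_results_csv(csv_path: Path | str) -> pd.DataFrame:
    """Re-read a results CSV exactly (all cells as strings, '' not NaN)."""
    return pd.read_csv(csv_path, dtype=str, keep_default_na=False)


def read_results_xlsx(xlsx_path: Path | str) -> pd.DataFrame:
    """Read back the XLSX with all cells as strings ('' for empty)."""
    table = pd.read_excel(xlsx_path, dtype=str, engine="openpyxl")
    return table.fillna("")
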