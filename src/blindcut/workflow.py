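"""End-to-end pipeline steps behind the command-line interface.

A results folder is the unit of persistence::

    results_dir/
      session.json    # full session state (contains the unblinding key —
                      # not to be opened until scoring is complete)
      blind/          # cropped segment media, named by blinded ID only
        S001.avi ...
      results.csv     # written by export, after unblinding
      results.xlsx

``run_segmentation`` validates everything before writing anything, crops
every segment, shuffles once, and writes the blinded media.  Re-running
it on an existing session folder is refused: the random order is fixed
at creation and never regenerated.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from blindcut import media as media_io
from blindcut import reporting, segmentation
from blindcut.errors import ConfigError, SequencingError
from blindcut.session import (
    BLIND_DIRNAME,
    STATE_FILENAME,
    Session,
    create_session,
    next_segment,
    record_score,
    resume_session,
)


def run_segmentation(
    config: Sequence[tuple[str, Sequence[tuple[str, segmentation.Rect]]]],
    stage_names: Sequence[str],
    results_dir: Path | str,
    seed: Optional[int] = None,
) -> Session:
    """Crop all configured segments and open a new blinded session.

    Validates every label and rectangle (and the single-media-type rule)
    before any file is written; any failure aborts cleanly.  The shuffle
    happens here, exactly once.
    """
    results_dir = Path(results_dir)
    state_path = results_dir / STATE_FILENAME
    if state_path.exists():
        raise ConfigError(
            f"{results_dir} already holds a session; refusing to re-segment "
            "(the existing random order would be lost)"
        )
    segments = segmentation.build_segments(config)
    session = create_session(segments, stage_names, seed=seed)

    blind_dir = results_dir / BLIND_DIRNAME
    blind_dir.mkdir(parents=True, exist_ok=True)
    for seg, bid in zip(session.segments, session.blinded_ids):
        frames = segmentation.crop_segment(seg)
        out = blind_dir / f"{bid}{seg.source.extension}"
        fps = seg.source.fps if seg.source.media_type == "video" else None
        media_io.write_segment(frames, out, fps=fps)
    session.save(state_path)
    return session


def review_one(session: Session, notes: Mapping[str, str]) -> Optional[str]:
    """Score the current segment; returns its blinded ID, or ``None`` if
    the session was already complete."""
    item = next_segment(session)
    if item is None:
        return None
    record_score(session, item.blinded_id, notes)
    return item.blinded_id


def review_batch(session: Session, rows: Sequence[Mapping[str, str]]) -> int:
    """Ingest scores non-interactively, enforcing presentation order.

    Each row must carry ``blinded_id`` plus one entry per stage, and the
    rows must follow the randomized order starting at the session's
    current position.  Returns the number of segments scored.
    """
    scored = 0
    for row in rows:
        bid = row.get("blinded_id", "")
        if bid not in session.blinded_ids:
            raise SequencingError(f"unknown blinded ID {bid!r} in scores input")
        notes = {s: row.get(s, "") for s in session.stage_names}
        missing = [s for s in session.stage_names if s not in row]
        if missing:
            raise ValueError(f"scores row for {bid} missing stage(s): {missing}")
        record_score(session, bid, notes)
        scored += 1
    return scored


def load_scores_csv(path: Path | str) -> list[dict[str, str]]:
    """Read a batch-scoring CSV (columns: blinded_id, then stage names)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "blinded_id" not in reader.fieldnames:
            raise ConfigError(f"scores CSV {path} needs a 'blinded_id' column")
        return [dict(row) for row in reader]


def export_results(
    results_dir: Path | str, partial: bool = False
) -> tuple[pd.DataFrame, Path, Path]:
    """Unblind a session folder and write results.csv / results.xlsx."""
    results_dir = Path(results_dir)
    session = resume_session(results_dir / STATE_FILENAME)
    table = reporting.unblind(session, partial=partial)
    csv_path, xlsx_path = reporting.write_results(table, results_dir)
    return table, csv_path, xlsx_path
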