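"""Randomized, resumable, blinded scoring sessions.

The pooled segments are shuffled once, with an explicit Fisher–Yates
pass, when the session is created — only after every source has been
segmented.  Each segment receives a blinded ID (``S001`` …) assigned in
*shuffled* order, so an ID encodes the segment's presentation rank and
nothing else; the label ↔ ID mapping lives only in the session state
file, which the review workflow never prints.  Blinded IDs always carry
at least one leading zero in their numeric part, which — because labels
never contain leading zeros — guarantees no label can occur as a
substring of any ID.

All state (segments, permutation, IDs, scores, progress) is persisted as
a single JSON document and rewritten atomically after every recorded
score, so scoring can be interrupted and resumed at any point without
re-randomization.  A state file whose permutation or score count fails
validation is refused outright: a session is never silently reshuffled.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import random
import secrets
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from blindcut.errors import (
    BlindingError,
    SequencingError,
    SessionLoadError,
)
from blindcut.segmentation import SegmentSpec

SCHEMA_VERSION = 1
STATE_FILENAME = "session.json"
BLIND_DIRNAME = "blind"


def fisher_yates_shuffle(n: int, rng: Union[int, random.Random, None]) -> list[int]:
    """Produce a uniformly random permutation of ``0..n-1``.

    The classic backward pass: for ``i`` from ``n-1`` down to ``1``,
    draw ``j`` uniformly from ``{0, ..., i}`` and swap positions ``i``
    and ``j``.  Every one of the ``n!`` permutations is equally likely,
    and the result is deterministic for a fixed seed.

    ``rng`` may be an integer seed, a ``random.Random`` instance, or
    ``None`` (OS entropy).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    perm = list(range(n))
    for i in range(n - 1, 0, -1):
        j = rng.randint(0, i)
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def blinded_id_format(n: int) -> str:
    """Zero-padded ID format wide enough that every ID keeps a leading
    zero after the ``S`` (labels have no leading zeros, so no label can
    then appear inside an ID)."""
    width = max(3, len(str(n)) + 1)
    return "S{:0" + str(width) + "d}"


def scan_for_leaks(text: str, labels: Sequence[str], source_names: Sequence[str]) -> list[str]:
    """Return every label or source-file name that occurs in ``text``.

    Used to assert that blinded artifacts (file names, review output)
    carry no identifying information.  Source names are checked both as
    full file names and as extension-less stems.
    """
    needles = set(labels)
    for name in source_names:
        needles.add(name)
        stem = Path(name).stem
        if stem:
            needles.add(stem)
    return sorted(n for n in needles if n and n in text)


@dataclass
class ScoreRecord:
    """Notes entered for one blinded segment, one entry per stage."""

    blinded_id: str
    notes: dict[str, str]
    completed_at: str = ""

    def to_dict(self) -> dict:
        return {
            "blinded_id": self.blinded_id,
            "notes": dict(self.notes),
            "completed_at": self.completed_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreRecord":
        return cls(d["blinded_id"], dict(d["notes"]), d.get("completed_at", ""))


@dataclass(frozen=True)
class BlindedItem:
    """What the reviewer is allowed to see for the current segment."""

    blinded_id: str
    media_path: Optional[Path]
    position: int  # 1-based rank in the randomized order
    total: int

    def describe(self) -> str:
        loc = f" media: {self.media_path}" if self.media_path else ""
        return f"segment {self.position} of {self.total} [{self.blinded_id}]{loc}"


@dataclass
class Session:
    """Persisted state of one blinded analysis.

    ``order[k]`` is the index (into ``segments``) of the segment shown
    at rank ``k``; ``blinded_ids[i]`` is the blinded ID of segment ``i``.
    ``order`` and ``blinded_ids`` are fixed at creation — resuming never
    reshuffles.
    """

    session_id: str
    stage_names: list[str]
    segments: list[SegmentSpec]
    order: list[int]
    blinded_ids: list[str]
    scores: dict[str, ScoreRecord] = field(default_factory=dict)
    cursor: int = 0
    seed: Optional[int] = None
    seed_source: str = "user"  # "user" | "entropy"
    state_path: Optional[Path] = None  # set when bound to a results folder

    # ---- derived --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.segments)

    @property
    def complete(self) -> bool:
        return self.cursor >= self.n

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    @property
    def source_names(self) -> list[str]:
        return sorted({s.source.source_name for s in self.segments})

    @property
    def media_dir(self) -> Optional[Path]:
        if self.state_path is None:
            return None
        return Path(self.state_path).parent / BLIND_DIRNAME

    def blind_media_path(self, blinded_id: str) -> Optional[Path]:
        if self.media_dir is None:
            return None
        ext = self.segments[0].source.extension
        return self.media_dir / f"{blinded_id}{ext}"

    def id_for_rank(self, rank: int) -> str:
        return self.blinded_ids[self.order[rank]]

    # ---- persistence ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "session_id": self.session_id,
            "stage_names": list(self.stage_names),
            "segments": [s.to_dict() for s in self.segments],
            "order": list(self.order),
            "blinded_ids": list(self.blinded_ids),
            "scores": {bid: r.to_dict() for bid, r in self.scores.items()},
            "cursor": self.cursor,
            "seed": self.seed,
            "seed_source": self.seed_source,
        }

    def save(self, state_path: Optional[Path] = None) -> Path:
        """Atomically persist state (write temp file, then rename)."""
        if state_path is not None:
            self.state_path = Path(state_path)
        if self.state_path is None:
            raise ValueError("session has no state path; pass one to save()")
        path = Path(self.state_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_name(path.name + f".tmp-{uuid.uuid4().hex[:8]}")
        tmp.write_text(json.dumps(self.to_dict(), indent=1))
        os.replace(tmp, path)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        try:
            if d.get("schema_version") != SCHEMA_VERSION:
                raise SessionLoadError(
                    f"unsupported session schema version {d.get('schema_version')!r}"
                )
            session = cls(
                session_id=d["session_id"],
                stage_names=list(d["stage_names"]),
                segments=[SegmentSpec.from_dict(s) for s in d["segments"]],
                order=[int(i) for i in d["order"]],
                blinded_ids=[str(b) for b in d["blinded_ids"]],
                scores={
                    bid: ScoreRecord.from_dict(r) for bid, r in d["scores"].items()
                },
                cursor=int(d["cursor"]),
                seed=d.get("seed"),
                seed_source=d.get("seed_source", "user"),
            )
        except SessionLoadError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise SessionLoadError(f"malformed session state: {exc}") from exc
        session.validate()
        return session

    def validate(self) -> None:
        """Check structural invariants; raise :class:`SessionLoadError`."""
        n = self.n
        if sorted(self.order) != list(range(n)):
            raise SessionLoadError("session order is not a permutation of its segments")
        if len(self.blinded_ids) != n or len(set(self.blinded_ids)) != n:
            raise SessionLoadError("blinded IDs are missing or not distinct")
        if not 0 <= self.cursor <= n:
            raise SessionLoadError(f"cursor {self.cursor} outside [0, {n}]")
        if len(self.scores) != self.cursor:
            raise SessionLoadError(
                f"score count {len(self.scores)} does not match cursor {self.cursor}"
            )
        expected = {self.id_for_rank(k) for k in range(self.cursor)}
        if set(self.scores) != expected:
            raise SessionLoadError("recorded scores do not match the presentation order")
        stage_set = list(self.stage_names)
        for rec in self.scores.values():
            if list(rec.notes.keys()) != stage_set and set(rec.notes) != set(stage_set):
                raise SessionLoadError(
                    f"score {rec.blinded_id} is missing stage notes"
                )
        labels = self.labels
        if len(set(labels)) != n:
            raise SessionLoadError("segment labels are not distinct")
        leaks = [
            bid
            for bid in self.blinded_ids
            if scan_for_leaks(bid, labels, self.source_names)
        ]
        if leaks:
            raise SessionLoadError(f"blinded IDs leak identifying strings: {leaks}")


def create_session(
    segments: Sequence[SegmentSpec],
    stage_names: Sequence[str],
    seed: Optional[int] = None,
) -> Session:
    """Shuffle the pooled segments once and open a fresh session.

    Blinded IDs are assigned in shuffled order (the ID's number is the
    presentation rank), so they reveal nothing about labels or sources.
    ``seed`` makes the shuffle reproducible; with ``seed=None`` a seed is
    drawn from OS entropy and recorded in the state for audit.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("cannot create a session with zero segments")
    stage_names = [str(s) for s in stage_names]
    if not stage_names:
        raise ValueError("cannot create a session with zero stages")
    if len(set(stage_names)) != len(stage_names):
        raise ValueError("stage names must be distinct")
    labels = [s.label for s in segments]
    if len(set(labels)) != len(labels):
        raise ValueError("segment labels must be distinct across the analysis")

    seed_source = "user"
    if seed is None:
        seed = secrets.randbits(31)
        seed_source = "entropy"
    order = fisher_yates_shuffle(len(segments), int(seed))

    fmt = blinded_id_format(len(segments))
    blinded_ids = [""] * len(segments)
    for rank, seg_index in enumerate(order):
        blinded_ids[seg_index] = fmt.format(rank + 1)

    source_names = sorted({s.source.source_name for s in segments})
    for bid in blinded_ids:
        leaks = scan_for_leaks(bid, labels, source_names)
        if leaks:
            raise BlindingError(
                f"blinded ID {bid!r} would contain identifying string(s) {leaks}"
            )

    return Session(
        session_id=uuid.uuid4().hex,
        stage_names=stage_names,
        segments=segments,
        order=order,
        blinded_ids=blinded_ids,
        seed=int(seed),
        seed_source=seed_source,
    )


def next_segment(session: Session) -> Optional[BlindedItem]:
    """Return the current blinded segment, or ``None`` when all scored.

    The returned bundle exposes only the blinded ID and the path of the
    blinded media copy — never the label or source file.
    """
    if session.cursor >= session.n:
        return None
    bid = session.id_for_rank(session.cursor)
    return BlindedItem(
        blinded_id=bid,
        media_path=session.blind_media_path(bid),
        position=session.cursor + 1,
        total=session.n,
    )


def record_score(
    session: Session, blinded_id: str, notes: Mapping[str, str]
) -> Session:
    """Store the notes for the current segment and advance the cursor.

    Scores must arrive in presentation order; state is persisted
    immediately (if the session is bound to a results folder) so a crash
    after this call loses nothing.
    """
    current = next_segment(session)
    if current is None:
        raise SequencingError("session is already complete")
    if blinded_id != current.blinded_id:
        raise SequencingError(
            f"segment {blinded_id!r} is not the current one "
            f"(expected {current.blinded_id!r})"
        )
    missing = [s for s in session.stage_names if s not in notes]
    if missing:
        raise ValueError(f"notes missing stage(s): {missing}")
    record = ScoreRecord(
        blinded_id=blinded_id,
        notes={s: str(notes[s]) for s in session.stage_names},
        completed_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    session.scores[blinded_id] = record
    session.cursor += 1
    if session.state_path is not None:
        session.save()
    return session


def resume_session(state_path: Path | str) -> Session:
    """Load and validate a persisted session; never re-randomizes.

    A missing or corrupt state file raises :class:`SessionLoadError` —
    the original random order is either restored exactly or not at all.
    """
    state_path = Path(state_path)
    if state_path.is_dir():
        state_path = state_path / STATE_FILENAME
    try:
        data = json.loads(state_path.read_text())
    except FileNotFoundError as exc:
        raise SessionLoadError(f"no session state at {state_path}") from exc
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionLoadError(f"corrupt session state {state_path}: {exc}") from exc
    session = Session.from_dict(data)
    session.state_path = state_path
    return session
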