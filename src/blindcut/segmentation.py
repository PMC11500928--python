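"""Labeled rectangular regions over source media.

A segment is an axis-aligned rectangle on one source file, labeled in
well-plate style: one uppercase letter ``A``–``Z`` followed by a number
``1``–``36`` with no leading zeros (``A1`` … ``Z36``), matching how wells
of a multi-well plate are addressed.  Labels are unique across the whole
analysis — all batched source files pooled — because segments from every
file are mixed together before randomization.

Coordinates are 0-based, half-open pixel indices: a rect ``(x, y, w, h)``
covers columns ``[x, x+w)`` and rows ``[y, y+h)``.  Rectangles must lie
fully inside the frame; out-of-bounds rects are rejected rather than
clamped, since silent clamping would change segment content invisibly.
Overlapping rectangles are permitted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from blindcut import media as media_io
from blindcut.errors import ConfigError, DuplicateLabelError, GeometryError, LabelError
from blindcut.media import MediaRef

#: one uppercase letter, then 1–36 with no leading zeros
LABEL_PATTERN = re.compile(r"^[A-Z]([1-9]|[12][0-9]|3[0-6])$")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle; 0-based, half-open."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise GeometryError(f"rect width/height must be >= 1, got {self.w}x{self.h}")
        if self.x < 0 or self.y < 0:
            raise GeometryError(f"rect origin must be >= 0, got ({self.x}, {self.y})")

    def validate_against(self, width: int, height: int) -> None:
        if self.x + self.w > width or self.y + self.h > height:
            raise GeometryError(
                f"rect ({self.x},{self.y},{self.w},{self.h}) exceeds "
                f"{width}x{height} frame bounds"
            )

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["x"]), int(d["y"]), int(d["w"]), int(d["h"]))


@dataclass(frozen=True)
class SegmentSpec:
    """One labeled rectangle bound to a source media file."""

    label: str
    rect: Rect
    source: MediaRef

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rect": self.rect.to_dict(),
            "source": self.source.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentSpec":
        return cls(d["label"], Rect.from_dict(d["rect"]), MediaRef.from_dict(d["source"]))


def validate_label(label: str, existing: Iterable[str]) -> str:
    """Validate a segment label against the grammar and the used set.

    Accepts exactly one uppercase letter A–Z followed by an integer 1–36
    without leading zeros.  Raises :class:`LabelError` for malformed
    labels and :class:`DuplicateLabelError` for reuse; a label, once
    assigned, is permanent for the analysis.
    """
    if not isinstance(label, str) or not LABEL_PATTERN.match(label):
        raise LabelError(
            f"label {label!r} is invalid: expected one uppercase letter A-Z "
            "followed by a number 1-36 with no leading zeros (e.g. 'A1', 'H12')"
        )
    if label in set(existing):
        raise DuplicateLabelError(f"label {label!r} is already used in this analysis")
    return label


def add_segment(
    segments: Sequence[SegmentSpec], label: str, rect: Rect, source: MediaRef
) -> list[SegmentSpec]:
    """Append a validated segment, preserving the user's definition order."""
    validate_label(label, (s.label for s in segments))
    rect.validate_against(source.width, source.height)
    return list(segments) + [SegmentSpec(label, rect, source)]


def crop_frames(frames: Sequence[np.ndarray], rect: Rect) -> list[np.ndarray]:
    """Crop each frame to ``rect``; pure array slicing, bit-exact."""
    return [np.ascontiguousarray(f[rect.y : rect.y + rect.h, rect.x : rect.x + rect.w]) for f in frames]


def crop_segment(spec: SegmentSpec) -> list[np.ndarray]:
    """Read the segment's source and return its cropped frames.

    Output frame ``t`` at pixel ``(r, c)`` equals source frame ``t`` at
    pixel ``(y + r, x + c)``; one output frame per source frame.
    """
    spec.rect.validate_against(spec.source.width, spec.source.height)
    return crop_frames(media_io.read_frames(spec.source), spec.rect)


def grid_segments(
    rows: int,
    cols: int,
    origin: tuple[int, int],
    pitch: int,
    well_size: int,
) -> list[tuple[str, Rect]]:
    """Expand a plate-grid shorthand into well-labeled rectangles.

    Wells are labeled row-letter + column-number (``A1`` top-left, then
    across the row), the convention printed on multi-well plates.
    """
    if rows < 1 or cols < 1:
        raise ConfigError("grid needs at least 1 row and 1 column")
    if rows > 26 or cols > 36:
        raise ConfigError("grid labels support at most 26 rows (A-Z) and 36 columns")
    ox, oy = origin
    out = []
    for r in range(rows):
        for c in range(cols):
            label = f"{chr(ord('A') + r)}{c + 1}"
            out.append((label, Rect(ox + c * pitch, oy + r * pitch, well_size, well_size)))
    return out


def load_config(path: Path | str) -> list[tuple[str, list[tuple[str, Rect]]]]:
    """Load a segmentation config file.

    JSON schema: a list of entries, each either

    * ``{"source": path, "segments": [{"label", "x", "y", "w", "h"}, ...]}``, or
    * ``{"source": path, "grid": {"rows", "cols", "origin": [x, y],
      "pitch", "well_size"}}`` (plate shorthand).

    Returns ``[(source_path, [(label, rect), ...]), ...]``; geometry and
    label validation happen later, against the probed media.
    """
    try:
        entries = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read segmentation config {path}: {exc}") from exc
    if not isinstance(entries, list):
        raise ConfigError("segmentation config must be a JSON list of entries")
    out = []
    for entry in entries:
        source = entry.get("source")
        if not source:
            raise ConfigError("config entry missing 'source'")
        if "grid" in entry:
            g = entry["grid"]
            segs = grid_segments(
                int(g["rows"]), int(g["cols"]),
                (int(g["origin"][0]), int(g["origin"][1])),
                int(g["pitch"]), int(g["well_size"]),
            )
        elif "segments" in entry:
            segs = [
                (s["label"], Rect(int(s["x"]), int(s["y"]), int(s["w"]), int(s["h"])))
                for s in entry["segments"]
            ]
        else:
            raise ConfigError(f"config entry for {source} needs 'segments' or 'grid'")
        out.append((str(source), segs))
    return out


def build_segments(
    config: Sequence[tuple[str, Sequence[tuple[str, Rect]]]],
) -> list[SegmentSpec]:
    """Probe every source and validate all labels and rects up front.

    All sources must share one media type (video or image) per analysis.
    Any failure aborts before anything is written.
    """
    segments: list[SegmentSpec] = []
    media_types = set()
    for source_path, entries in config:
        ref = media_io.probe_media(source_path)
        media_types.add(ref.media_type)
        if len(media_types) > 1:
            raise ConfigError(
                "all sources in one analysis must share a media type; "
                f"got both video and image (at {source_path})"
            )
        for label, rect in entries:
            segments = add_segment(segments, label, rect, ref)
    return segments
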