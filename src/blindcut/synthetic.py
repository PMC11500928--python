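"""Synthetic multi-well plate fixtures with ground truth.

Emulates the kind of recording the blinded workflow is built for: a
plate of wells filmed from above, one animal per well, where each well's
condition determines how much the animal moves.  Each well holds one
bright disk ("blob") on a dark background performing a bounded random
walk whose per-frame step length is the well's *activity level* (pixels
per frame); activity 0 is a stationary blob.  The walk reflects off the
well walls so the blob never leaves its well.

The default plate mirrors a 96-well assay in which only rows A–E are
occupied (60 wells) and the treatment varies across four bands of three
columns each, strongest in columns 1–3 and untreated in columns 10–12 —
the classic concentration-gradient layout of a plate-based behavioral
assay.  The default activity levels (8, 4, 2, 0.5 px/frame across the
four bands) give clearly separated motion magnitudes while keeping the
untreated band visibly alive.

:func:`generate_plate_video` returns the ground truth — well rectangles
(directly usable as a segmentation config), per-well activity and the
exact blob trajectory — so every stage of the pipeline can be verified
against it.  :func:`activity_score` is a deterministic stand-in for a
human scorer: mean absolute pixel difference between consecutive frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from blindcut import media as media_io
from blindcut.errors import PlateSpecError
from blindcut.media import MediaRef
from blindcut.segmentation import Rect, grid_segments

_BG = 16        # plate background gray level
_WELL = 40      # well floor gray level
_BLOB = 230     # blob gray level

#: activity levels for the four default column bands, strongest first
DEFAULT_BAND_LEVELS = (8.0, 4.0, 2.0, 0.5)


def condition_bands(
    rows: int, cols: int, levels: Sequence[float]
) -> dict[str, float]:
    """Assign activity levels to equal column bands, left to right.

    ``levels=(8, 4, 2, 0.5)`` on 12 columns puts 8 px/frame in columns
    1–3, 4 in 4–6, 2 in 7–9 and 0.5 in 10–12.
    """
    if not levels:
        raise PlateSpecError("need at least one activity level")
    if cols % len(levels):
        raise PlateSpecError(
            f"{cols} columns do not divide evenly into {len(levels)} bands"
        )
    band = cols // len(levels)
    out = {}
    for r in range(rows):
        for c in range(cols):
            out[f"{chr(ord('A') + r)}{c + 1}"] = float(levels[c // band])
    return out


@dataclass(frozen=True)
class PlateSpec:
    """Geometry, timing and per-well conditions of a synthetic plate."""

    rows: int = 5
    cols: int = 12
    well_size: int = 40
    pitch: int = 48
    origin: tuple[int, int] = (12, 12)
    frame_count: int = 200
    fps: float = 25.0
    conditions: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise PlateSpecError("plate needs at least one row and one column")
        if self.pitch < self.well_size:
            raise PlateSpecError(
                f"pitch {self.pitch} < well size {self.well_size}: wells overlap"
            )
        if self.frame_count < 1:
            raise PlateSpecError("frame_count must be >= 1")
        if self.conditions is not None and any(
            a < 0 for a in self.conditions.values()
        ):
            raise PlateSpecError("activity levels must be non-negative")

    @property
    def frame_width(self) -> int:
        return 2 * self.origin[0] + self.pitch * (self.cols - 1) + self.well_size

    @property
    def frame_height(self) -> int:
        return 2 * self.origin[1] + self.pitch * (self.rows - 1) + self.well_size

    def well_grid(self) -> list[tuple[str, Rect]]:
        return grid_segments(
            self.rows, self.cols, self.origin, self.pitch, self.well_size
        )

    def resolved_conditions(self) -> dict[str, float]:
        if self.conditions is not None:
            return {label: float(self.conditions.get(label, 0.0))
                    for label, _ in self.well_grid()}
        return condition_bands(self.rows, self.cols, DEFAULT_BAND_LEVELS)


@dataclass
class WellTruth:
    rect: Rect
    activity: float
    trajectory: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for pipeline tests."""

    wells: dict[str, WellTruth]
    source: Optional[str] = None

    def segmentation_config(self, source: Optional[str] = None) -> list[dict]:
        """The true well grid in the segmentation-config schema."""
        src = source or self.source
        return [
            {
                "source": str(src),
                "segments": [
                    {"label": label, **wt.rect.to_dict()}
                    for label, wt in self.wells.items()
                ],
            }
        ]

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "wells": {
                label: {
                    "rect": wt.rect.to_dict(),
                    "activity": wt.activity,
                    "trajectory": [[float(x), float(y)] for x, y in wt.trajectory],
                }
                for label, wt in self.wells.items()
            },
            "segmentation": self.segmentation_config() if self.source else None,
        }

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        wells = {
            label: WellTruth(
                Rect.from_dict(w["rect"]),
                float(w["activity"]),
                [(float(x), float(y)) for x, y in w["trajectory"]],
            )
            for label, w in d["wells"].items()
        }
        return cls(wells, d.get("source"))


def _walk(
    rect: Rect, radius: float, activity: float, frame_count: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Reflecting random walk of the blob center inside its well.

    The whole disk stays inside the well: the center is confined to the
    rect shrunk by ``radius + 1`` on every side.  Each step has length
    exactly ``activity`` in a uniformly random direction (before any
    wall reflection).
    """
    margin = radius + 1.0
    lo_x, hi_x = rect.x + margin, rect.x + rect.w - margin
    lo_y, hi_y = rect.y + margin, rect.y + rect.h - margin
    if lo_x > hi_x or lo_y > hi_y:
        raise PlateSpecError(f"well {rect} too small for blob radius {radius}")

    def reflect(v: float, lo: float, hi: float) -> float:
        span = hi - lo
        if span <= 0:
            return lo
        v = (v - lo) % (2 * span)
        return lo + (v if v <= span else 2 * span - v)

    cx = (lo_x + hi_x) / 2
    cy = (lo_y + hi_y) / 2
    traj = [(cx, cy)]
    for _ in range(frame_count - 1):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cx = reflect(cx + activity * np.cos(theta), lo_x, hi_x)
        cy = reflect(cy + activity * np.sin(theta), lo_y, hi_y)
        traj.append((cx, cy))
    return traj


def generate_plate_frames(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the plate movie in memory.

    Returns ``(frames, truth)`` where ``frames`` is a
    ``(frame_count, H, W, 3)`` uint8 array and ``truth`` holds each
    well's rect, activity level and exact blob-center trajectory.
    Deterministic for a fixed spec (each well gets its own RNG stream
    derived from ``spec.seed`` and its grid position, so adding wells
    never perturbs existing ones).
    """
    grid = spec.well_grid()
    conditions = spec.resolved_conditions()
    radius = max(2.0, spec.well_size / 8.0)

    base = np.full((spec.frame_height, spec.frame_width), _BG, dtype=np.uint8)
    for _, rect in grid:
        base[rect.y : rect.y + rect.h, rect.x : rect.x + rect.w] = _WELL

    wells: dict[str, WellTruth] = {}
    for idx, (label, rect) in enumerate(grid):
        r, c = divmod(idx, spec.cols)
        rng = np.random.default_rng([int(spec.seed), r, c])
        activity = conditions[label]
        traj = _walk(rect, radius, activity, spec.frame_count, rng)
        wells[label] = WellTruth(rect, activity, traj)

    frames = np.empty(
        (spec.frame_count, spec.frame_height, spec.frame_width, 3), dtype=np.uint8
    )
    height, width = base.shape
    for t in range(spec.frame_count):
        canvas = base.copy()
        for wt in wells.values():
            cx, cy = wt.trajectory[t]
            x0 = max(0, int(cx - radius) - 1)
            x1 = min(width, int(cx + radius) + 2)
            y0 = max(0, int(cy - radius) - 1)
            y1 = min(height, int(cy + radius) + 2)
            xs = np.arange(x0, x1, dtype=np.float64)
            ys = np.arange(y0, y1, dtype=np.float64)
            mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= radius**2
            canvas[y0:y1, x0:x1][mask] = _BLOB
        frames[t] = canvas[:, :, None]
    return frames, GroundTruth(wells)


def generate_plate_video(
    spec: PlateSpec, out_path: Path | str
) -> tuple[MediaRef, GroundTruth]:
    """Render the plate and write it to ``out_path``.

    ``.avi`` output is uncompressed, so frames read back from the file
    are bit-identical to the rendered ones; a single-frame spec may be
    written to an image container instead.  The returned ground truth
    records the output path as its source.
    """
    frames, truth = generate_plate_frames(spec)
    out_path = Path(out_path)
    if media_io.media_type_of(out_path) == "image":
        if spec.frame_count != 1:
            raise PlateSpecError(
                f"cannot write {spec.frame_count} frames to an image container"
            )
        ref = media_io.write_segment([frames[0]], out_path)
    else:
        ref = media_io.write_segment(list(frames), out_path, fps=spec.fps)
    truth.source = str(out_path)
    return ref, truth


def activity_score(frames: Sequence[np.ndarray]) -> float:
    """Motion score: mean absolute pixel change between consecutive frames.

    Averages, over all consecutive frame pairs, the mean absolute
    per-pixel intensity difference.  Zero if and only if all frames are
    identical; monotone in how much of the image changes per frame.
    """
    if len(frames) < 2:
        raise ValueError("activity_score needs at least 2 frames")
    diffs = [
        float(np.mean(np.abs(np.asarray(a, dtype=np.int64) - np.asarray(b, dtype=np.int64))))
        for a, b in zip(frames[:-1], frames[1:])
    ]
    return float(np.mean(diffs))
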