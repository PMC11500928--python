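"""Reading, probing and writing of the supported media formats.

Supported inputs are the common laboratory capture formats: ``.mp4`` and
``.avi`` video, and ``.png``, ``.jpg``/``.jpeg`` and ``.bmp`` still
images.  Frames are exchanged as ``uint8`` numpy arrays (``H × W`` for
grayscale images, ``H × W × 3``/``4`` otherwise).  Cropped segments are
always re-encoded from raw pixels — never stream-copied — and written
without any container metadata, so a blinded segment file can never leak
the name, timestamps or tags of its source recording.  Pixel resolution
is preserved exactly: no resampling ever occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from blindcut.containers import avi, mp4
from blindcut.errors import BoundsError, DecodeError, FormatError

VIDEO_EXTENSIONS = {".mp4", ".avi"}
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}

#: fps assumed when a source video reports no frame rate
DEFAULT_FPS = 25.0


@dataclass(frozen=True)
class MediaRef:
    """Probed description of one media file.

    ``frame_count`` is 1 and ``fps`` is ``None`` for still images.
    """

    path: str
    media_type: str  # "video" | "image"
    width: int
    height: int
    frame_count: int
    fps: Optional[float] = None

    @property
    def extension(self) -> str:
        return Path(self.path).suffix.lower()

    @property
    def source_name(self) -> str:
        """Basename of the source file (the identifying string to blind)."""
        return Path(self.path).name

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MediaRef":
        return cls(**d)


def media_type_of(path: Path | str) -> str:
    ext = Path(path).suffix.lower()
    if ext in VIDEO_EXTENSIONS:
        return "video"
    if ext in IMAGE_EXTENSIONS:
        return "image"
    raise FormatError(
        f"unsupported media format {ext!r} ({Path(path).name}); "
        f"supported: {sorted(VIDEO_EXTENSIONS | IMAGE_EXTENSIONS)}"
    )


def probe_media(path: Path | str) -> MediaRef:
    """Inspect a media file and return its :class:`MediaRef`.

    Raises :class:`FormatError` for unsupported extensions and
    :class:`DecodeError` for unreadable files.  The file is not modified.
    """
    path = Path(path)
    mtype = media_type_of(path)
    if not path.is_file():
        raise DecodeError(f"file not found: {path}")
    if mtype == "image":
        try:
            with Image.open(path) as img:
                w, h = img.size
        except UnidentifiedImageError as exc:
            raise DecodeError(f"cannot decode image {path}: {exc}") from exc
        return MediaRef(str(path), "image", w, h, 1, None)
    reader = avi if path.suffix.lower() == ".avi" else mp4
    try:
        w, h, n, fps = reader.probe(path)
    except DecodeError:
        raise
    except Exception as exc:  # struct errors on corrupt files
        raise DecodeError(f"cannot decode video {path}: {exc}") from exc
    return MediaRef(str(path), "video", w, h, n, fps or DEFAULT_FPS)


def _video_module(ext: str):
    return avi if ext == ".avi" else mp4


def read_frame(media: MediaRef, index: int) -> np.ndarray:
    """Return frame ``index`` (0-based) as a pixel array.

    Images accept only index 0.  The returned array always has the
    probed height and width.
    """
    if not 0 <= index < media.frame_count:
        raise BoundsError(
            f"frame index {index} out of range [0, {media.frame_count})"
        )
    if media.media_type == "image":
        with Image.open(media.path) as img:
            return np.asarray(img)
    return _video_module(media.extension).read_frame(media.path, index)


def read_frames(media: MediaRef) -> list[np.ndarray]:
    """Return every frame of the media as a list of pixel arrays."""
    if media.media_type == "image":
        return [read_frame(media, 0)]
    return _video_module(media.extension).read_frames(media.path)


def write_segment(
    frames: Sequence[np.ndarray],
    out_path: Path | str,
    fps: Optional[float] = None,
) -> MediaRef:
    """Write pixel frames to ``out_path``, re-encoding from raw pixels.

    The container is chosen by extension.  ``.png``/``.bmp`` round-trip
    bit-exactly, as does ``.avi`` (uncompressed frames); ``.jpg`` and
    ``.mp4`` are lossy and guarantee only dimensions and frame count.
    Grayscale frames are promoted to 3 channels only where the container
    requires it (video); alpha channels are preserved for ``.png``.
    """
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("write_segment requires at least one frame")
    shape0 = frames[0].shape
    if any(f.shape != shape0 for f in frames):
        raise ValueError("all frames must share identical dimensions")
    out_path = Path(out_path)
    ext = out_path.suffix.lower()
    mtype = media_type_of(out_path)
    try:
        if mtype == "image":
            if len(frames) != 1:
                raise ValueError(
                    f"image container {ext!r} holds exactly one frame, got {len(frames)}"
                )
            frame = frames[0]
            if ext in (".jpg", ".jpeg") and frame.ndim == 3 and frame.shape[2] == 4:
                frame = frame[:, :, :3]  # JPEG has no alpha channel
            Image.fromarray(frame).save(out_path)
        else:
            fps = fps if fps else DEFAULT_FPS
            rgb = [_ensure_rgb(f) for f in frames]
            _video_module(ext).write(out_path, rgb, fps)
    except OSError as exc:
        raise OSError(f"cannot write segment to {out_path}: {exc}") from exc
    return probe_media(out_path)


def _ensure_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.repeat(frame[:, :, None], 3, axis=2)
    if frame.shape[2] == 4:
        return frame[:, :, :3]
    return frame
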