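"""Uncompressed RIFF AVI reader/writer.

Frames are stored as classic device-independent bitmaps: 24-bit BGR,
rows bottom-up and padded to 4-byte boundaries (``BI_RGB``).  This is the
oldest and most widely decodable AVI payload and, being uncompressed, it
round-trips pixel values exactly.  The reader additionally decodes
Motion-JPEG (``MJPG``) chunks through Pillow so MJPEG-in-AVI files from
other tools remain readable.

No container metadata (source names, creation times) is ever written;
the file carries nothing but dimensions, timing and pixels.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np

from blindcut.errors import DecodeError

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def _frame_to_dib(frame: np.ndarray) -> bytes:
    """RGB (H, W, 3) uint8 -> bottom-up BGR rows padded to 4 bytes."""
    h, w, _ = frame.shape
    bgr = frame[::-1, :, ::-1]  # flip vertically, swap channel order
    row_bytes = w * 3
    stride = _pad4(row_bytes)
    if stride == row_bytes:
        return bgr.tobytes()
    out = np.zeros((h, stride), dtype=np.uint8)
    out[:, :row_bytes] = bgr.reshape(h, row_bytes)
    return out.tobytes()


def _dib_to_frame(data: bytes, width: int, height: int) -> np.ndarray:
    stride = _pad4(width * 3)
    if len(data) < stride * height:
        raise DecodeError("truncated DIB frame")
    arr = np.frombuffer(data[: stride * height], dtype=np.uint8)
    arr = arr.reshape(height, stride)[:, : width * 3].reshape(height, width, 3)
    return arr[::-1, :, ::-1].copy()


def write(path: Path | str, frames, fps: float) -> None:
    """Write RGB frames as an uncompressed (BI_RGB) AVI file."""
    frames = [np.ascontiguousarray(f, dtype=np.uint8) for f in frames]
    h, w, _ = frames[0].shape
    n = len(frames)
    frame_size = _pad4(w * 3) * h

    # ---- stream format: BITMAPINFOHEADER, biCompression = 0 (BI_RGB)
    strf = struct.pack(
        "<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_size, 0, 0, 0, 0
    )
    # ---- stream header: video stream, rate/scale encodes fps
    scale, rate = 1000, round(fps * 1000)
    strh = struct.pack(
        "<4s4sIHHIIIIIIII4H",
        b"vids", b"DIB ", 0, 0, 0, 0, scale, rate, 0, n, frame_size,
        0xFFFFFFFF, 0, 0, 0, w, h,
    )
    strl = _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf))
    avih = struct.pack(
        "<14I",
        round(1_000_000 / fps) if fps else 0,  # microseconds per frame
        frame_size * max(1, round(fps)), 0, _AVIF_HASINDEX, n, 0, 1,
        frame_size, w, h, 0, 0, 0, 0,
    )
    hdrl = _list(b"hdrl", _chunk(b"avih", avih) + strl)

    movi_body = b""
    index = b""
    offset = 4  # relative to the 'movi' fourcc
    for frame in frames:
        data = _frame_to_dib(frame)
        movi_body += _chunk(b"00db", data)
        index += struct.pack("<4sIII", b"00db", _AVIIF_KEYFRAME, offset, len(data))
        offset += 8 + len(data) + (len(data) & 1)
    movi = _list(b"movi", movi_body)
    idx1 = _chunk(b"idx1", index)

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _chunk(fourcc: bytes, data: bytes) -> bytes:
    pad = b"\x00" if len(data) & 1 else b""
    return fourcc + struct.pack("<I", len(data)) + data + pad


def _list(fourcc: bytes, body: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + body)


class _Parsed:
    __slots__ = ("width", "height", "fps", "compression", "frame_chunks")

    def __init__(self):
        self.width = self.height = 0
        self.fps = 0.0
        self.compression = 0
        self.frame_chunks: list[tuple[int, int]] = []  # (offset, size) in file


def _parse(path: Path | str) -> _Parsed:
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise DecodeError(f"not a RIFF AVI file: {path}")
    p = _Parsed()
    _walk(data, 12, len(data), p)
    if p.width <= 0 or p.height <= 0:
        raise DecodeError(f"no video stream header found in {path}")
    return p


def _walk(data: bytes, pos: int, end: int, p: _Parsed) -> None:
    while pos + 8 <= end:
        fourcc = data[pos : pos + 4]
        size = struct.unpack_from("<I", data, pos + 4)[0]
        body_start = pos + 8
        if fourcc == b"LIST":
            list_type = data[body_start : body_start + 4]
            inner = body_start + 4
            if list_type == b"movi":
                _collect_frames(data, inner, body_start + size, p)
            else:
                _walk(data, inner, body_start + size, p)
        elif fourcc == b"strh":
            if data[body_start : body_start + 4] == b"vids":
                scale, rate = struct.unpack_from("<II", data, body_start + 20)
                p.fps = rate / scale if scale else 0.0
        elif fourcc == b"strf" and p.width == 0:
            (_, w, h, _, _, comp) = struct.unpack_from("<IiiHHI", data, body_start)
            p.width, p.height, p.compression = w, abs(h), comp
        pos = body_start + size + (size & 1)


def _collect_frames(data: bytes, pos: int, end: int, p: _Parsed) -> None:
    while pos + 8 <= end:
        fourcc = data[pos : pos + 4]
        size = struct.unpack_from("<I", data, pos + 4)[0]
        if fourcc[2:4] in (b"db", b"dc") and size > 0:
            p.frame_chunks.append((pos + 8, size))
        pos += 8 + size + (size & 1)


def probe(path: Path | str) -> tuple[int, int, int, float]:
    """Return (width, height, frame_count, fps)."""
    p = _parse(path)
    return p.width, p.height, len(p.frame_chunks), p.fps


def _decode_chunk(data: bytes, p: _Parsed) -> np.ndarray:
    if p.compression == 0:  # BI_RGB
        return _dib_to_frame(data, p.width, p.height)
    if p.compression in (0x47504A4D, 0x67706A6D):  # 'MJPG' / 'mjpg'
        from PIL import Image

        img = Image.open(io.BytesIO(data)).convert("RGB")
        return np.asarray(img)
    raise DecodeError(f"unsupported AVI codec 0x{p.compression:08x}")


def read_frames(path: Path | str) -> list[np.ndarray]:
    p = _parse(path)
    raw = Path(path).read_bytes()
    return [_decode_chunk(raw[off : off + size], p) for off, size in p.frame_chunks]


def read_frame(path: Path | str, index: int) -> np.ndarray:
    p = _parse(path)
    off, size = p.frame_chunks[index]
    raw = Path(path).read_bytes()
    return _decode_chunk(raw[off : off + size], p)
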