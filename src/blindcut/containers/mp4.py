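"""Motion-JPEG in an ISO base media (.mp4) container.

Each video sample is an independent baseline-JPEG image (sample entry
``jpeg``), encoded and decoded with Pillow.  The writer emits the minimal
box tree — ``ftyp`` / ``mdat`` / ``moov`` with a single video track — and
no metadata beyond dimensions and timing.  The reader walks the box tree
and decodes samples via the ``stsz``/``stsc``/``stco`` tables, so it can
read any MJPEG-in-MP4 file; other codecs (H.264 etc.) raise
:class:`~blindcut.errors.DecodeError`.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np
from PIL import Image

from blindcut.errors import DecodeError

_TIMESCALE = 90_000
_JPEG_QUALITY = 95


def _box(fourcc: bytes, payload: bytes) -> bytes:
    return struct.pack(">I", 8 + len(payload)) + fourcc + payload


def _full(fourcc: bytes, version: int, flags: int, payload: bytes) -> bytes:
    return _box(fourcc, struct.pack(">I", (version << 24) | flags) + payload)


def _matrix_identity() -> bytes:
    return struct.pack(">9i", 0x00010000, 0, 0, 0, 0x00010000, 0, 0, 0, 0x40000000)


def write(path: Path | str, frames, fps: float) -> None:
    """Write RGB frames as Motion-JPEG samples in an MP4 container."""
    samples = []
    for frame in frames:
        buf = io.BytesIO()
        Image.fromarray(np.ascontiguousarray(frame, dtype=np.uint8)).save(
            buf, format="JPEG", quality=_JPEG_QUALITY
        )
        samples.append(buf.getvalue())
    h, w = np.asarray(frames[0]).shape[:2]
    n = len(samples)
    delta = round(_TIMESCALE / fps)
    duration = n * delta

    ftyp = _box(b"ftyp", b"isom" + struct.pack(">I", 512) + b"isomiso2mp41")
    mdat_payload = b"".join(samples)
    mdat_offset = len(ftyp) + 8  # first sample byte, needed for stco

    stsd_entry = (
        b"\x00" * 6
        + struct.pack(">H", 1)           # data_reference_index
        + b"\x00" * 16                   # pre_defined / reserved
        + struct.pack(">HH", w, h)
        + struct.pack(">II", 0x00480000, 0x00480000)  # 72 dpi
        + struct.pack(">I", 0)
        + struct.pack(">H", 1)           # frame_count
        + b"\x00" * 32                   # compressor name
        + struct.pack(">Hh", 24, -1)     # depth, pre_defined
    )
    stbl = _box(
        b"stbl",
        _full(b"stsd", 0, 0, struct.pack(">I", 1) + _box(b"jpeg", stsd_entry))
        + _full(b"stts", 0, 0, struct.pack(">III", 1, n, delta))
        + _full(b"stsc", 0, 0, struct.pack(">IIII", 1, 1, n, 1))
        + _full(
            b"stsz", 0, 0,
            struct.pack(">II", 0, n) + b"".join(struct.pack(">I", len(s)) for s in samples),
        )
        + _full(b"stco", 0, 0, struct.pack(">II", 1, mdat_offset)),
    )
    dinf = _box(b"dinf", _full(b"dref", 0, 0, struct.pack(">I", 1) + _full(b"url ", 0, 1, b"")))
    minf = _box(b"minf", _full(b"vmhd", 0, 1, b"\x00" * 8) + dinf + stbl)
    hdlr = _full(b"hdlr", 0, 0, b"\x00" * 4 + b"vide" + b"\x00" * 12 + b"VideoHandler\x00")
    mdhd = _full(
        b"mdhd", 0, 0,
        struct.pack(">IIIIHH", 0, 0, _TIMESCALE, duration, 0x55C4, 0),
    )
    mdia = _box(b"mdia", mdhd + hdlr + minf)
    tkhd = _full(
        b"tkhd", 0, 3,
        struct.pack(">IIII", 0, 0, 1, 0)       # times, track id, reserved
        + struct.pack(">I", duration)
        + b"\x00" * 8
        + struct.pack(">HHHH", 0, 0, 0, 0)     # layer, group, volume, reserved
        + _matrix_identity()
        + struct.pack(">II", w << 16, h << 16),
    )
    trak = _box(b"trak", tkhd + mdia)
    mvhd = _full(
        b"mvhd", 0, 0,
        struct.pack(">IIII", 0, 0, _TIMESCALE, duration)
        + struct.pack(">IHH", 0x00010000, 0x0100, 0)
        + b"\x00" * 8
        + _matrix_identity()
        + b"\x00" * 24
        + struct.pack(">I", 2),                # next track id
    )
    moov = _box(b"moov", mvhd + trak)

    with open(path, "wb") as fh:
        fh.write(ftyp + _box(b"mdat", mdat_payload) + moov)


class _Track:
    __slots__ = ("width", "height", "codec", "timescale", "delta", "sizes", "offsets")

    def __init__(self):
        self.width = self.height = 0
        self.codec = b""
        self.timescale = _TIMESCALE
        self.delta = 0
        self.sizes: list[int] = []
        self.offsets: list[int] = []


def _children(data: bytes, pos: int, end: int):
    while pos + 8 <= end:
        size = struct.unpack_from(">I", data, pos)[0]
        fourcc = data[pos + 4 : pos + 8]
        if size == 1:  # 64-bit largesize
            size = struct.unpack_from(">Q", data, pos + 8)[0]
            yield fourcc, pos + 16, pos + size
        else:
            if size == 0:
                size = end - pos
            yield fourcc, pos + 8, pos + size
        pos += size


def _find(data: bytes, pos: int, end: int, *path: bytes):
    for fourcc, body, box_end in _children(data, pos, end):
        if fourcc == path[0]:
            if len(path) == 1:
                return body, box_end
            return _find(data, body, box_end, *path[1:])
    return None


def _parse(path: Path | str) -> tuple[bytes, _Track]:
    data = Path(path).read_bytes()
    if _find(data, 0, len(data), b"ftyp") is None:
        raise DecodeError(f"not an ISO media file: {path}")
    t = _Track()
    found = _find(data, 0, len(data), b"moov", b"trak", b"mdia")
    if found is None:
        raise DecodeError(f"no video track in {path}")
    mdia_start, mdia_end = found
    mdhd = _find(data, mdia_start, mdia_end, b"mdhd")
    if mdhd:
        version = data[mdhd[0]]
        t.timescale = struct.unpack_from(
            ">I", data, mdhd[0] + (4 + 16 if version else 4 + 8)
        )[0]
    stbl = _find(data, mdia_start, mdia_end, b"minf", b"stbl")
    if stbl is None:
        raise DecodeError(f"no sample table in {path}")
    for fourcc, body, box_end in _children(data, *stbl):
        if fourcc == b"stsd":
            entry_size = struct.unpack_from(">I", data, body + 8)[0]
            t.codec = data[body + 12 : body + 16]
            t.width, t.height = struct.unpack_from(">HH", data, body + 16 + 24)
            del entry_size
        elif fourcc == b"stts":
            count = struct.unpack_from(">I", data, body + 4)[0]
            if count:
                t.delta = struct.unpack_from(">I", data, body + 12)[0]
        elif fourcc == b"stsz":
            fixed, count = struct.unpack_from(">II", data, body + 4)
            if fixed:
                t.sizes = [fixed] * count
            else:
                t.sizes = list(struct.unpack_from(f">{count}I", data, body + 12))
        elif fourcc == b"stco":
            count = struct.unpack_from(">I", data, body + 4)[0]
            chunk_offsets = struct.unpack_from(f">{count}I", data, body + 8)
            t.offsets = list(chunk_offsets)  # refined below via stsc
    # expand chunk offsets to per-sample offsets using stsc
    stsc = _find(data, stbl[0], stbl[1], b"stsc")
    sample_offsets: list[int] = []
    if stsc and t.offsets:
        body = stsc[0]
        count = struct.unpack_from(">I", data, body + 4)[0]
        entries = [
            struct.unpack_from(">III", data, body + 8 + 12 * i) for i in range(count)
        ]
        chunk_count = len(t.offsets)
        per_chunk = []
        for i, (first, spc, _) in enumerate(entries):
            last = entries[i + 1][0] - 1 if i + 1 < len(entries) else chunk_count
            per_chunk.extend([spc] * (last - first + 1))
        si = 0
        for ci, chunk_off in enumerate(t.offsets):
            off = chunk_off
            for _ in range(per_chunk[ci] if ci < len(per_chunk) else 0):
                if si >= len(t.sizes):
                    break
                sample_offsets.append(off)
                off += t.sizes[si]
                si += 1
    t.offsets = sample_offsets
    if len(t.offsets) != len(t.sizes):
        raise DecodeError(f"inconsistent sample tables in {path}")
    return data, t


def probe(path: Path | str) -> tuple[int, int, int, float]:
    """Return (width, height, frame_count, fps)."""
    _, t = _parse(path)
    fps = t.timescale / t.delta if t.delta else 0.0
    return t.width, t.height, len(t.sizes), fps


def _decode(data: bytes, t: _Track, i: int) -> np.ndarray:
    if t.codec != b"jpeg":
        raise DecodeError(
            f"unsupported MP4 codec {t.codec!r}; only Motion-JPEG is readable"
        )
    chunk = data[t.offsets[i] : t.offsets[i] + t.sizes[i]]
    return np.asarray(Image.open(io.BytesIO(chunk)).convert("RGB"))


def read_frames(path: Path | str) -> list[np.ndarray]:
    data, t = _parse(path)
    return [_decode(data, t, i) for i in range(len(t.sizes))]


def read_frame(path: Path | str, index: int) -> np.ndarray:
    data, t = _parse(path)
    return _decode(data, t, index)
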