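import numpy as np
import pytest

from blindcut.media import MediaRef, write_segment


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def make_image(tmp_path, rng):
    """Factory: write a random image file, return (MediaRef-able path, frames)."""

    counter = {"n": 0}

    def _make(width=64, height=48, ext=".png", constant=None):
        counter["n"] += 1
        if constant is not None:
            frame = np.full((height, width, 3), constant, dtype=np.uint8)
        else:
            frame = rng.integers(0, 256, (height, width, 3), dtype=np.uint8)
        path = tmp_path / f"img{counter['n']}{ext}"
        write_segment([frame], path)
        return path, frame

    return _make


@pytest.fixture
def make_video(tmp_path, rng):
    """Factory: write a random video, return (path, ground-truth frames)."""

    counter = {"n": 0}

    def _make(width=128, height=96, n_frames=10, ext=".avi", fps=20.0):
        counter["n"] += 1
        frames = rng.integers(0, 256, (n_frames, height, width, 3), dtype=np.uint8)
        path = tmp_path / f"vid{counter['n']}{ext}"
        write_segment(list(frames), path, fps=fps)
        return path, frames

    return _make


def fake_media(name="plate.avi", width=200, height=100, frame_count=5):
    """An unprobed MediaRef for tests that never touch pixels."""
    return MediaRef(name, "video", width, height, frame_count, 25.0)
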