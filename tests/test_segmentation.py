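import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blindcut.errors import (
    ConfigError,
    DuplicateLabelError,
    GeometryError,
    LabelError,
)
from blindcut.media import probe_media
from blindcut.segmentation import (
    Rect,
    add_segment,
    build_segments,
    crop_frames,
    crop_segment,
    grid_segments,
    load_config,
    validate_label,
)

from conftest import fake_media


class TestLabelGrammar:
    @pytest.mark.parametrize("label", ["A1", "Z36", "M7", "B29", "C30", "A36"])
    def test_wellplate_style_labels_accepted(self, label):
        assert validate_label(label, set()) == label

    @pytest.mark.parametrize(
        "label",
        ["A0", "A37", "AA1", "a1", "5B", "", "A", "1", "A01", "A1 ", " A1", "A-1"],
    )
    def test_malformed_labels_rejected(self, label):
        with pytest.raises(LabelError):
            validate_label(label, set())

    def test_duplicate_rejected_with_specific_error(self):
        with pytest.raises(DuplicateLabelError):
            validate_label("B2", {"B2"})

    def test_duplicate_error_is_a_label_error(self):
        # callers catching LabelError see both failure kinds
        assert issubclass(DuplicateLabelError, LabelError)


class TestRect:
    def test_degenerate_rect_rejected(self):
        with pytest.raises(GeometryError):
            Rect(0, 0, 0, 5)
        with pytest.raises(GeometryError):
            Rect(-1, 0, 5, 5)

    def test_bounds_are_half_open(self):
        Rect(0, 0, 200, 100).validate_against(200, 100)  # exact fit allowed
        with pytest.raises(GeometryError):
            Rect(1, 0, 200, 100).validate_against(200, 100)


class TestAddSegment:
    def test_full_frame_segment(self):
        src = fake_media()
        segs = add_segment([], "A1", Rect(0, 0, src.width, src.height), src)
        assert [s.label for s in segs] == ["A1"]

    def test_one_past_edge_is_geometry_error(self):
        src = fake_media(width=200, height=100)
        with pytest.raises(GeometryError):
            add_segment([], "A1", Rect(1, 0, 200, 100), src)

    def test_uniqueness_is_global_across_files(self):
        a, b = fake_media("one.avi"), fake_media("two.avi")
        segs = add_segment([], "C3", Rect(0, 0, 10, 10), a)
        with pytest.raises(DuplicateLabelError):
            add_segment(segs, "C3", Rect(0, 0, 10, 10), b)

    def test_definition_order_is_stable(self):
        src = fake_media()
        segs = []
        labels = ["B2", "A1", "C9", "A2"]
        for lab in labels:
            segs = add_segment(segs, lab, Rect(0, 0, 5, 5), src)
        assert [s.label for s in segs] == labels

    def test_sixty_well_grid_all_distinct(self):
        src = fake_media(width=600, height=300)
        segs = []
        for label, rect in grid_segments(5, 12, (10, 10), 48, 40):
            segs = add_segment(segs, label, rect, src)
        assert len(segs) == 60
        assert len({s.label for s in segs}) == 60


class TestCrop:
    def test_full_frame_crop_is_identity(self, make_image):
        path, truth = make_image(width=40, height=30)
        src = probe_media(path)
        segs = add_segment([], "A1", Rect(0, 0, 40, 30), src)
        (out,) = crop_segment(segs[0])
        assert np.array_equal(out, truth)

    def test_single_pixel_crop(self, make_image):
        path, truth = make_image(width=40, height=30)
        src = probe_media(path)
        (out,) = crop_segment(add_segment([], "A1", Rect(7, 3, 1, 1), src)[0])
        assert out.shape == (1, 1, 3)
        assert np.array_equal(out[0, 0], truth[3, 7])

    def test_video_crop_matches_slicing_oracle_per_frame(self, make_video):
        path, truth = make_video(width=60, height=40, n_frames=6)
        src = probe_media(path)
        rect = Rect(11, 5, 23, 17)
        out = crop_segment(add_segment([], "A1", rect, src)[0])
        assert len(out) == 6
        for t in range(6):
            assert np.array_equal(out[t], truth[t, 5:22, 11:34])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_crop_frames_equals_numpy_slicing(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        h, w = rng.integers(4, 64, 2)
        frame = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
        x = data.draw(st.integers(0, int(w) - 1))
        y = data.draw(st.integers(0, int(h) - 1))
        rw = data.draw(st.integers(1, int(w) - x))
        rh = data.draw(st.integers(1, int(h) - y))
        (out,) = crop_frames([frame], Rect(x, y, rw, rh))
        assert np.array_equal(out, frame[y : y + rh, x : x + rw])


class TestConfig:
    def test_grid_shorthand_layout(self):
        grid = grid_segments(2, 3, (5, 7), 20, 16)
        assert [label for label, _ in grid] == ["A1", "A2", "A3", "B1", "B2", "B3"]
        assert grid[4][1] == Rect(5 + 20, 7 + 20, 16, 16)

    def test_load_config_both_schemas(self, tmp_path):
        cfg = [
            {"source": "a.png", "segments": [{"label": "A1", "x": 0, "y": 0, "w": 5, "h": 5}]},
            {"source": "b.png", "grid": {"rows": 1, "cols": 2, "origin": [0, 0], "pitch": 10, "well_size": 8}},
        ]
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps(cfg))
        loaded = load_config(p)
        assert loaded[0] == ("a.png", [("A1", Rect(0, 0, 5, 5))])
        assert [label for label, _ in loaded[1][1]] == ["A1", "A2"]

    def test_mixed_media_types_rejected(self, make_image, make_video):
        img, _ = make_image()
        vid, _ = make_video()
        config = [
            (str(vid), [("A1", Rect(0, 0, 10, 10))]),
            (str(img), [("A2", Rect(0, 0, 10, 10))]),
        ]
        with pytest.raises(ConfigError):
            build_segments(config)

    def test_build_segments_validates_before_accepting(self, make_image):
        img, _ = make_image(width=64, height=48)
        with pytest.raises(GeometryError):
            build_segments([(str(img), [("A1", Rect(0, 0, 65, 48))])])
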