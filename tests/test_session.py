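import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from blindcut.errors import SequencingError, SessionLoadError
from blindcut.segmentation import Rect, SegmentSpec
from blindcut.session import (
    Session,
    blinded_id_format,
    create_session,
    fisher_yates_shuffle,
    next_segment,
    record_score,
    resume_session,
    scan_for_leaks,
)

from conftest import fake_media


def make_segments(n, source_name="plate.avi"):
    src = fake_media(source_name, width=400, height=400)
    labels = [f"{chr(ord('A') + i // 12)}{i % 12 + 1}" for i in range(n)]
    return [SegmentSpec(lab, Rect(0, 0, 10, 10), src) for lab in labels]


class TestFisherYates:
    def test_degenerate_sizes(self):
        assert fisher_yates_shuffle(0, 1) == []
        assert fisher_yates_shuffle(1, 1) == [0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(0, 200), seed=st.integers(0, 2**31 - 1))
    def test_always_a_permutation(self, n, seed):
        assert sorted(fisher_yates_shuffle(n, seed)) == list(range(n))

    def test_deterministic_under_seed(self):
        assert fisher_yates_shuffle(50, 123) == fisher_yates_shuffle(50, 123)
        assert fisher_yates_shuffle(50, 123) != fisher_yates_shuffle(50, 124)

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 42), (12, 7)])
    def test_matches_stdlib_shuffle_stream(self, n, seed):
        # random.shuffle implements the same backward Fisher-Yates pass;
        # with an identical seeded generator the permutations must agree.
        expected = list(range(n))
        random.Random(seed).shuffle(expected)
        assert fisher_yates_shuffle(n, seed) == expected


class TestBlindedIds:
    def test_small_sessions_use_three_digits(self):
        assert blinded_id_format(60).format(1) == "S001"
        assert blinded_id_format(60).format(60) == "S060"

    def test_large_sessions_keep_a_leading_zero(self):
        # labels never have leading zeros, so an ID whose digits start
        # with 0 can never contain a label as a substring
        fmt = blinded_id_format(150)
        ids = [fmt.format(k) for k in range(1, 151)]
        labels = [f"{ch}{num}" for ch in "SA" for num in range(1, 37)]
        assert all(not scan_for_leaks(i, labels, []) for i in ids)


class TestCreateSession:
    def test_single_segment_session(self):
        s = create_session(make_segments(1), ["stage 1"], seed=0)
        assert s.order == [0]
        assert s.blinded_ids == ["S001"]
        assert s.cursor == 0

    def test_same_seed_same_order(self):
        a = create_session(make_segments(20), ["s"], seed=9)
        b = create_session(make_segments(20), ["s"], seed=9)
        assert a.order == b.order
        assert a.blinded_ids == b.blinded_ids

    def test_entropy_seed_is_recorded(self):
        s = create_session(make_segments(3), ["s"])
        assert s.seed_source == "entropy"
        assert isinstance(s.seed, int)
        # the recorded seed reproduces the order
        assert fisher_yates_shuffle(3, s.seed) == s.order

    def test_zero_segments_or_stages_rejected(self):
        with pytest.raises(ValueError):
            create_session([], ["s"], seed=0)
        with pytest.raises(ValueError):
            create_session(make_segments(2), [], seed=0)

    def test_ids_carry_rank_not_identity(self):
        s = create_session(make_segments(60), ["s"], seed=4)
        # blinded ID of the segment at rank k is S{k+1}
        for k in range(60):
            assert s.id_for_rank(k) == f"S{k + 1:03d}"
        for bid in s.blinded_ids:
            assert not scan_for_leaks(bid, s.labels, s.source_names)


class TestScoringFlow:
    def test_next_then_score_advances(self, tmp_path):
        s = create_session(make_segments(3), ["activity"], seed=1)
        s.save(tmp_path / "session.json")
        first = next_segment(s)
        assert first.position == 1 and first.blinded_id == s.id_for_rank(0)
        record_score(s, first.blinded_id, {"activity": "high"})
        assert s.cursor == 1
        assert next_segment(s).blinded_id == s.id_for_rank(1)

    def test_out_of_turn_score_rejected(self):
        s = create_session(make_segments(3), ["a"], seed=1)
        wrong = s.id_for_rank(1)
        with pytest.raises(SequencingError):
            record_score(s, wrong, {"a": "x"})

    def test_missing_stage_notes_rejected(self):
        s = create_session(make_segments(2), ["a", "b"], seed=1)
        with pytest.raises(ValueError):
            record_score(s, s.id_for_rank(0), {"a": "x"})

    def test_done_marker_after_last_segment(self):
        s = create_session(make_segments(2), ["a"], seed=1)
        for _ in range(2):
            record_score(s, next_segment(s).blinded_id, {"a": ""})
        assert next_segment(s) is None
        with pytest.raises(SequencingError):
            record_score(s, "S001", {"a": ""})

    def test_blinded_bundle_leaks_nothing(self, tmp_path):
        s = create_session(make_segments(10, "plate_15mM_PTZ.avi"), ["a"], seed=2)
        s.save(tmp_path / "results" / "session.json")
        item = next_segment(s)
        text = repr(item) + item.describe() + str(item.media_path)
        assert scan_for_leaks(text, s.labels, s.source_names) == []


class TestPersistence:
    def test_save_load_roundtrip_is_field_for_field(self, tmp_path):
        s = create_session(make_segments(5), ["a", "b"], seed=3)
        record_score(s, s.id_for_rank(0), {"a": "x", "b": "y"})
        path = s.save(tmp_path / "session.json")
        loaded = resume_session(path)
        assert loaded.to_dict() == s.to_dict()

    def test_resume_accepts_directory(self, tmp_path):
        s = create_session(make_segments(2), ["a"], seed=3)
        s.save(tmp_path / "session.json")
        assert resume_session(tmp_path).session_id == s.session_id

    def test_tampered_permutation_refused(self, tmp_path):
        s = create_session(make_segments(4), ["a"], seed=3)
        path = s.save(tmp_path / "session.json")
        doc = json.loads(path.read_text())
        doc["order"][1] = doc["order"][0]  # duplicate index
        path.write_text(json.dumps(doc))
        with pytest.raises(SessionLoadError):
            resume_session(path)

    def test_cursor_score_mismatch_refused(self, tmp_path):
        s = create_session(make_segments(4), ["a"], seed=3)
        path = s.save(tmp_path / "session.json")
        doc = json.loads(path.read_text())
        doc["cursor"] = 2  # claims scores that are not there
        path.write_text(json.dumps(doc))
        with pytest.raises(SessionLoadError):
            resume_session(path)

    @pytest.mark.parametrize("content", ["", "{not json", '{"schema_version": 99}'])
    def test_corrupt_state_never_reshuffles(self, tmp_path, content):
        path = tmp_path / "session.json"
        path.write_text(content)
        with pytest.raises(SessionLoadError):
            resume_session(path)

    def test_absent_state_file(self, tmp_path):
        with pytest.raises(SessionLoadError):
            resume_session(tmp_path / "nope.json")

    def test_resume_equivalence_with_reload_after_every_score(self, tmp_path):
        stages = ["a"]
        notes = lambda k: {"a": f"obs {k}"}

        uninterrupted = create_session(make_segments(12), stages, seed=8)
        for k in range(12):
            record_score(uninterrupted, uninterrupted.id_for_rank(k), notes(k))

        s = create_session(make_segments(12), stages, seed=8)
        path = s.save(tmp_path / "session.json")
        for k in range(12):
            s = resume_session(path)  # simulate a restart before each score
            item = next_segment(s)
            record_score(s, item.blinded_id, notes(k))
        final = resume_session(path)
        assert final.order == uninterrupted.order
        assert {b: r.notes for b, r in final.scores.items()} == {
            b: r.notes for b, r in uninterrupted.scores.items()
        }
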