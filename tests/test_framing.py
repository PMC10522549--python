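import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tmsflow as tf
from tmsflow.framing import AlignmentError, TacParseError


class TestDefaultSchedule:
    def test_shape_and_total(self, schedule):
        assert schedule.n_frames == 40
        durs = schedule.durations
        assert np.all(durs[:28] == 5.0) and np.all(durs[28:] == 10.0)
        assert schedule.total_duration_s == 260.0
        assert round(schedule.total_duration_s / 60.0, 1) == 4.3

    def test_frame_29_starts_at_140(self, schedule):
        start, dur = schedule.frames[28]
        assert start == 140.0 and dur == 10.0

    def test_contiguity_enforced(self):
        with pytest.raises(ValueError, match="contiguous"):
            tf.FramingSchedule(((0.0, 5.0), (6.0, 5.0)))
        with pytest.raises(ValueError, match="duration"):
            tf.FramingSchedule(((0.0, 0.0),))
        with pytest.raises(ValueError, match="start at 0"):
            tf.FramingSchedule(((1.0, 5.0),))


class TestTimeActivityCurve:
    def test_length_checked(self, schedule):
        with pytest.raises(ValueError, match="length"):
            tf.TimeActivityCurve(schedule, np.ones(39))

    def test_negative_needs_noise_flag(self, schedule):
        vals = np.ones(40)
        vals[3] = -0.5
        with pytest.raises(ValueError, match="noise"):
            tf.TimeActivityCurve(schedule, vals)
        tac = tf.TimeActivityCurve(schedule, vals, noisy=True)
        assert tac.values[3] == -0.5

    def test_nonfinite_rejected(self, schedule):
        vals = np.ones(40)
        vals[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tf.TimeActivityCurve(schedule, vals)


class TestFrameWindowSum:
    def test_constant_curve(self, schedule):
        tac = tf.TimeActivityCurve(schedule, np.ones(40))
        assert tf.frame_window_sum(tac, 0.0, 120.0) == pytest.approx(120.0)

    def test_window_covers_24_frames(self, schedule):
        # 120 s of 5-s frames
        assert schedule.boundary_index(120.0) == 24

    def test_index_curve_hand_sum(self, schedule):
        tac = tf.TimeActivityCurve(schedule, np.arange(40, dtype=float))
        assert tf.frame_window_sum(tac, 0.0, 10.0) == pytest.approx(0 * 5 + 1 * 5)

    def test_unaligned_window_raises(self, schedule):
        tac = tf.TimeActivityCurve(schedule, np.ones(40))
        with pytest.raises(AlignmentError):
            tf.frame_window_sum(tac, 0.0, 122.5)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 39), st.integers(0, 39), st.integers(0, 39))
    def test_additivity_over_adjacent_windows(self, i, j, k):
        sched = tf.build_default_schedule()
        rng = np.random.default_rng(0)
        tac = tf.TimeActivityCurve(sched, rng.uniform(0, 10, 40))
        a, b, c = sorted([i, j, k])
        bounds = np.append(sched.starts, sched.total_duration_s)
        ta, tb, tc = bounds[a], bounds[b], bounds[c]
        if ta < tb < tc:
            total = tf.frame_window_sum(tac, ta, tc)
            split = tf.frame_window_sum(tac, ta, tb) + tf.frame_window_sum(tac, tb, tc)
            assert split == pytest.approx(total)


class TestTacIO:
    def test_json_roundtrip_bit_exact(self, schedule, tmp_path):
        rng = np.random.default_rng(1)
        tac = tf.TimeActivityCurve(schedule, rng.uniform(0, 200, 40), region_label="blood")
        path = tmp_path / "tac.json"
        tf.write_tac(tac, path, dialect="json")
        back = tf.read_tac(path)
        assert np.array_equal(back.values, tac.values)
        assert back.schedule.frames == tac.schedule.frames
        assert back.region_label == "blood"

    def test_csv_roundtrip_6_decimals(self, schedule, tmp_path):
        rng = np.random.default_rng(2)
        tac = tf.TimeActivityCurve(schedule, rng.uniform(0, 200, 40))
        path = tmp_path / "tac.csv"
        tf.write_tac(tac, path, dialect="csv")
        back = tf.read_tac(path)
        np.testing.assert_allclose(back.values, tac.values, atol=5e-7)

    def test_csv_missing_row_is_schema_error(self, schedule, tmp_path):
        tac = tf.TimeActivityCurve(schedule, np.ones(40))
        path = tmp_path / "tac.csv"
        tf.write_tac(tac, path, dialect="csv")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(TacParseError, match="inconsistent|frame"):
            # dropping the last row leaves a valid but shorter schedule;
            # dropping an interior row breaks contiguity
            path2 = tmp_path / "tac2.csv"
            path2.write_text("\n".join(lines[:5] + lines[6:]) + "\n")
            tf.read_tac(path2)

    def test_csv_bad_token_names_line_and_field(self, schedule, tmp_path):
        tac = tf.TimeActivityCurve(schedule, np.ones(40))
        path = tmp_path / "tac.csv"
        tf.write_tac(tac, path, dialect="csv")
        lines = path.read_text().splitlines()
        lines[3] = lines[3].rsplit(",", 1)[0] + ",oops"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TacParseError, match="line 4.*value_kBq_per_mL.*oops"):
            tf.read_tac(path)

    def test_json_length_mismatch(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"frames": [[0, 5], [5, 5]], "values": [1.0]}')
        with pytest.raises(TacParseError, match="values"):
            tf.read_tac(path)
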