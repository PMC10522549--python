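import numpy as np
import pytest

import tmsflow as tf
from tmsflow.conv import exp_conv_frame_avg
from tmsflow.framing import TimeActivityCurve
from tmsflow.kinetics import RetentionConfig, fit_1tcm, retention_mbf


def _forward(aif, mbf, k2=0.15, pv=0.85, spill=0.0):
    return tf.forward_tissue_tac(aif, mbf, k2, pv_recovery=pv, spillover=spill)


class TestRetention:
    def test_zero_tissue_gives_zero_flow(self, bolus_aif, schedule):
        tissue = TimeActivityCurve(schedule, np.zeros(40))
        res = retention_mbf(bolus_aif, tissue)
        assert res.mbf == 0.0

    @pytest.mark.parametrize("mbf", [0.15, 0.25, 0.5, 1.0])
    def test_noiseless_recovery_within_10pct(self, bolus_aif, mbf):
        tissue = _forward(bolus_aif, mbf)
        res = retention_mbf(bolus_aif, tissue, RetentionConfig())
        assert res.mbf == pytest.approx(mbf, rel=0.10)

    def test_halved_blood_doubles_retention(self, bolus_aif, schedule):
        tissue = _forward(bolus_aif, 0.25)
        r1 = retention_mbf(bolus_aif, tissue)
        half = bolus_aif.with_values(bolus_aif.values * 0.5)
        r2 = retention_mbf(half, tissue)
        assert r2.retention == pytest.approx(2 * r1.retention, rel=1e-9)
        assert r2.mbf > r1.mbf

    def test_input_scale_knob_monotone(self, bolus_aif):
        tissue = _forward(bolus_aif, 0.4)
        flows = [
            retention_mbf(bolus_aif, tissue, RetentionConfig(input_scale=s)).mbf
            for s in (1.2, 1.0, 0.8, 0.6)
        ]
        assert np.all(np.diff(flows) > 0)

    def test_refuses_uncorrected_curves(self, bolus_aif, schedule):
        tissue = TimeActivityCurve(schedule, np.ones(40), decay_corrected=False)
        with pytest.raises(ValueError, match="decay-corrected"):
            retention_mbf(bolus_aif, tissue)

    def test_zero_blood_is_input_error(self, schedule):
        blood = TimeActivityCurve(schedule, np.zeros(40))
        tissue = TimeActivityCurve(schedule, np.ones(40))
        with pytest.raises(ValueError, match="input"):
            retention_mbf(blood, tissue)


class TestOneTissueFit:
    def test_self_consistency_within_1pct(self, bolus_aif, schedule):
        k1, k2, vb = 0.30, 0.15, 0.10
        conv = exp_conv_frame_avg(schedule.durations, bolus_aif.values, k2 / 60) / 60
        m = (1 - vb) * k1 * conv + vb * bolus_aif.values
        res = fit_1tcm(bolus_aif, TimeActivityCurve(schedule, m))
        assert res.k1 == pytest.approx(k1, rel=0.01)
        assert res.k2 == pytest.approx(k2, rel=0.01)
        assert res.spillover_fraction == pytest.approx(vb, abs=0.005)
        assert res.converged

    def test_all_zero_tissue_returns_zero_k1(self, bolus_aif, schedule):
        res = fit_1tcm(bolus_aif, TimeActivityCurve(schedule, np.zeros(40)))
        assert res.k1 == 0.0 and res.spillover_fraction == 0.0

    def test_recovers_phantom_flow_with_pv_and_spill(self, bolus_aif):
        for mbf in (0.15, 0.25, 0.5, 1.0):
            tissue = _forward(bolus_aif, mbf, spill=0.10)
            res = fit_1tcm(bolus_aif, tissue, pv_recovery=0.85)
            assert res.mbf == pytest.approx(mbf, rel=0.10)
            assert res.spillover_fraction == pytest.approx(0.10, abs=0.02)

    def test_fixed_dv_equal_to_true_dv_matches_free_fit(self, bolus_aif, schedule):
        k1, k2, vb = 0.40, 0.20, 0.10
        conv = exp_conv_frame_avg(schedule.durations, bolus_aif.values, k2 / 60) / 60
        m = (1 - vb) * k1 * conv + vb * bolus_aif.values
        tissue = TimeActivityCurve(schedule, m)
        free = fit_1tcm(bolus_aif, tissue)
        fixed = fit_1tcm(bolus_aif, tissue, fixed_dv=k1 / k2)
        assert fixed.k1 == pytest.approx(free.k1, rel=0.01)
        assert fixed.dv == k1 / k2  # exactly the configured constant

    def test_wrong_fixed_dv_biases_k1(self, bolus_aif, schedule):
        # generated with DV = 2.0, fit with DV pinned at 0.8
        k1, vb = 0.30, 0.05
        k2 = k1 / 2.0
        conv = exp_conv_frame_avg(schedule.durations, bolus_aif.values, k2 / 60) / 60
        m = (1 - vb) * k1 * conv + vb * bolus_aif.values
        tissue = TimeActivityCurve(schedule, m)
        res = fit_1tcm(bolus_aif, tissue, fixed_dv=0.8)
        assert abs(res.k1 - k1) / k1 > 0.05

    def test_too_few_frames_rejected(self):
        sched = tf.FramingSchedule(tuple((i * 5.0, 5.0) for i in range(8)))
        blood = TimeActivityCurve(sched, np.ones(8))
        with pytest.raises(ValueError, match="frames"):
            fit_1tcm(blood, blood)


@pytest.fixture(scope="module")
def variant():
    return tf.EstimatorVariant("ret", "retention", "la_aorta")


class TestEstimateStudy:
    def test_whole_heart_within_10pct_of_truth(self, clean_study, variant):
        est = tf.estimate_study(clean_study, variant)
        truth = clean_study.flow_map.area_weighted_mean_mbf * clean_study.flow_scale
        assert est.whole_heart_mbf == pytest.approx(truth, rel=0.10)

    def test_deterministic(self, clean_study, variant):
        a = tf.estimate_study(clean_study, variant)
        b = tf.estimate_study(clean_study, variant)
        assert np.array_equal(a.fine_mbf, b.fine_mbf)
        assert a.seg_table.df.equals(b.seg_table.df)

    def test_biased_input_raises_every_sector(self, clean_study, variant):
        base = tf.estimate_study(clean_study, variant)
        biased = tf.estimate_study(
            clean_study,
            tf.EstimatorVariant("ret_b", "retention", "la_aorta", input_scale=0.7),
        )
        assert np.all(biased.fine_mbf >= base.fine_mbf)
        assert biased.whole_heart_mbf > base.whole_heart_mbf

    def test_1tcm_study_estimate_close_to_truth(self, clean_study):
        est = tf.estimate_study(
            clean_study, tf.EstimatorVariant("k", "1tcm_free_dv", "la_aorta")
        )
        truth = clean_study.flow_map.area_weighted_mean_mbf * clean_study.flow_scale
        assert est.whole_heart_mbf == pytest.approx(truth, rel=0.10)

    def test_missing_input_location(self, clean_study, variant):
        bad = tf.EstimatorVariant("x", "retention", "subclavian")
        with pytest.raises(KeyError):
            tf.estimate_study(clean_study, bad)

    def test_segment_table_well_formed(self, noisy_studies, variant):
        est = tf.estimate_study(noisy_studies[0], variant)
        df = est.seg_table.df
        assert sorted(df["segment_id"]) == list(range(1, 18))
        assert df["ru_percent"].max() == pytest.approx(100.0)
        assert (df["rmbf"] >= 0).all()
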