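import numpy as np
import pytest

import tmsflow as tf
from tmsflow.phantom import make_flow_map, SCAR_BAND, BORDER_BAND, NORMAL_BAND
from tmsflow.segments import PolarGrid


class TestFlowMap:
    def test_bands_and_contiguity(self):
        grid = PolarGrid()
        rng = np.random.default_rng(0)
        fm = make_flow_map(grid, rng, scar_center_deg=270.0, scar_extent_deg=100.0)
        scar = fm.true_mbf[fm.scar_mask]
        assert SCAR_BAND[0] - 1e-9 <= scar.min() and scar.max() <= SCAR_BAND[1] + 1e-9
        border = fm.true_mbf[fm.border_mask]
        assert BORDER_BAND[0] - 1e-9 <= border.min() and border.max() <= BORDER_BAND[1] + 1e-9
        normal = fm.true_mbf[fm.normal_mask]
        assert NORMAL_BAND[0] - 1e-9 <= normal.min() and normal.max() <= NORMAL_BAND[1] + 1e-9
        assert len(grid.connected_components(fm.scar_mask)) == 1

    def test_scar_size_tracks_extent(self):
        grid = PolarGrid()
        rng = np.random.default_rng(1)
        fm = make_flow_map(grid, rng, 180.0, 100.0)
        # wedge over the three myocardial rings: extent/360 * 16/17 of LV
        assert fm.scar_pct_lv == pytest.approx(100 * (100 / 360) * (16 / 17), abs=2.0)

    def test_noncontiguous_scar_rejected(self):
        grid = PolarGrid()
        mask = np.zeros(grid.n_sectors, dtype=bool)
        mask[0] = mask[30] = True  # two disjoint sectors
        with pytest.raises(ValueError, match="contiguous"):
            tf.GroundTruthFlowMap(
                grid=grid,
                true_mbf=np.full(grid.n_sectors, 0.25),
                scar_mask=mask,
                border_mask=np.zeros(grid.n_sectors, dtype=bool),
                scar_band=(0.0, 1.0),
            )


class TestSimulate:
    def test_deterministic_under_fixed_seed(self):
        spec = tf.random_phantom_spec(3, noise_level=0.0, flow_jitter_sd=0.0)
        a = tf.simulate_phantom(spec)
        b = tf.simulate_phantom(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.tissue, sb.tissue)
            for loc in sa.blood:
                assert np.array_equal(sa.blood[loc].values, sb.blood[loc].values)

    def test_noise_reproducible_and_independent_across_scans(self):
        spec = tf.random_phantom_spec(3)
        a = tf.simulate_phantom(spec)
        b = tf.simulate_phantom(spec)
        assert np.array_equal(a[0].tissue, b[0].tissue)
        assert not np.array_equal(a[0].tissue, a[1].tissue)

    def test_three_scans_share_one_flow_map(self):
        spec = tf.random_phantom_spec(4)
        studies = tf.simulate_phantom(spec)
        assert len(studies) == 3
        assert all(s.flow_map is spec.flow_map for s in studies)

    def test_noiseless_min_uptake_inside_scar(self, clean_study):
        """The minimum late-window relative uptake falls inside the scar mask."""
        sched = clean_study.schedule
        sel = sched.starts >= 140.0
        uptake = clean_study.tissue[:, sel].mean(axis=1)
        assert clean_study.flow_map.scar_mask[int(np.argmin(uptake))]

    def test_uptake_monotone_in_true_flow(self, clean_study):
        sched = clean_study.schedule
        sel = sched.starts >= 140.0
        uptake = clean_study.tissue[:, sel].mean(axis=1)
        order = np.argsort(clean_study.flow_map.true_mbf)
        assert np.all(np.diff(uptake[order]) > -1e-9)

    def test_scan_profiles_follow_protocol(self):
        spec = tf.random_phantom_spec(8)
        assert set(spec.scan_profiles[:2]) == {"bolus_50", "slow_20"}
        assert spec.scan_profiles[2] in {"bolus_50", "slow_20"}


class TestArtifacts:
    def test_saturation_clips_at_ceiling(self, clean_study):
        st = tf.inject_artifact(clean_study, "saturation", ceiling_fraction=0.8)
        for loc in st.blood:
            orig = clean_study.blood[loc].values
            assert st.blood[loc].values.max() == pytest.approx(0.8 * orig.max())

    def test_abrupt_motion_preserves_early_frames(self, clean_study):
        st = tf.inject_artifact(clean_study, "abrupt_motion", at_s=130.0, shift_sectors=2)
        early = clean_study.schedule.starts < 130.0
        assert np.array_equal(st.tissue[:, early], clean_study.tissue[:, early])
        assert not np.array_equal(st.tissue[:, ~early], clean_study.tissue[:, ~early])

    def test_frame_duration_changes_schedule_only(self, clean_study):
        st = tf.inject_artifact(clean_study, "frame_duration", index=29, new_duration_s=12.0)
        assert st.schedule.durations[29] == 12.0
        assert st.schedule.frames != clean_study.schedule.frames
        assert np.array_equal(st.tissue, clean_study.tissue)

    def test_spillover_excess_adds_blood(self, clean_study):
        st = tf.inject_artifact(clean_study, "spillover_excess", fraction=0.7)
        delta = st.tissue - clean_study.tissue
        base = clean_study.spec.spillover_per_sector()
        ref = clean_study.blood["la_aorta"].values
        np.testing.assert_allclose(delta, (0.7 - base)[:, None] * ref[None, :])

    def test_unknown_kind_rejected(self, clean_study):
        with pytest.raises(ValueError, match="artifact kind"):
            tf.inject_artifact(clean_study, "gamma_ray_burst")

    def test_input_does_not_mutate(self, clean_study):
        before = clean_study.tissue.copy()
        tf.inject_artifact(clean_study, "gradual_motion")
        assert np.array_equal(clean_study.tissue, before)


class TestSpecValidation:
    def test_bad_spillover(self):
        spec = tf.random_phantom_spec(0)
        with pytest.raises(ValueError):
            tf.PhantomSpec(flow_map=spec.flow_map, blood_spillover_fraction=1.2)

    def test_artifact_plan_checked(self):
        spec = tf.random_phantom_spec(0)
        with pytest.raises(ValueError, match="artifact"):
            tf.PhantomSpec(flow_map=spec.flow_map, artifact_plan=((0, "nope", {}),))

    def test_artifact_plan_applied_to_designated_scan(self):
        base = tf.random_phantom_spec(0, noise_level=0.0, flow_jitter_sd=0.0)
        import dataclasses

        spec = dataclasses.replace(
            base, artifact_plan=((1, "flat_tail", {}),)
        )
        studies = tf.simulate_phantom(spec)
        assert studies[0].artifacts == ()
        assert studies[1].artifacts == ("flat_tail",)
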