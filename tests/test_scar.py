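import numpy as np
import pytest

import tmsflow as tf
from tmsflow.scar import (
    SegScarCriteria,
    classify_segments,
    compute_relative_uptake,
    identify_roi_scar,
    segment_rest_score,
)
from tmsflow.segments import PolarGrid, SegmentTable, aha_neighbors


class TestRelativeUptake:
    def test_proportionality(self):
        np.testing.assert_allclose(compute_relative_uptake([2, 1, 4]), [50, 25, 100])

    def test_uniform_map(self):
        np.testing.assert_allclose(compute_relative_uptake(np.ones(5)), 100.0)

    def test_constructed_scar_fraction(self):
        vals = np.array([0.43, 1.0, 0.9])
        assert compute_relative_uptake(vals)[0] == pytest.approx(43.0)

    def test_all_zero_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_relative_uptake(np.zeros(3))


class TestRestScore:
    @pytest.mark.parametrize("ru, score", [(100, 0), (43, 2), (5, 4), (70, 0), (69, 1), (34, 3)])
    def test_bins(self, ru, score):
        assert segment_rest_score(ru) == score

    def test_monotone_non_increasing(self):
        scores = [segment_rest_score(r) for r in range(0, 101)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            segment_rest_score(101)


class TestRoiScar:
    def test_uniform_map_empty_roi(self):
        grid = PolarGrid()
        out = identify_roi_scar(np.ones(grid.n_sectors), np.ones(grid.n_sectors), grid)
        assert out["empty_roi"] and out["roi_size_pct_lv"] == 0.0

    def test_constructed_block_size(self):
        """A contiguous wedge at 43 %RU covering ~26% of the LV."""
        grid = PolarGrid()
        mask = grid.wedge_mask(270.0, 99.5)  # ~26 %LV over three rings
        uptake = np.ones(grid.n_sectors)
        uptake[mask] = 0.43
        rmbf = np.where(mask, 0.25, 0.8)
        out = identify_roi_scar(uptake, rmbf, grid)
        assert out["roi_size_pct_lv"] == pytest.approx(26.0, abs=1.0)
        assert out["roi_mean_ru"] == pytest.approx(43.0)
        assert out["roi_mean_rmbf"] == pytest.approx(0.25)

    def test_largest_component_wins(self):
        grid = PolarGrid()
        big = grid.wedge_mask(90.0, 80.0)    # ~20 %LV
        small = grid.wedge_mask(270.0, 20.0)  # ~5 %LV, disjoint
        uptake = np.ones(grid.n_sectors)
        uptake[big | small] = 0.40
        rmbf = np.full(grid.n_sectors, 0.5)
        out = identify_roi_scar(uptake, rmbf, grid)
        assert out["roi_size_pct_lv"] == pytest.approx(100 * 80 / 360 * 16 / 17, abs=1.0)
        assert out["secondary_defect_pct_lv"] == pytest.approx(100 * 20 / 360 * 16 / 17, abs=1.0)


def _table(ru_by_segment, rmbf_by_segment):
    ru = np.full(17, 100.0)
    rmbf = np.full(17, 0.8)
    for sid, v in ru_by_segment.items():
        ru[sid - 1] = v
    for sid, v in rmbf_by_segment.items():
        rmbf[sid - 1] = v
    return SegmentTable.from_arrays(rmbf, ru, [segment_rest_score(r) for r in ru])


class TestClassifySegments:
    def test_inferior_scar_partition(self):
        """Full coverage of segments 4, 10, 15 and 30% of 3 and 9."""
        grid = PolarGrid()
        seg = grid.segment_of
        mask = np.isin(seg, [4, 10, 15])
        for sid in (3, 9):
            members = np.where(seg == sid)[0]
            mask[members[: int(0.3 * len(members))]] = True
        table = _table(
            {3: 60, 4: 43, 9: 60, 10: 43, 15: 43},
            {3: 0.5, 4: 0.25, 9: 0.5, 10: 0.25, 15: 0.28},
        )
        out = classify_segments(table, mask, grid)
        assert out["seg_scar"] == (4, 10, 15)
        assert out["seg_border"] == (3, 9)
        assert len(out["seg_norm"]) == 12
        assert out["seg_scar_mean_rmbf"] == pytest.approx((0.25 + 0.25 + 0.28) / 3)
        assert out["lowest_segment_rmbf"] == pytest.approx(0.25)

    def test_low_coverage_goes_to_border(self):
        grid = PolarGrid()
        seg = grid.segment_of
        mask = np.isin(seg, [4])
        members = np.where(seg == 10)[0]
        mask_partial = mask.copy()
        mask_partial[members[: int(0.4 * len(members))]] = True
        table = _table({4: 43, 10: 60}, {4: 0.25, 10: 0.5})
        out = classify_segments(table, mask_partial, grid)
        assert 4 in out["seg_scar"]
        assert 10 in out["seg_border"]  # fails the >50% coverage criterion

    def test_tightening_criteria_never_enlarges_seg_scar(self, noisy_studies):
        variant = tf.EstimatorVariant("ret", "retention", "la_aorta")
        est = tf.estimate_study(noisy_studies[0], variant)
        grid = noisy_studies[0].grid
        roi = identify_roi_scar(est.fine_ru, est.fine_mbf, grid)
        loose = classify_segments(est.seg_table, roi["roi_mask"], grid, SegScarCriteria())
        for tightened in (
            SegScarCriteria(defect_coverage_threshold=0.7),
            SegScarCriteria(segment_score_min=3),
            SegScarCriteria(ru_max_percent=50.0),
        ):
            tight = classify_segments(est.seg_table, roi["roi_mask"], grid, tightened)
            assert set(tight["seg_scar"]) <= set(loose["seg_scar"])

    def test_partition_and_contiguity_on_random_phantoms(self):
        nbrs = aha_neighbors()
        variant = tf.EstimatorVariant("ret", "retention", "la_aorta")
        for seed in range(6):
            spec = tf.random_phantom_spec(seed, n_rest_scans=1)
            study = tf.simulate_phantom(spec)[0]
            est = tf.estimate_study(study, variant)
            sa = tf.analyze_scar(est.fine_ru, est.fine_mbf, est.seg_table, study.grid)
            ids = set(sa.seg_scar) | set(sa.seg_border) | set(sa.seg_norm)
            assert ids == set(range(1, 18))
            if len(sa.seg_scar) > 1:
                # contiguity: each scar segment touches another scar segment
                for sid in sa.seg_scar:
                    assert nbrs[sid] & set(sa.seg_scar)
            if not sa.empty_roi:
                assert sa.roi_min_rmbf <= sa.roi_mean_rmbf + 1e-12


class TestAdjacency:
    def test_apex_adjacent_to_apical_segments(self):
        nbrs = aha_neighbors()
        assert nbrs[17] == frozenset({13, 14, 15, 16})

    def test_symmetric(self):
        nbrs = aha_neighbors()
        for a in range(1, 18):
            for b in nbrs[a]:
                assert a in nbrs[b]
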