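"""Time-course extraction, Pearson/Fisher machinery, contrast maps, ISPS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from narsync import (
    build_condition_cells,
    build_general_cells,
    compute_contrast_maps,
    extract_video_timecourses,
    fisher_z,
    loo_average,
    make_design,
    spatial_pattern_similarity,
    subject_contrast,
    voxelwise_correlation,
)
from narsync.design import Cell, POOL_ALL


def _naive_pearson(a, b):
    """Two-pass covariance-formula oracle, one voxel row at a time."""
    t = min(a.shape[1], b.shape[1])
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        x, y = a[i, :t], b[i, :t]
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        denom = x.std() * y.std()
        out[i] = cov / denom if denom > 0 else np.nan
    return out


class TestExtraction:
    def test_trim_arithmetic(self, small_design):
        """duration 13 with trim 2 leaves 11 timepoints; 2 TRs = 5.24 s."""
        data = np.random.default_rng(0).standard_normal(
            (3, 3, 3, small_design.n_volumes))
        mask = np.ones((3, 3, 3), bool)
        tcs = extract_video_timecourses(data, mask, small_design)
        for v in small_design.video_ids:
            assert tcs[v].shape == (27, 11)
        assert small_design.trim_seconds == pytest.approx(5.24)

    def test_zero_trim_is_identity(self):
        design = make_design(n_videos=2, n_runs=1, trim_volumes=0,
                             duration_volumes=5, gap_volumes=0)
        data = np.arange(2 * 10, dtype=float).reshape(1, 1, 2, 10)
        mask = np.ones((1, 1, 2), bool)
        tcs = extract_video_timecourses(data, mask, design)
        v0 = design.video_ids[0]
        onset = design.onsets_volumes[v0]
        np.testing.assert_array_equal(tcs[v0], data[0, 0, :, onset:onset + 5])

    def test_errors(self, small_design):
        mask = np.ones((2, 2, 2), bool)
        short = np.zeros((2, 2, 2, 5))
        with pytest.raises(ValueError, match="exceeds"):
            extract_video_timecourses(short, mask, small_design)
        long = np.zeros((2, 2, 2, 100))
        with pytest.raises(ValueError, match="empty"):
            extract_video_timecourses(long, np.zeros((2, 2, 2), bool), small_design)


class TestLooAverage:
    def test_pool_of_two_returns_the_other(self):
        pool = {"a": np.ones((2, 5)), "b": np.full((2, 5), 3.0)}
        np.testing.assert_array_equal(loo_average(pool, "a"), pool["b"])

    def test_identical_members(self):
        ts = np.random.default_rng(1).standard_normal((3, 6))
        pool = {s: ts.copy() for s in "abc"}
        np.testing.assert_allclose(loo_average(pool, "b"), ts)

    def test_hand_computed_mean_of_three(self):
        pool = {
            "a": np.array([[1.0, 2.0, 3.0]]),
            "b": np.array([[3.0, 4.0, 5.0]]),
            "c": np.array([[5.0, 6.0, 10.0]]),
        }
        np.testing.assert_array_equal(
            loo_average(pool, "a"), np.array([[4.0, 5.0, 7.5]])
        )

    def test_held_out_must_be_member(self):
        with pytest.raises(KeyError):
            loo_average({"a": np.zeros((1, 3))}, "zz")


class TestVoxelwiseCorrelation:
    def test_self_and_anti_correlation(self):
        a = np.random.default_rng(2).standard_normal((4, 8))
        np.testing.assert_allclose(voxelwise_correlation(a, a), 1.0)
        np.testing.assert_allclose(voxelwise_correlation(a, -a), -1.0)

    def test_against_scipy_on_fixed_vectors(self):
        a = np.array([[1.0, 2.0, 3.0, 4.0]])
        b = np.array([[2.0, 4.0, 5.0, 9.0]])
        expected = stats.pearsonr(a[0], b[0]).statistic
        assert voxelwise_correlation(a, b)[0] == pytest.approx(expected, abs=1e-12)

    def test_against_naive_oracle_random(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((500, 12))
        b = rng.standard_normal((500, 12))
        np.testing.assert_allclose(
            voxelwise_correlation(a, b), _naive_pearson(a, b), atol=1e-10
        )

    def test_truncates_to_shorter(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((3, 10))
        b = rng.standard_normal((3, 7))
        np.testing.assert_allclose(
            voxelwise_correlation(a, b), voxelwise_correlation(a[:, :7], b)
        )

    def test_zero_variance_flagged(self):
        a = np.vstack([np.ones(5), np.arange(5.0)])
        b = np.tile(np.arange(5.0), (2, 1))
        r = voxelwise_correlation(a, b)
        assert np.isnan(r[0]) and r[1] == pytest.approx(1.0)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 overlapping"):
            voxelwise_correlation(np.zeros((1, 2)), np.zeros((1, 2)))

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 2**20),
    )
    def test_affine_invariance(self, scale, offset, seed):
        """Pearson r is unchanged by positive-slope affine rescaling."""
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((5, 9))
        b = rng.standard_normal((5, 9))
        r0 = voxelwise_correlation(a, b)
        r1 = voxelwise_correlation(scale * a + offset, b)
        np.testing.assert_allclose(r0, r1, atol=1e-8)


class TestFisherZ:
    def test_fixed_points(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_boundary_is_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1.0 - 1e-7))
        assert fisher_z(-1.0) == -fisher_z(1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_nan_propagates(self):
        assert np.isnan(fisher_z(np.nan))


class TestSubjectContrast:
    def _cells(self, n_pos, n_neg):
        pos = [Cell("s", f"v{i}", f"v{i}", POOL_ALL, "same", 1.0 / n_pos)
               for i in range(n_pos)]
        neg = [Cell("s", f"v{i}", f"w{i}", POOL_ALL, "different", -1.0 / n_neg)
               for i in range(n_neg)]
        return pos + neg

    def test_equal_z_gives_zero(self):
        cells = self._cells(3, 6)
        z = {c: np.full(4, 0.7) for c in cells}
        np.testing.assert_allclose(subject_contrast(cells, z), 0.0, atol=1e-12)

    def test_mean_difference(self):
        """20 same cells at z=1.0 vs 80 different at z=0.2 -> contrast 0.8."""
        cells = self._cells(20, 80)
        z = {c: np.full(2, 1.0 if c.weight > 0 else 0.2) for c in cells}
        np.testing.assert_allclose(subject_contrast(cells, z), 0.8)

    def test_missing_cells_error(self):
        cells = self._cells(2, 2)
        with pytest.raises(ValueError, match="missing"):
            subject_contrast(cells, {cells[0]: np.zeros(2)})


class TestContrastPipeline:
    def test_noise_free_same_video_isc_is_one(self, small_design, small_assignment):
        """With no noise and no boost every same-video correlation is 1."""
        from narsync import BoldSimConfig, simulate_bold_cohort

        cfg = BoldSimConfig(
            n_subjects=8, grid_shape=(3, 3, 3), design=small_design,
            assignment=small_assignment, shared_gain_base=1.0,
            noise_sd=1e-12, seed=5,
        )
        cohort = simulate_bold_cohort(cfg)
        mask = np.ones((3, 3, 3), bool)
        tcs = {s: extract_video_timecourses(v, mask, small_design)
               for s, v in cohort.data.items()}
        for s in small_assignment.subject_ids:
            for v in small_design.video_ids:
                ref = loo_average({t: tcs[t][v] for t in tcs}, s)
                r = voxelwise_correlation(tcs[s][v], ref)
                np.testing.assert_allclose(r, 1.0, atol=1e-6)

    def test_bit_identical_contrast_maps(self, small_design, small_assignment,
                                         small_cohort, full_mask):
        tcs = {s: extract_video_timecourses(v, full_mask, small_design)
               for s, v in small_cohort.data.items()}
        cells = build_general_cells(small_design, small_assignment.subject_ids)
        m1 = compute_contrast_maps(tcs, cells)
        m2 = compute_contrast_maps(tcs, cells)
        for s in m1:
            assert np.array_equal(m1[s], m2[s])

    def test_missing_video_drops_subject_from_pools(self, small_design,
                                                    small_assignment,
                                                    small_cohort, full_mask):
        tcs = {s: extract_video_timecourses(v, full_mask, small_design)
               for s, v in small_cohort.data.items()}
        victim = small_assignment.subject_ids[0]
        gone = small_design.video_ids[0]
        del tcs[victim][gone]
        cells = build_general_cells(small_design, small_assignment.subject_ids)
        maps = compute_contrast_maps(tcs, cells)
        assert set(maps) == set(small_assignment.subject_ids)
        assert all(np.isfinite(m).all() for m in maps.values())


class TestSpatialPatternSimilarity:
    def test_shared_pattern_contrast(self, small_design, small_assignment):
        """All subjects share per-video patterns -> same-video r = 1 exactly."""
        rng = np.random.default_rng(6)
        pattern = {v: rng.standard_normal(27) for v in small_design.video_ids}
        tcs = {
            s: {v: np.tile(pattern[v][:, None], (1, 11)) for v in pattern}
            for s in small_assignment.subject_ids
        }
        cells = build_general_cells(small_design, small_assignment.subject_ids)
        out = spatial_pattern_similarity(tcs, cells, np.arange(27))
        # same-video r = 1 (z = arctanh(1 - eps)); different-video r < 1
        assert all(v > 0 for v in out.values())

    def test_small_roi_rejected(self, small_design, small_assignment):
        tcs = {s: {} for s in small_assignment.subject_ids}
        cells = build_general_cells(small_design, small_assignment.subject_ids)
        with pytest.raises(ValueError, match="10 voxels"):
            spatial_pattern_similarity(tcs, cells, np.arange(5))

    def test_orthogonal_patterns_give_zero_r(self):
        """Centered-orthogonal vectors correlate at ~0 by the direct formula."""
        rng = np.random.default_rng(7)
        a = rng.standard_normal(12)
        a -= a.mean()
        b = rng.standard_normal(12)
        b -= b.mean()
        b -= (a @ b) / (a @ a) * a  # orthogonalize
        r = voxelwise_correlation(a[None, :], b[None, :])[0]
        assert r == pytest.approx(0.0, abs=1e-10)
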