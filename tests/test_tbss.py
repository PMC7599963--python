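"""Skeleton extraction, projection, TFCE, permutation FWE, ROI report."""
import numpy as np
import pytest

from dwimicro import (
    InferenceConfig, LabelMap, ScalarMap, ValidationError, VolumeGrid,
    build_skeleton, permutation_fwe, project_to_skeleton, roi_report,
    tfce_enhance,
)
from dwimicro._tfce import tfce_graph
from dwimicro.tbss import (
    SkeletonModel, StatMaps, projection_indices, skeleton_adjacency,
)


def tube_fa_map(shape=(24, 20, 12), center=(10.0, 6.0), radius=3.0,
                fa_in=0.6, fa_out=0.1, voxel_mm=2.0) -> ScalarMap:
    """FA volume with a straight x-aligned tube of given voxel radius."""
    grid = VolumeGrid.isotropic(shape, voxel_mm)
    jj, kk = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]),
                         indexing="ij")
    dist = np.hypot(jj - center[0], kk - center[1])
    section = np.where(dist <= radius, fa_in, fa_out)
    return ScalarMap(grid, "FA", np.broadcast_to(section, shape).copy())


class TestBuildSkeleton:
    def test_tube_skeleton_is_the_centerline_within_one_voxel(self):
        fa = tube_fa_map()
        sk = build_skeleton([fa, fa])
        assert sk.n_voxels > 10
        dist = np.hypot(sk.indices[:, 1] - 10.0, sk.indices[:, 2] - 6.0)
        assert dist.max() <= 1.0

    def test_uniform_subthreshold_fa_gives_empty_skeleton(self):
        grid = VolumeGrid.isotropic((10, 10, 10), 2.0)
        fa = ScalarMap(grid, "FA", np.full(grid.shape, 0.15))
        sk = build_skeleton([fa, fa])
        assert sk.n_voxels == 0

    def test_arc_skeleton_follows_the_analytic_centerline(self):
        grid = VolumeGrid.isotropic((30, 30, 10), 2.0)
        ii, jj, kk = np.indices(grid.shape).astype(float)
        x, y, z = ii * 2.0, jj * 2.0, kk * 2.0
        r = np.hypot(x - 10.0, y - 10.0)
        dist = np.sqrt((r - 36.0) ** 2 + (z - 10.0) ** 2)
        phi = np.arctan2(y - 10.0, x - 10.0)
        inside = (dist <= 6.0) & (phi > 0.1) & (phi < np.pi / 2 - 0.1)
        fa = ScalarMap(grid, "FA", np.where(inside, 0.6, 0.1))
        sk = build_skeleton([fa, fa])
        assert sk.n_voxels > 10
        pts = sk.indices * 2.0
        d = np.sqrt((np.hypot(pts[:, 0] - 10.0, pts[:, 1] - 10.0) - 36.0) ** 2
                    + (pts[:, 2] - 10.0) ** 2) / 2.0
        assert d.max() <= 1.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 subjects"):
            build_skeleton([tube_fa_map()])


class TestProjection:
    def test_constant_measure_projects_to_the_constant(self):
        fa = tube_fa_map()
        sk = build_skeleton([fa, fa])
        md = ScalarMap(fa.grid, "MD", np.full(fa.grid.shape, 0.7e-3))
        proj = project_to_skeleton(sk, md, subject_fa=fa)
        assert np.allclose(proj, 0.7e-3)

    def test_offset_subject_ridge_supplies_the_source_voxel(self):
        """A subject whose FA ridge sits one voxel off the skeleton must
        contribute its own ridge voxel's value, not the skeleton voxel's."""
        fa_cohort = tube_fa_map(center=(10.0, 6.0))
        sk = build_skeleton([fa_cohort, fa_cohort])
        # subject ridge peaked at (y, z) = (11, 6), one voxel off the skeleton
        grid = fa_cohort.grid
        jj, kk = np.meshgrid(np.arange(grid.shape[1]), np.arange(grid.shape[2]),
                             indexing="ij")
        profile = 0.6 * np.exp(-(np.hypot(jj - 11.0, kk - 6.0) ** 2) / 8.0)
        subject_fa = ScalarMap(grid, "FA",
                               np.broadcast_to(profile, grid.shape).copy())
        ad_values = np.zeros(fa_cohort.grid.shape)
        ad_values[:, 11, 6] = 2.0e-3                     # marker on the ridge
        ad = ScalarMap(fa_cohort.grid, "AD", ad_values)
        idx = projection_indices(sk, subject_fa)
        proj = project_to_skeleton(sk, ad, indices=idx)
        on_axis = np.hypot(sk.indices[:, 1] - 10.0, sk.indices[:, 2] - 6.0) < 0.5
        # hand-computed: the search must land on (x, 11, 6)
        expected = np.ravel_multi_index(
            (sk.indices[on_axis, 0], np.full(on_axis.sum(), 11),
             np.full(on_axis.sum(), 6)), fa_cohort.grid.shape)
        assert np.array_equal(idx[on_axis], expected)
        assert np.allclose(proj[on_axis], 2.0e-3)

    def test_projected_own_fa_dominates_the_point_value(self):
        fa_cohort = tube_fa_map()
        sk = build_skeleton([fa_cohort, fa_cohort])
        rng = np.random.default_rng(0)
        vals = np.clip(fa_cohort.values + rng.normal(0, 0.05,
                                                     fa_cohort.grid.shape),
                       0, 1)
        subject_fa = ScalarMap(fa_cohort.grid, "FA", vals)
        proj = project_to_skeleton(sk, subject_fa, subject_fa=subject_fa)
        at_voxel = subject_fa.values[tuple(sk.indices.T)]
        assert np.all(proj >= at_voxel - 1e-12)

    def test_wrong_index_count_rejected(self):
        fa = tube_fa_map()
        sk = build_skeleton([fa, fa])
        with pytest.raises(ValidationError, match="projection index"):
            project_to_skeleton(sk, fa, indices=np.zeros(3, np.int64))


class TestTfce:
    def test_zero_map_enhances_to_zero(self):
        out = tfce_enhance(np.zeros((5, 5, 5)))
        assert np.all(out == 0)
        assert np.all(tfce_enhance(-np.ones((5, 5, 5))) == 0)

    def test_constant_segment_matches_fine_step_threshold_sum(self):
        """1-D segment of constant height: coarse vs 10x finer integration."""
        vals = np.zeros((30, 3, 3))
        vals[5:25, 1, 1] = 2.0
        coarse = tfce_enhance(vals, n_steps=100)
        fine = tfce_enhance(vals, n_steps=1000)
        seg = vals > 0
        rel = np.abs(coarse[seg] / fine[seg] - 1.0)
        assert rel.max() < 0.02

    def test_height_integration_limit_on_single_voxel_cluster(self):
        """With E -> 0, H = 1, TFCE degenerates to the height sum
        sum_k (k dh) dh = max^2 (n+1) / (2n)."""
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 3.0
        n = 100
        out = tfce_enhance(vals, e=1e-9, h=1.0, n_steps=n)
        expected = 3.0 ** 2 * (n + 1) / (2 * n)
        assert out[2, 2, 2] == pytest.approx(expected, rel=1e-9)

    def test_graph_kernel_matches_volumetric_reference(self, rng):
        mask = rng.random((8, 8, 8)) > 0.4
        indptr, indices = skeleton_adjacency(mask)
        for _ in range(5):
            vals = np.zeros(mask.shape)
            vals[mask] = rng.normal(0.5, 1.0, mask.sum())
            ref = tfce_enhance(vals, mask)
            out = tfce_graph(np.ascontiguousarray(vals[mask]), indptr, indices,
                             0.5, 2.0, 100)
            np.testing.assert_allclose(out, ref[mask], rtol=1e-10, atol=1e-12)

    def test_raising_one_voxel_never_decreases_any_tfce_value(self, rng):
        """Monotonicity, checked by re-evaluation on 50 random maps.

        The continuous threshold integral is exactly monotone; the
        discrete sum re-grids its thresholds when the map maximum moves,
        so violations up to the discretization scale (~max/n_steps) are
        tolerated, and must shrink when the steps are refined.
        """
        mask = np.ones((6, 6, 6), bool)
        for _ in range(50):
            vals = rng.normal(0.5, 1.0, mask.shape)
            base = tfce_enhance(vals, mask)
            bumped = vals.copy()
            i, j, k = rng.integers(0, 6, 3)
            bumped[i, j, k] += rng.uniform(0.1, 2.0)
            out = tfce_enhance(bumped, mask)
            assert np.all(out >= base - 0.03 * base.max())
        for _ in range(10):
            vals = rng.normal(0.5, 1.0, mask.shape)
            base = tfce_enhance(vals, mask, n_steps=1000)
            bumped = vals.copy()
            i, j, k = rng.integers(0, 6, 3)
            bumped[i, j, k] += rng.uniform(0.1, 2.0)
            out = tfce_enhance(bumped, mask, n_steps=1000)
            assert np.all(out >= base - 0.004 * base.max())


def _skeleton_line(n=40, voxel_mm=1.0):
    grid = VolumeGrid.isotropic((n, 3, 3), voxel_mm)
    mask = np.zeros(grid.shape, bool)
    mask[:, 1, 1] = True
    idx = np.argwhere(mask)
    return SkeletonModel(grid, np.where(mask, 0.5, 0.0), mask, idx,
                         np.tile([0.0, 1.0, 0.0], (n, 1)),
                         np.tile([0.0, 0.0, 1.0], (n, 1)), 0.2)


class TestPermutationFwe:
    def test_corrected_p_never_below_the_permutation_floor(self):
        sk = _skeleton_line()
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (24, sk.n_voxels))
        data[:12] += 5.0                      # overwhelming group effect
        groups = np.array(["A"] * 12 + ["B"] * 12)
        cfg = InferenceConfig(n_permutations=200, seed=9)
        pos, neg = permutation_fwe(data, groups, sk, cfg)
        floor = 1.0 / (cfg.n_permutations + 1)
        assert pos.p_corrected.min() == pytest.approx(floor)
        assert np.all(pos.p_corrected >= floor)
        assert np.all(neg.p_corrected >= floor)
        assert np.all(neg.p_corrected <= 1.0)

    def test_tiny_groups_switch_to_exact_enumeration(self):
        sk = _skeleton_line(12)
        rng = np.random.default_rng(4)
        data = rng.normal(0, 1, (9, sk.n_voxels))
        groups = np.array(["A"] * 4 + ["B"] * 5)
        pos, _ = permutation_fwe(data, groups, sk,
                                 InferenceConfig(n_permutations=500))
        assert pos.exact
        assert pos.p_corrected.min() >= 1.0 / 126    # C(9, 4) relabelings

    def test_corrected_p_invariant_to_affine_data_rescaling(self):
        sk = _skeleton_line(20)
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (16, sk.n_voxels))
        data[:8, :10] += 1.5
        groups = np.array(["A"] * 8 + ["B"] * 8)
        cfg = InferenceConfig(n_permutations=300, seed=11)
        base = permutation_fwe(data, groups, sk, cfg)
        scaled = permutation_fwe(7.0 * data - 3.0, groups, sk, cfg)
        for m_base, m_scaled in zip(base, scaled):
            np.testing.assert_array_equal(m_scaled.p_corrected,
                                          m_base.p_corrected)

    def test_freedman_lane_removes_a_confounding_covariate(self):
        """A group difference explained entirely by a covariate must not
        reach significance once the covariate is regressed out."""
        sk = _skeleton_line(20)
        rng = np.random.default_rng(12)
        n = 30
        age = np.r_[rng.uniform(20, 40, 15), rng.uniform(40, 60, 15)]
        data = 0.05 * age[:, None] + rng.normal(0, 0.2, (n, sk.n_voxels))
        groups = np.array(["A"] * 15 + ["B"] * 15)
        cfg = InferenceConfig(n_permutations=300, seed=13)
        naive = permutation_fwe(data, groups, sk, cfg)
        adjusted = permutation_fwe(data, groups, sk, cfg,
                                   covariates=age[:, None])
        naive_min = min(m.p_corrected.min() for m in naive)
        adj_min = min(m.p_corrected.min() for m in adjusted)
        assert naive_min < 0.05 < adj_min

    def test_collinear_covariate_rejected(self):
        sk = _skeleton_line(10)
        data = np.random.default_rng(1).normal(0, 1, (10, sk.n_voxels))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        cov = (groups == "A").astype(float)   # constant within both groups
        with pytest.raises(ValidationError, match="collinear"):
            permutation_fwe(data, groups, sk, InferenceConfig(), covariates=cov)

    def test_group_smaller_than_two_rejected(self):
        sk = _skeleton_line(10)
        data = np.zeros((4, sk.n_voxels))
        groups = np.array(["A", "B", "B", "B"])
        with pytest.raises(ValidationError, match=">= 2"):
            permutation_fwe(data, groups, sk, InferenceConfig())


class TestRoiReport:
    def _setup(self, n=90, sig_a=40, sig_b=20):
        sk = _skeleton_line(n, voxel_mm=1.0)     # 1 mm^3 voxels
        half = n // 2
        labels = np.zeros(sk.grid.shape, np.int32)
        labels[:half, 1, 1] = 1
        labels[half:, 1, 1] = 2
        atlas = LabelMap(sk.grid, labels, {1: "region_A", 2: "region_B"})
        p = np.ones(sk.n_voxels)
        p[:sig_a] = 0.01                         # 40 significant 1-mm^3 voxels
        p[half:half + sig_b] = 0.01              # 20 in region B
        tfce = np.zeros(sk.n_voxels)
        tfce[:sig_a] = np.linspace(1, 2, sig_a)
        stat = StatMaps("A > B", np.zeros(sk.n_voxels), tfce, p, 500)
        return sk, atlas, stat

    def test_null_p_map_gives_empty_report(self):
        sk, atlas, stat = self._setup()
        null = StatMaps("A > B", stat.tstat, stat.tfce,
                        np.ones(sk.n_voxels), 500)
        assert roi_report(null, atlas, sk) == []

    def test_volume_and_peak_of_a_constructed_significant_region(self):
        sk, atlas, stat = self._setup()
        findings = roi_report(stat, atlas, sk)
        assert [f.region for f in findings] == ["region_A"]
        f = findings[0]
        assert f.volume_mm3 == pytest.approx(40.0)
        assert f.min_p == pytest.approx(0.01)
        # ties on p resolve to the largest TFCE: the last significant voxel
        assert f.peak_mm == tuple(sk.grid.voxel_to_world([39, 1, 1]))

    def test_region_below_the_minimum_volume_is_excluded(self):
        sk, atlas, stat = self._setup()
        findings = roi_report(stat, atlas, sk)    # region_B: 20 mm^3 < 30
        assert all(f.region != "region_B" for f in findings)
        # and a region at exactly the minimum volume is excluded too
        sk30, atlas30, stat30 = self._setup(sig_b=30)
        findings30 = roi_report(stat30, atlas30, sk30)
        assert all(f.region != "region_B" for f in findings30)

    def test_atlas_grid_mismatch_rejected(self):
        sk, _, stat = self._setup()
        other = VolumeGrid.isotropic((10, 3, 3), 1.0)
        atlas = LabelMap(other, np.zeros(other.shape, np.int32), {})
        with pytest.raises(ValidationError, match="grid"):
            roi_report(stat, atlas, sk)
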