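"""Modeled activation, ALE union, null/thresholding and conjunction."""

import numpy as np
import pytest

from focimeta import (
    GridMismatchError,
    StatMap,
    VolumeGrid,
    ale_union,
    cluster_report,
    conjunction,
    cut_at_resolution,
    extent_threshold,
    intersect_with_clusters,
    load_map,
    ma_map,
    mc_null,
    save_map,
    summarize_clusters,
    threshold_fdr,
    threshold_uncorrected,
    ward_linkage,
)

SIGMA = 10.0 / (2 * np.sqrt(2 * np.log(2)))  # default 10-mm FWHM


def kernel_value(dist_mm: float, voxel_volume: float) -> float:
    return voxel_volume * np.exp(-(dist_mm**2) / (2 * SIGMA**2)) / (
        (2 * np.pi * SIGMA**2) ** 1.5
    )


class TestMaMap:
    def test_single_focus_peak_at_its_voxel(self, small_grid):
        m = ma_map([(0.0, 0.0, 0.0)], small_grid)
        peak = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert peak == (5, 5, 5)  # centre voxel of the 11^3 grid
        assert m.values[peak] == pytest.approx(
            kernel_value(0.0, small_grid.voxel_volume), rel=1e-9
        )

    def test_coincident_foci_do_not_add(self, small_grid):
        one = ma_map([(0.0, 0.0, 0.0)], small_grid)
        two = ma_map([(0.0, 0.0, 0.0), (0.0, 0.0, 0.0)], small_grid)
        np.testing.assert_array_equal(one.values, two.values)

    def test_midpoint_of_two_foci_at_twice_fwhm(self):
        grid = VolumeGrid.box((-30, -10, -10), (30, 10, 10), 2.0)
        m = ma_map([(-10.0, 0, 0), (10.0, 0, 0)], grid, fwhm_mm=10.0)
        mid = tuple(np.round(grid.mm_to_voxel((0.0, 0.0, 0.0))[0]).astype(int))
        assert m.values[mid] == pytest.approx(
            kernel_value(10.0, grid.voxel_volume), rel=1e-9
        )

    def test_focus_outside_grid_warns_and_clips(self, small_grid):
        with pytest.warns(UserWarning, match="clipped"):
            m = ma_map([(500.0, 0.0, 0.0)], small_grid)
        assert np.all(m.values >= 0) and m.values.max() < kernel_value(0, 8.0)


class TestAleUnion:
    def test_single_experiment_is_identity(self, small_grid):
        m = ma_map([(0.0, 0.0, 0.0)], small_grid)
        np.testing.assert_allclose(ale_union([m]).values, m.values, rtol=1e-12)

    def test_union_probability_formula(self, small_grid):
        a = StatMap(small_grid, np.full(small_grid.shape, 0.5), "MA")
        b = StatMap(small_grid, np.full(small_grid.shape, 0.5), "MA")
        assert ale_union([a, b]).values[0, 0, 0] == pytest.approx(0.75)

    def test_ale_dominates_every_ma(self, small_grid, rng):
        mas = [
            ma_map(rng.uniform(-8, 8, (4, 3)), small_grid) for _ in range(5)
        ]
        ale = ale_union(mas)
        stack = np.stack([m.values for m in mas])
        assert np.all(ale.values >= stack.max(axis=0) - 1e-15)
        assert np.all(ale.values < 1.0)

    def test_permutation_invariance_and_zero_map(self, small_grid, rng):
        mas = [ma_map(rng.uniform(-8, 8, (3, 3)), small_grid) for _ in range(3)]
        fwd = ale_union(mas).values
        rev = ale_union(mas[::-1]).values
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)
        zero = StatMap(small_grid, np.zeros(small_grid.shape), "MA")
        np.testing.assert_allclose(ale_union(mas + [zero]).values, fwd, rtol=1e-12)

    def test_new_experiment_never_decreases_ale(self, small_grid):
        base = [ma_map([(0.0, 0.0, 0.0)], small_grid)]
        more = base + [ma_map([(2.0, 0.0, 0.0)], small_grid)]
        assert np.all(ale_union(more).values >= ale_union(base).values - 1e-15)

    def test_grid_mismatch_rejected(self, small_grid):
        other = VolumeGrid.box((-10, -10, -10), (10, 10, 10), 5.0)
        with pytest.raises(GridMismatchError):
            ale_union([
                ma_map([(0, 0, 0)], small_grid),
                ma_map([(0, 0, 0)], other),
            ])


class TestMonteCarloNull:
    def test_bounded_by_kernel_peak_for_single_focus(self, small_grid):
        null = mc_null([1], small_grid, n_iter=100, seed=5)
        assert null.samples.max() <= kernel_value(0, small_grid.voxel_volume) + 1e-15

    def test_deterministic_given_seed(self, small_grid):
        a = mc_null([2, 3], small_grid, n_iter=100, seed=9)
        b = mc_null([2, 3], small_grid, n_iter=100, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_hotspot_more_significant_than_background(self):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 4.0)
        rng = np.random.default_rng(2)
        # five experiments all reporting near the origin
        mas = [
            ma_map(rng.normal(0, 2, (4, 3)), grid) for _ in range(5)
        ]
        ale = ale_union(mas)
        null = mc_null([4] * 5, grid, n_iter=150, seed=3)
        p = null.sf(ale.values)
        centre = tuple(np.round(grid.mm_to_voxel((0, 0, 0))[0]).astype(int))
        corner = (0, 0, 0)
        assert p[centre] < p[corner]

    def test_quantile_stable_under_more_iterations(self):
        grid = VolumeGrid.box((-16, -16, -16), (16, 16, 16), 4.0)
        q1 = mc_null([3, 3], grid, n_iter=150, seed=1).quantile(0.95)
        q2 = mc_null([3, 3], grid, n_iter=300, seed=2).quantile(0.95)
        assert abs(q2 - q1) / q1 < 0.05


def bh_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Textbook sort-and-compare Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order]
    below = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * q)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    return reject


class TestThresholding:
    def test_fdr_matches_bh_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = np.concatenate([rng.random(900), rng.random(100) * 1e-4])
        ours, _, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(ours, bh_oracle(pvals, 0.05))

    def test_all_zero_pvalues_all_survive(self, small_grid):
        ale = StatMap(small_grid, np.full(small_grid.shape, 0.9), "ALE")
        null = mc_null([1], small_grid, n_iter=100, seed=0)
        binary, pmap = threshold_fdr(ale, null, q=0.05)
        # observed ALE far above anything the null produced
        assert binary.values.all()

    def test_no_signal_yields_almost_nothing(self):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 4.0)
        rng = np.random.default_rng(4)
        mas = [ma_map(rng.uniform(-18, 18, (3, 3)), grid) for _ in range(3)]
        ale = ale_union(mas)
        null = mc_null([3] * 3, grid, n_iter=200, seed=11)
        binary, _ = threshold_fdr(ale, null, q=0.05)
        assert binary.values.mean() <= 0.05

    def test_uncorrected_threshold_keeps_suprathreshold_ale(self, small_grid):
        ale = ma_map([(0.0, 0.0, 0.0)], small_grid)
        null = mc_null([1], small_grid, n_iter=100, seed=1)
        thr, pmap = threshold_uncorrected(ale, null, p=0.05)
        assert ((thr.values > 0) == (pmap.values <= 0.05)).all()


class TestExtentThreshold:
    @pytest.mark.parametrize("n_vox, kept", [(37, False), (38, True)])
    def test_300mm3_boundary_at_2mm_voxels(self, n_vox, kept):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 2.0)
        vals = np.zeros(grid.shape)
        # a single straight run of voxels is one 26-connected component
        vals[2, 2, : n_vox // 2] = 1.0
        vals[2, 3, : n_vox - n_vox // 2] = 1.0
        out = extent_threshold(StatMap(grid, vals, "binary"), 300.0)
        assert out.values.any() == kept

    def test_matches_floodfill_oracle(self, rng):
        from scipy import ndimage

        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 2.0)
        vals = (rng.random(grid.shape) < 0.2).astype(float)
        out = extent_threshold(StatMap(grid, vals, "binary"), 100.0)
        lab, n = ndimage.label(vals > 0, structure=np.ones((3, 3, 3)))
        expect = np.zeros(grid.shape)
        for comp in range(1, n + 1):
            if (lab == comp).sum() * grid.voxel_volume > 100.0:
                expect[lab == comp] = 1.0
        np.testing.assert_array_equal(out.values, expect)

    def test_monotone_in_volume_threshold(self, rng):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 2.0)
        vals = (rng.random(grid.shape) < 0.25).astype(float)
        m = StatMap(grid, vals, "binary")
        small = extent_threshold(m, 50.0)
        large = extent_threshold(m, 200.0)
        assert np.all(small.values >= large.values)


class TestConjunction:
    def test_idempotent_commutative_and_absorbing(self, small_grid, rng):
        a = StatMap(small_grid, rng.random(small_grid.shape), "ALE")
        b = StatMap(small_grid, rng.random(small_grid.shape), "ALE")
        zero = StatMap(small_grid, np.zeros(small_grid.shape), "ALE")
        np.testing.assert_array_equal(conjunction(a, a).values, a.values)
        np.testing.assert_array_equal(
            conjunction(a, b).values, conjunction(b, a).values
        )
        assert not conjunction(a, zero).values.any()

    def test_toy_elementwise_minimum(self):
        grid = VolumeGrid.box((0, 0, 0), (2, 2, 2), 2.0)
        av = np.arange(8, dtype=float).reshape(2, 2, 2) / 10
        bv = av[::-1].copy()
        out = conjunction(StatMap(grid, av), StatMap(grid, bv))
        np.testing.assert_array_equal(out.values, np.minimum(av, bv))

    def test_suprathreshold_set_is_the_intersection(self, small_grid, rng):
        a = StatMap(small_grid, rng.random(small_grid.shape), "ALE")
        b = StatMap(small_grid, rng.random(small_grid.shape), "ALE")
        thr = 0.6
        conj = conjunction(a, b)
        np.testing.assert_array_equal(
            conj.values > thr, (a.values > thr) & (b.values > thr)
        )


class TestClusterReport:
    def test_single_voxel_cluster(self, small_grid):
        binary = np.zeros(small_grid.shape)
        binary[5, 5, 5] = 1.0
        ale = StatMap(small_grid, np.full(small_grid.shape, 0.3), "ALE")
        tab = cluster_report(StatMap(small_grid, binary, "binary"), ale)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["volume_mm3"] == pytest.approx(small_grid.voxel_volume)
        assert (row[["wc_x", "wc_y", "wc_z"]] == 0).all()

    def test_symmetric_cluster_centre_at_midpoint(self, small_grid):
        binary = np.zeros(small_grid.shape)
        binary[4, 5, 5] = binary[5, 5, 5] = 1.0
        vals = np.zeros(small_grid.shape)
        vals[4, 5, 5] = vals[5, 5, 5] = 0.5
        tab = cluster_report(
            StatMap(small_grid, binary, "binary"), StatMap(small_grid, vals, "ALE")
        )
        assert len(tab) == 1
        assert tab.iloc[0]["wc_x"] == pytest.approx(-1.0)  # midpoint of -2 and 0

    def test_planted_hotspot_centre_within_one_voxel(self):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 4.0)
        ale = ma_map([(4.0, -4.0, 4.0)], grid)
        binary = StatMap(grid, (ale.values > ale.values.max() * 0.5).astype(float), "binary")
        tab = cluster_report(binary, ale)
        centre = tab.iloc[0][["wc_x", "wc_y", "wc_z"]].to_numpy(dtype=float)
        assert np.linalg.norm(centre - (4.0, -4.0, 4.0)) <= 4.0

    def test_empty_map_gives_empty_table(self, small_grid):
        empty = StatMap(small_grid, np.zeros(small_grid.shape), "binary")
        ale = StatMap(small_grid, np.zeros(small_grid.shape), "ALE")
        assert len(cluster_report(empty, ale)) == 0


class TestIntersectWithClusters:
    def _solution(self, pts):
        return summarize_clusters(
            cut_at_resolution(ward_linkage(pts), pts, 5.0), ["a"] * len(pts)
        )

    def test_centroid_inside_surviving_blob_is_validated(self):
        grid = VolumeGrid.box((-20, -20, -20), (20, 20, 20), 4.0)
        pts = np.zeros((5, 3))
        sol = self._solution(pts)
        surviving = np.zeros(grid.shape)
        surviving[tuple(np.round(grid.mm_to_voxel((0, 0, 0))[0]).astype(int))] = 1.0
        flags = intersect_with_clusters(sol, StatMap(grid, surviving, "binary"), 5.0)
        assert flags.all()

    def test_distant_centroid_not_validated(self):
        grid = VolumeGrid.box((-60, -60, -60), (60, 60, 60), 4.0)
        pts = np.full((5, 3), 50.0)
        sol = self._solution(pts)
        surviving = np.zeros(grid.shape)
        surviving[0, 0, 0] = 1.0  # ~190 mm away
        flags = intersect_with_clusters(sol, StatMap(grid, surviving, "binary"), 5.0)
        assert not flags.any()

    def test_partial_overlap_design(self):
        grid = VolumeGrid.box((-60, -60, -60), (60, 60, 60), 4.0)
        pts = np.vstack(
            [np.zeros((4, 3)), np.full((4, 3), 40.0), np.full((4, 3), -40.0)]
        )
        sol = self._solution(pts)
        ale = ale_union(
            [ma_map([(0, 0, 0)], grid), ma_map([(40.0, 40.0, 40.0)], grid)]
        )
        surviving = StatMap(grid, (ale.values > ale.values.max() * 0.5).astype(float), "binary")
        flags = intersect_with_clusters(sol, surviving, 5.0)
        assert int(flags.sum()) == 2


def test_nifti_round_trip(tmp_path, small_grid, rng):
    m = StatMap(small_grid, rng.random(small_grid.shape), "ALE")
    save_map(m, tmp_path / "m.nii.gz")
    back = load_map(tmp_path / "m.nii.gz")
    np.testing.assert_allclose(back.values, m.values, atol=1e-12)
    assert back.grid.same_as(small_grid)
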