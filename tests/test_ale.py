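"""ALE engine: kernels, MA maps, union scores, empirical nulls, inference."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

import coactiv as ca
from coactiv.ale import (NullDistribution, ale_from_ma, ale_from_matrix,
                         cluster_fwe_threshold, kernel_for_experiment, ma_map,
                         ma_matrix, p_map, z_map)
from coactiv.grids import volume_from_values


class TestKernel:
    @pytest.mark.parametrize("n_subjects,fwhm", [(5, 8.0), (20, 10.0), (50, 14.0)])
    def test_mass_sums_to_one(self, small_grid, n_subjects, fwhm):
        k = kernel_for_experiment(n_subjects, small_grid, fwhm)
        assert k.support.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(k.support >= 0)

    def test_central_mass_matches_normal_cdf_oracle(self):
        grid = ca.BrainGrid((15, 15, 15), np.diag([2., 2., 2., 1.]),
                            np.ones((15, 15, 15), bool))
        k = kernel_for_experiment(10, grid, 10.0)
        sigma = 10.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = (ndtr(1.0 / sigma) - ndtr(-1.0 / sigma)) ** 3
        # truncation at 3.5 sigma + renormalisation shifts by < 1e-3 rel
        assert k.central_mass == pytest.approx(expected, rel=2e-3)

    def test_central_mass_decreases_with_fwhm(self, small_grid):
        k8 = kernel_for_experiment(10, small_grid, 8.0)
        k12 = kernel_for_experiment(10, small_grid, 12.0)
        assert k8.central_mass > k12.central_mass

    def test_subjects_table_policy(self, small_grid):
        policy = ca.SubjectsTableFWHM({10: 11.0, 50: 8.5})
        assert policy(12) == 11.0 and policy(45) == 8.5
        k = kernel_for_experiment(45, small_grid, policy)
        assert k.fwhm_mm == 8.5


class TestMAMap:
    def test_single_focus_is_translated_kernel(self, small_grid):
        k = kernel_for_experiment(10, small_grid, 10.0)
        center = small_grid.voxel_to_mm(np.array([6.0, 6.0, 6.0]))
        exp = ca.Experiment("e", 10, [center])
        ma = ma_map(exp, small_grid, k)
        r = k.radii
        sub = ma.data[6 - r[0]:6 + r[0] + 1, 6 - r[1]:6 + r[1] + 1,
                      6 - r[2]:6 + r[2] + 1]
        expected = np.where(small_grid.mask[6 - r[0]:6 + r[0] + 1,
                                            6 - r[1]:6 + r[1] + 1,
                                            6 - r[2]:6 + r[2] + 1],
                            k.support, 0.0)
        assert np.allclose(sub, expected)

    def test_duplicate_foci_idempotent_under_max_rule(self, small_grid):
        k = kernel_for_experiment(10, small_grid, 10.0)
        mm = small_grid.voxel_to_mm(np.array([6.0, 6.0, 6.0]))
        one = ma_map(ca.Experiment("a", 10, [mm]), small_grid, k)
        two = ma_map(ca.Experiment("b", 10, [mm, mm]), small_grid, k)
        assert np.array_equal(one.data, two.data)

    def test_multi_focus_equals_voxelwise_max_oracle(self, small_grid, rng):
        k = kernel_for_experiment(10, small_grid, 10.0)
        idx = small_grid.mask_indices
        mms = small_grid.voxel_to_mm(
            idx[rng.integers(0, idx.shape[0], 4)].astype(float))
        joint = ma_map(ca.Experiment("j", 10, mms), small_grid, k)
        singles = [ma_map(ca.Experiment(f"s{i}", 10, [mm]), small_grid, k)
                   for i, mm in enumerate(mms)]
        oracle = np.maximum.reduce([s.data for s in singles])
        assert np.allclose(joint.data, oracle, atol=1e-12)

    def test_no_usable_focus_is_error(self, small_grid):
        k = kernel_for_experiment(10, small_grid, 10.0)
        exp = ca.Experiment("far", 10, [[500.0, 500.0, 500.0]])
        with pytest.raises(ValueError, match="usable"):
            ma_map(exp, small_grid, k)


class TestUnionALE:
    def test_closed_form_two_values(self, small_grid):
        v1 = volume_from_values(small_grid,
                                np.full(small_grid.n_in_mask, 0.2), "MA")
        v2 = volume_from_values(small_grid,
                                np.full(small_grid.n_in_mask, 0.3), "MA")
        ale = ale_from_ma([v1, v2])
        assert np.allclose(ale.values, 0.44)

    def test_single_map_identity(self, small_grid, rng):
        v = volume_from_values(small_grid, rng.random(small_grid.n_in_mask) * 0.5,
                               "MA")
        assert np.allclose(ale_from_ma([v]).values, v.values)

    def test_union_bounds_and_brute_force_exactness(self, small_grid, rng):
        mat = rng.random((6, small_grid.n_in_mask)) * 0.4
        ale = ale_from_matrix(mat)
        # brute-force per-voxel oracle
        oracle = np.array([1.0 - np.prod(1.0 - mat[:, j])
                           for j in range(mat.shape[1])])
        assert np.max(np.abs(ale - oracle)) < 1e-12
        assert np.all(ale >= mat.max(axis=0) - 1e-15)
        assert np.all(ale <= mat.sum(axis=0) + 1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ale_from_ma([])

    def test_order_invariant_and_monotone(self, small_grid, rng,
                                          random_db_factory):
        db = random_db_factory(small_grid, 6, rng)
        mat, _ = ma_matrix(db, small_grid)
        perm = rng.permutation(6)
        assert np.allclose(ale_from_matrix(mat), ale_from_matrix(mat[perm]))
        # adding an experiment never decreases ALE anywhere
        assert np.all(ale_from_matrix(mat) >= ale_from_matrix(mat[:4]) - 1e-15)


class TestNullDistribution:
    def test_constant_ma_map_gives_point_mass(self, small_grid):
        c = 0.123
        mat = np.full((1, small_grid.n_in_mask), c)
        null = NullDistribution.analytic(mat)
        assert null.bins.size == 1
        assert null.bins[0] * null.bin_width == pytest.approx(c, abs=1e-5)
        assert null.probs[0] == pytest.approx(1.0)

    def test_two_valued_maps_match_exhaustive_enumeration(self):
        # two experiments whose MA maps each take value c on a known fraction
        # f of the mask and 0 elsewhere: the null is the 4-outcome mixture
        shape = (10, 10, 10)
        grid = ca.BrainGrid(shape, np.eye(4), np.ones(shape, bool))
        n = grid.n_in_mask
        c1, f1, c2, f2 = 0.20, 0.25, 0.10, 0.50
        m1 = np.zeros(n); m1[:int(f1 * n)] = c1
        m2 = np.zeros(n); m2[:int(f2 * n)] = c2
        null = NullDistribution.analytic(np.vstack([m1, m2]))
        outcomes = {0.0: (1 - f1) * (1 - f2),
                    c2: (1 - f1) * f2,
                    c1: f1 * (1 - f2),
                    1 - (1 - c1) * (1 - c2): f1 * f2}
        for val, prob in outcomes.items():
            lo, hi = val - 1e-4, val + 1e-4
            got = null.probs[(null.bins * null.bin_width >= lo)
                             & (null.bins * null.bin_width <= hi)].sum()
            assert got == pytest.approx(prob, abs=1e-9)

    def test_analytic_and_sampling_agree(self, small_grid, rng,
                                         random_db_factory):
        db = random_db_factory(small_grid, 8, rng)
        mat, _ = ma_matrix(db, small_grid)
        na = NullDistribution.analytic(mat)
        ns = NullDistribution.from_sampling(mat, 200_000, rng)
        xs = np.linspace(0, float(na.bins[-1] * na.bin_width), 400)
        assert np.max(np.abs(na.cdf(xs) - ns.cdf(xs))) < 0.01

    def test_small_sampling_warns(self, small_grid, caplog):
        mat = np.full((1, small_grid.n_in_mask), 0.1)
        with caplog.at_level("WARNING"):
            NullDistribution.from_sampling(mat, 100, np.random.default_rng(0))
        assert any("noisy" in r.message for r in caplog.records)


class TestPandZ:
    def test_sampling_counting_example(self, small_grid):
        null = NullDistribution("sampling", samples=[0.1, 0.2, 0.3, 0.4])
        # raw proportion of null values >= 0.35 is 1/4; the +1-corrected
        # estimator reported is (1+1)/(4+1)
        p = float(null.sf(0.35))
        assert p == pytest.approx(2 / 5)
        raw = (p * (null.n_draws + 1) - 1) / null.n_draws
        assert raw == pytest.approx(1 / 4)

    def test_observed_zero_has_p_one(self, small_grid):
        null = NullDistribution("sampling", samples=[0.1, 0.2, 0.3, 0.4])
        assert float(null.sf(0.0)) == pytest.approx(1.0)
        mat = np.random.default_rng(0).random((3, small_grid.n_in_mask)) * 0.3
        na = NullDistribution.analytic(mat)
        assert float(na.sf(0.0)) == pytest.approx(1.0)

    def test_above_support_returns_smallest_tail_mass(self, small_grid, rng):
        mat = rng.random((3, small_grid.n_in_mask)) * 0.3
        na = NullDistribution.analytic(mat)
        p = float(na.sf(0.99))
        assert p > 0
        assert p == pytest.approx(float(na.probs[-1]))

    def test_z_transform_values(self, small_grid):
        pvals = np.full(small_grid.n_in_mask, 0.5)
        p = volume_from_values(small_grid, pvals, "P", fill=1.0)
        assert np.allclose(z_map(p).values, 0.0, atol=1e-12)
        p2 = volume_from_values(small_grid,
                                np.full(small_grid.n_in_mask, 0.001), "P", fill=1.0)
        assert np.allclose(z_map(p2).values, ndtri(0.999), atol=1e-9)

    def test_z_monotone_and_floored(self, small_grid, rng):
        pv = np.sort(rng.uniform(1e-6, 1.0, small_grid.n_in_mask))
        pv[-1] = 1.0
        z = z_map(volume_from_values(small_grid, pv, "P", fill=1.0)).values
        assert np.all(np.diff(z) <= 1e-12)  # p up => z down
        assert z[-1] == pytest.approx(-8.2)

    def test_single_experiment_p_is_monotone_in_ma(self, small_grid, rng,
                                                   random_db_factory):
        db = random_db_factory(small_grid, 1, rng)
        mat, _ = ma_matrix(db, small_grid)
        null = NullDistribution.analytic(mat)
        ale = ale_from_matrix(mat)
        p = null.sf(ale)
        order = np.argsort(ale)
        assert np.all(np.diff(p[order]) <= 1e-12)


class TestClusterFWE:
    def test_alpha_one_limit_threshold_is_one(self, small_grid, rng,
                                              random_db_factory):
        db = random_db_factory(small_grid, 5, rng)
        spec = ca.ThresholdSpec(voxel_p=0.001, cluster_alpha=0.999,
                                n_cluster_sims=20)
        k = cluster_fwe_threshold(db, small_grid, None, spec, rng_seed=1)
        assert k == 1

    def test_deterministic_given_seed(self, small_grid, rng, random_db_factory):
        db = random_db_factory(small_grid, 6, rng)
        spec = ca.ThresholdSpec(n_cluster_sims=30)
        k1 = cluster_fwe_threshold(db, small_grid, None, spec, rng_seed=5)
        k2 = cluster_fwe_threshold(db, small_grid, None, spec, rng_seed=5)
        assert k1 == k2


class TestALEModel:
    def test_fit_pipeline_and_summary(self, rng):
        spec = ca.paper_like_network_spec()
        db, _ = ca.simulate_foci_db(spec, rng)
        sel = ca.select_by_seed(db, spec.region_masks()["seedA"])
        res = ca.ALE(sel, spec.grid).fit(ca.ThresholdSpec(n_cluster_sims=50),
                                         seed=2)
        assert res.ale.values.max() <= 1.0
        assert res.p.values.min() > 0
        assert len(res.clusters) >= 1
        text = res.summary()
        assert "experiments" in text and "min extent" in text
        # p-map and z-map consistent
        assert np.allclose(res.z.values,
                           np.maximum(-ndtri(res.p.values), -8.2), atol=1e-9)

    def test_empty_db_rejected(self, small_grid):
        with pytest.raises(ValueError):
            ca.ALE(ca.FociDatabase([]), small_grid)
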