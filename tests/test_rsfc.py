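"""Resting-state pipeline: nuisance model, filtering, eigenvariate,
correlation maps, paired group inference."""

import numpy as np
import pytest

import coactiv as ca
from coactiv.grids import volume_from_values
from coactiv.rsfc import (CleanedBold, NuisanceMatrix, SubjectConnMap,
                          bandpass, build_nuisance, group_contrast,
                          regress_out, seed_corr_map, seed_eigenvariate)


@pytest.fixture(scope="module")
def subject():
    spec = ca.BoldSpec(T=120, shape=(14, 16, 14), n_discard=4)
    ds, lat = ca.simulate_subject(spec, 0, np.random.default_rng(5))
    return spec, ds.trim(), lat


class TestNuisanceMatrix:
    def test_column_count_and_labels(self, subject):
        spec, ds, lat = subject
        nm = build_nuisance(ds)
        # 15 first-order columns, 5 PCA components, 15 squares, intercept
        assert nm.K == 36
        assert nm.column_labels.count("intercept") == 1
        assert sum(l.endswith("_sq") for l in nm.column_labels) == 15
        # all but intercept centred
        for j, lab in enumerate(nm.column_labels):
            if lab != "intercept":
                assert abs(nm.matrix[:, j].mean()) < 1e-10, lab

    def test_constant_motion_has_zero_derivatives(self, subject):
        spec, ds, lat = subject
        from dataclasses import replace
        ds2 = replace(ds, motion=np.ones((ds.n_timepoints, 6)))
        nm = build_nuisance(ds2)
        cols = [j for j, l in enumerate(nm.column_labels)
                if l.startswith("motion_deriv") and not l.endswith("_sq")]
        assert np.allclose(nm.matrix[:, cols], 0.0)

    def test_rank_one_bold_first_pc_matches_signal(self):
        grid = ca.ellipsoid_grid((10, 10, 10), 4.0)
        rng = np.random.default_rng(3)
        T = 80
        s = rng.standard_normal(T)
        w = rng.standard_normal(grid.n_in_mask)
        bold = np.zeros(grid.shape + (T,))
        bold[grid.mask] = np.outer(w, s) + 1e-6 * rng.standard_normal(
            (grid.n_in_mask, T))
        ds = ca.TimeSeriesDataset("s", bold, 2.2, np.cumsum(
            rng.standard_normal((T, 6)), axis=0) * 0.01,
            ca.tissue_masks_for(grid), grid)
        nm = build_nuisance(ds)
        pc1 = nm.matrix[:, nm.column_labels.index("pca_1")]
        assert abs(np.corrcoef(pc1, s)[0, 1]) > 0.999

    def test_untrimmed_dataset_rejected(self):
        spec = ca.BoldSpec(T=80, shape=(10, 10, 10), n_discard=4)
        ds, _ = ca.simulate_subject(spec, 0, np.random.default_rng(1))
        with pytest.raises(ValueError, match="trim"):
            build_nuisance(ds)

    def test_too_few_timepoints_unidentifiable(self):
        grid = ca.ellipsoid_grid((10, 10, 10), 4.0)
        rng = np.random.default_rng(1)
        T = 35  # fewer frames than the 36 design columns
        bold = rng.standard_normal(grid.shape + (T,))
        ds = ca.TimeSeriesDataset("s", bold, 2.2,
                                  rng.standard_normal((T, 6)) * 0.01,
                                  ca.tissue_masks_for(grid), grid)
        with pytest.raises(ValueError, match="unidentifiable"):
            build_nuisance(ds)


class TestRegressOut:
    def test_nuisance_column_fully_removed(self, subject):
        spec, ds, lat = subject
        nm = build_nuisance(ds)
        col = nm.matrix[:, 3].copy()
        resid = regress_out(col, nm)
        assert np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(col), 1.0)

    def test_orthogonal_series_unchanged(self, rng):
        T = 100
        X = np.column_stack([np.ones(T), np.sin(np.arange(T))])
        nm = NuisanceMatrix(X, ["intercept", "sin"])
        ts = rng.standard_normal(T)
        # orthogonalize ts against X first
        ts -= X @ np.linalg.lstsq(X, ts, rcond=None)[0]
        assert np.allclose(regress_out(ts, nm), ts, atol=1e-10)

    def test_residuals_orthogonal_to_every_column(self, subject, rng):
        spec, ds, lat = subject
        nm = build_nuisance(ds)
        Y = rng.standard_normal((ds.n_timepoints, 5))
        R = regress_out(Y, nm)
        inner = nm.matrix.T @ R
        scale = np.linalg.norm(nm.matrix, axis=0)[:, None] * \
            np.linalg.norm(Y, axis=0)[None, :]
        assert np.max(np.abs(inner) / scale) < 1e-8

    def test_planted_confound_removed(self, rng):
        T = 200
        conf = rng.standard_normal(T)
        signal = rng.standard_normal(T)
        probe = rng.standard_normal(T)  # reference series correlated w/ signal
        probe = 0.6 * signal + 0.8 * probe
        clean_r = np.corrcoef(signal, probe)[0, 1]
        ts = signal + 0.7 * conf
        nm = NuisanceMatrix(np.column_stack([conf - conf.mean(), np.ones(T)]),
                            ["conf", "intercept"])
        resid = regress_out(ts, nm)
        assert abs(np.corrcoef(resid, probe)[0, 1] - clean_r) < 0.02

    def test_rank_deficient_design_handled(self, rng):
        T = 60
        a = rng.standard_normal(T)
        X = np.column_stack([a, 2 * a, np.ones(T)])
        nm = NuisanceMatrix(X, ["a", "2a", "intercept"])
        resid = regress_out(a.copy(), nm)
        assert np.linalg.norm(resid) < 1e-8


class TestBandpass:
    TR = 2.2
    T = 296

    def _probe(self, f):
        t = np.arange(self.T) * self.TR
        return np.sin(2 * np.pi * f * t)

    def _gain(self, f):
        x = self._probe(f)
        y = bandpass(x, self.TR)
        fr = np.fft.rfftfreq(self.T, self.TR)
        k = np.argmin(np.abs(fr - f))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x))[k]

    def test_passband_preserved(self):
        assert self._gain(0.04) > 0.95

    def test_stopband_attenuated(self):
        assert self._gain(0.004) < 0.10
        assert self._gain(0.2) < 0.10

    def test_dc_removed(self):
        out = bandpass(np.full(self.T, 5.0), self.TR)
        assert np.max(np.abs(out)) < 1e-8

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(self._probe(0.04), tr_s=10.0, f_lo=0.01, f_hi=0.08)

    def test_idempotent_within_two_percent(self, rng):
        x = rng.standard_normal(self.T)
        once = bandpass(x, self.TR)
        twice = bandpass(once, self.TR)
        assert np.max(np.abs(twice - once)) < 0.02 * np.linalg.norm(once)


class TestSeedExtraction:
    def _cleaned(self, grid, data, tr=2.2):
        return CleanedBold(grid, data, tr)

    def test_shared_time_course_recovered(self, small_grid, rng):
        T = 90
        t = rng.standard_normal(T)
        data = np.zeros((T, small_grid.n_in_mask))
        seed = ca.sphere_mask(small_grid, (0, 0, 0), 6.0)
        cols = seed.binary[small_grid.mask]
        data[:, cols] = t[:, None] * rng.uniform(0.5, 2.0, cols.sum())[None, :]
        ev = seed_eigenvariate(self._cleaned(small_grid, data), seed)
        assert abs(np.corrcoef(ev, t)[0, 1]) > 0.999999
        assert np.corrcoef(ev, data[:, cols].mean(1))[0, 1] > 0

    def test_sign_convention_follows_mean(self, small_grid, rng):
        T = 90
        t = rng.standard_normal(T)
        seed = ca.sphere_mask(small_grid, (0, 0, 0), 6.0)
        cols = np.flatnonzero(seed.binary[small_grid.mask])
        data = np.zeros((T, small_grid.n_in_mask))
        # two anti-correlated halves, unequal weight so the mean is defined
        half = len(cols) // 2
        data[:, cols[:half + 1]] = t[:, None]
        data[:, cols[half + 1:]] = -t[:, None]
        ev = seed_eigenvariate(self._cleaned(small_grid, data), seed)
        mean_ts = data[:, cols].mean(1)
        assert np.corrcoef(ev, mean_ts)[0, 1] >= 0

    def test_matches_svd_oracle_up_to_sign(self, small_grid, rng):
        T = 70
        seed = ca.sphere_mask(small_grid, (0, 0, 0), 8.0)
        cols = seed.binary[small_grid.mask]
        data = np.zeros((T, small_grid.n_in_mask))
        low_rank = (rng.standard_normal((T, 2))
                    @ rng.standard_normal((2, cols.sum())))
        data[:, cols] = low_rank + 0.01 * rng.standard_normal(low_rank.shape)
        ev = seed_eigenvariate(self._cleaned(small_grid, data), seed)
        u = np.linalg.svd(data[:, cols], full_matrices=False)[0][:, 0]
        assert min(np.linalg.norm(ev / np.linalg.norm(ev) - u),
                   np.linalg.norm(ev / np.linalg.norm(ev) + u)) < 1e-6

    def test_zero_variance_seed_rejected(self, small_grid):
        seed = ca.sphere_mask(small_grid, (0, 0, 0), 6.0)
        data = np.zeros((50, small_grid.n_in_mask))
        with pytest.raises(ValueError):
            seed_eigenvariate(self._cleaned(small_grid, data), seed)

    @pytest.mark.parametrize("r,expected", [(0.5, np.arctanh(0.5)), (0.0, 0.0)])
    def test_fisher_z_closed_form(self, small_grid, rng, r, expected):
        T = 20000
        grey = ca.StatVolume(small_grid, small_grid.mask.astype(float), "MASK")
        s = rng.standard_normal(T)
        other = r * s + np.sqrt(1 - r ** 2) * rng.standard_normal(T)
        data = np.tile(other[:, None], (1, small_grid.n_in_mask))
        m = seed_corr_map(self._cleaned(small_grid, data), s, grey)
        assert np.allclose(m.z.values, expected, atol=0.05)

    def test_self_correlation_clipped(self, small_grid, rng):
        T = 60
        grey = ca.StatVolume(small_grid, small_grid.mask.astype(float), "MASK")
        s = rng.standard_normal(T)
        data = np.tile(s[:, None], (1, small_grid.n_in_mask))
        m = seed_corr_map(self._cleaned(small_grid, data), s, grey)
        assert np.allclose(m.z.values, np.arctanh(1 - 1e-7))


class TestSubjectPipeline:
    def test_end_to_end_maps_and_summary(self):
        spec = ca.BoldSpec(T=120, shape=(14, 16, 14))
        ds, _ = ca.simulate_subject(spec, 0, np.random.default_rng(2))
        seeds = {"seed": spec.region_masks()["seed"]}
        res = ca.SubjectConnectivity(ds, seeds).fit()
        z = res.maps["seed"].z
        assert np.all(np.isfinite(z.values))
        assert res.nuisance.K == 36
        assert "seeds: seed" in res.summary()

    def test_filter_regressors_variant_runs(self):
        spec = ca.BoldSpec(T=120, shape=(14, 16, 14))
        ds, _ = ca.simulate_subject(spec, 1, np.random.default_rng(3))
        seeds = {"seed": spec.region_masks()["seed"]}
        res = ca.SubjectConnectivity(ds, seeds, filter_regressors=True).fit()
        assert np.all(np.isfinite(res.maps["seed"].z.values))


class TestDatasetModel:
    def test_trim_aligns_motion_rows(self):
        spec = ca.BoldSpec(T=80, shape=(10, 10, 10), n_discard=4)
        ds, _ = ca.simulate_subject(spec, 0, np.random.default_rng(1))
        tr = ds.trim()
        assert tr.n_discard == 0
        assert tr.bold.shape[3] == 76 and tr.motion.shape == (76, 6)
        assert np.array_equal(tr.motion, ds.motion[4:])

    def test_too_short_run_rejected(self, small_grid, rng):
        bold = rng.standard_normal(small_grid.shape + (20,))
        with pytest.raises(ValueError, match="timepoints"):
            ca.TimeSeriesDataset("s", bold, 2.2, np.zeros((20, 6)),
                                 ca.tissue_masks_for(small_grid), small_grid,
                                 n_discard=4)

    def test_motion_shape_enforced(self, small_grid, rng):
        bold = rng.standard_normal(small_grid.shape + (60,))
        with pytest.raises(ValueError, match="motion"):
            ca.TimeSeriesDataset("s", bold, 2.2, np.zeros((59, 6)),
                                 ca.tissue_masks_for(small_grid), small_grid)


def _maps_from_diffs(grid, diffs, tag):
    out_a, out_b = [], []
    for s, d in enumerate(diffs):
        za = volume_from_values(grid, d, "Z")
        zb = volume_from_values(grid, np.zeros(grid.n_in_mask), "Z")
        out_a.append(SubjectConnMap(f"{tag}{s}", "A", za))
        out_b.append(SubjectConnMap(f"{tag}{s}", "B", zb))
    return out_a, out_b


class TestGroupContrast:
    def test_zero_differences_give_empty_maps(self, small_grid):
        diffs = [np.zeros(small_grid.n_in_mask) for _ in range(8)]
        a, b = _maps_from_diffs(small_grid, diffs, "s")
        res = group_contrast(a, b, n_perm=200, rng_seed=1)
        assert res.mask_AgtB.values.sum() == 0
        assert res.mask_BgtA.values.sum() == 0

    def test_planted_effect_recovered(self, small_grid):
        region = ca.sphere_mask(small_grid, (0, 0, 0), 9.0)
        cols = region.binary[small_grid.mask]
        recovered = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            diffs = []
            for s in range(20):
                d = np.zeros(small_grid.n_in_mask)
                d += 0.02 * rng.standard_normal(small_grid.n_in_mask)
                d[cols] += rng.normal(0.4, 0.1)
                diffs.append(d)
            a, b = _maps_from_diffs(small_grid, diffs, "s")
            res = group_contrast(a, b, n_perm=300, rng_seed=rep)
            recovered += (res.mask_AgtB.binary & region.binary).any()
        assert recovered == 5

    def test_swapping_lists_exchanges_directions(self, small_grid, rng):
        diffs = [0.3 * rng.standard_normal(small_grid.n_in_mask)
                 for _ in range(10)]
        a, b = _maps_from_diffs(small_grid, diffs, "s")
        r1 = group_contrast(a, b, n_perm=200, rng_seed=2)
        r2 = group_contrast(b, a, n_perm=200, rng_seed=2)
        assert np.array_equal(r1.mask_AgtB.binary, r2.mask_BgtA.binary)
        assert np.array_equal(r1.mask_BgtA.binary, r2.mask_AgtB.binary)
        assert np.allclose(r1.t.values, -r2.t.values, atol=1e-10)

    def test_unpaired_subjects_rejected(self, small_grid):
        diffs = [np.zeros(small_grid.n_in_mask) for _ in range(6)]
        a, _ = _maps_from_diffs(small_grid, diffs, "x")
        _, b = _maps_from_diffs(small_grid, diffs, "y")
        with pytest.raises(ValueError, match="paired"):
            group_contrast(a, b, n_perm=50, rng_seed=0)

    def test_minimum_cohort_size(self, small_grid):
        diffs = [np.zeros(small_grid.n_in_mask) for _ in range(4)]
        a, b = _maps_from_diffs(small_grid, diffs, "s")
        with pytest.raises(ValueError, match="at least 6"):
            group_contrast(a, b, n_perm=50, rng_seed=0)
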