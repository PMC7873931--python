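"""Polychoric estimation, principal-axis factoring, Friedman and comparisons."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from fpdkit import association, synth


class TestPolychoric:
    def test_identical_vectors_near_one(self):
        x = np.tile([0, 1, 2, 3, 4], 20)
        res = association.polychoric(x, x)
        assert res.rho >= 0.99

    def test_independent_margins_near_zero(self):
        th = synth.equiprobable_thresholds(4)
        data = synth.simulate_ordinal_latent(np.eye(2), [th, th], 5000, seed=2)
        res = association.polychoric(data[:, 0], data[:, 1])
        assert abs(res.rho) < 0.05

    def test_latent_rho_recovered(self):
        th = synth.equiprobable_thresholds(5)
        data = synth.simulate_ordinal_latent(
            [[1.0, 0.6], [0.6, 1.0]], [th, th], 2000, seed=3
        )
        res = association.polychoric(data[:, 0], data[:, 1])
        assert res.rho == pytest.approx(0.6, abs=0.05)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(association.DegenerateMarginError):
            association.polychoric([1] * 50, list(range(5)) * 10)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            association.polychoric([0, 1], [1, 0])

    def test_tetrachoric_consistency_via_cdf_inversion(self):
        # 2x2 case: rho can be found independently by inverting
        # P(X=0, Y=0) = Phi2(t_x, t_y; rho) with a root bracketing search
        rng = np.random.default_rng(8)
        z = rng.standard_normal((4000, 2))
        z[:, 1] = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        x, y = (z[:, 0] > 0.2).astype(int), (z[:, 1] > -0.3).astype(int)
        res = association.polychoric(x, y)
        p00 = np.mean((x == 0) & (y == 0))
        tx = stats.norm.ppf(np.mean(x == 0))
        ty = stats.norm.ppf(np.mean(y == 0))

        def gap(r):
            mvn = stats.multivariate_normal([0, 0], [[1, r], [r, 1]])
            return mvn.cdf([tx, ty]) - p00

        rho_inv = brentq(gap, -0.99, 0.99, xtol=1e-8)
        assert res.rho == pytest.approx(rho_inv, abs=1e-3)


class TestPolychoricMatrix:
    def test_matches_pairwise_calls(self):
        th = synth.equiprobable_thresholds(3)
        corr = synth.one_factor_corr([0.6, 0.6, 0.6])
        data = synth.simulate_ordinal_latent(corr, [th] * 3, 500, seed=4)
        r = association.polychoric_matrix(data)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        for i in range(3):
            for j in range(i + 1, 3):
                pair = association.polychoric(data[:, i], data[:, j]).rho
                assert r[i, j] == pytest.approx(pair, abs=1e-12)

    def test_one_factor_structure_recovered(self):
        loadings = [0.7] * 7
        corr = synth.one_factor_corr(loadings)
        th = synth.equiprobable_thresholds(5)
        data = synth.simulate_ordinal_latent(corr, [th] * 7, 2000, seed=5)
        r = association.polychoric_matrix(data)
        off = ~np.eye(7, dtype=bool)
        assert np.max(np.abs(r[off] - corr[off])) < 0.05


class TestFactorExtract:
    def test_one_factor_retained_with_loadings_recovered(self):
        corr = synth.one_factor_corr([0.7] * 6)
        th = synth.equiprobable_thresholds(5)
        data = synth.simulate_ordinal_latent(corr, [th] * 6, 2000, seed=6)
        fac = association.factor_extract(association.polychoric_matrix(data))
        assert fac.n_retained == 1
        assert np.allclose(fac.loadings[:, 0], 0.7, atol=0.1)

    def test_identity_matrix_retains_nothing(self):
        fac = association.factor_extract(np.eye(6))
        assert fac.n_retained == 0
        assert fac.loadings.shape == (6, 0)

    def test_two_factor_rotation_preserves_communalities(self):
        lam = np.zeros((6, 2))
        lam[:3, 0], lam[3:, 1] = 0.8, 0.8
        corr = lam @ lam.T
        np.fill_diagonal(corr, 1.0)
        fac = association.factor_extract(corr)
        assert fac.n_retained == 2
        # orthogonal rotation: communalities equal row sums of squared loadings
        assert np.allclose(
            fac.communalities, np.sum(fac.loadings**2, axis=1), atol=1e-10
        )
        assert np.allclose(sorted(fac.communalities), sorted(0.64 * np.ones(6)), atol=0.05)

    def test_sign_convention_positive_loading_sums(self):
        corr = synth.one_factor_corr([0.7] * 5)
        fac = association.factor_extract(corr)
        assert fac.loadings[:, 0].sum() > 0


class TestFactorScores:
    def test_constant_variable_rejected(self):
        corr = synth.one_factor_corr([0.7] * 3)
        fac = association.factor_extract(corr)
        data = np.ones((50, 3))
        with pytest.raises(ValueError):
            association.factor_scores(fac, data)

    def test_scores_monotone_in_dominant_variable(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 5, size=(300, 3)).astype(float)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.2
        fac = association.factor_extract(
            synth.one_factor_corr([0.9, 0.3, 0.3]), mineigen=0.5
        )
        s = association.factor_scores(fac, x)[:, 0]
        # raising the dominant variable raises the score
        x2 = x.copy()
        x2[:, 0] += 1.0
        s2 = association.factor_scores(fac, np.vstack([x, x2]))[len(x):, 0]
        s1 = association.factor_scores(fac, np.vstack([x, x2]))[: len(x), 0]
        assert np.all(s2 > s1)

    def test_missing_rows_become_nan(self):
        fac = association.factor_extract(synth.one_factor_corr([0.7] * 3))
        data = np.random.default_rng(1).integers(0, 4, (30, 3)).astype(float)
        data[4, 1] = np.nan
        s = association.factor_scores(fac, data)
        assert np.isnan(s[4, 0]) and np.isfinite(s[5, 0])


class TestFriedman:
    def test_constant_across_digits_gives_zero_statistic(self):
        vals = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = association.friedman_blocked(vals)
        assert res.f_statistic == 0.0 and res.p_value == 1.0
        assert res.chi2 == 0.0

    def test_hand_computed_toy_grid(self):
        # 3 feet x 3 digits, no ties: rank sums are 3, 6, 9
        # chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1) = 12/36*126 - 36 = 6
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [2.0, 3.0, 9.0]])
        res = association.friedman_blocked(vals)
        assert res.chi2 == pytest.approx(6.0, abs=1e-12)

    def test_matches_scipy_on_untied_data(self, rng):
        vals = rng.standard_normal((25, 4))
        res = association.friedman_blocked(vals)
        ref = stats.friedmanchisquare(*vals.T)
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert res.chi2_p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_block_transforms(self, rng):
        vals = rng.standard_normal((15, 3))
        base = association.friedman_blocked(vals)
        warped = vals.copy()
        warped[::2] = np.exp(warped[::2])       # different strictly increasing
        warped[1::2] = np.arctan(warped[1::2])  # map per block
        res = association.friedman_blocked(warped)
        assert res.f_statistic == pytest.approx(base.f_statistic, abs=1e-12)

    def test_missing_blocks_dropped_and_counted(self, rng):
        vals = rng.standard_normal((12, 3))
        vals[3, 1] = np.nan
        res = association.friedman_blocked(vals)
        assert res.n_blocks == 11 and res.n_dropped == 1


class TestCorrelate:
    def test_identity_and_antimonotone(self):
        x = np.arange(10.0)
        assert association.correlate(x, x)[0] == pytest.approx(1.0)
        rs, _ = association.correlate(x, -(x**3), method="spearman")
        assert rs == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # r = cov/(sx sy) on a 5-point example, worked out by hand
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        r, p = association.correlate(x, y)
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            association.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareLevels:
    def test_strong_shift_detected(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        levels = np.repeat([0, 1], 50)
        comp = association.compare_levels(scores, levels)
        assert comp.p_value < 0.05
        assert bool(comp.pairs["reject"].iloc[0])

    def test_identical_constant_groups_find_no_pairs(self):
        scores = np.full(90, 2.5)
        levels = np.repeat([0, 1, 2], 30)
        comp = association.compare_levels(scores, levels)
        assert not comp.pairs["reject"].any()

    def test_small_levels_excluded(self, rng):
        scores = np.concatenate([rng.normal(size=20), [5.0]])
        levels = np.array([0] * 10 + [1] * 10 + [2])
        comp = association.compare_levels(scores, levels)
        assert comp.excluded_levels == [2]

    def test_equal_n_reduces_to_tukey_hsd(self, rng):
        # with equal group sizes the Tukey-Kramer p equals the classic HSD p
        # computed directly from the studentized range distribution
        k, n = 3, 20
        scores = rng.normal(size=k * n)
        levels = np.repeat(np.arange(k), n)
        comp = association.compare_levels(scores, levels)
        groups = scores.reshape(k, n)
        mse = groups.var(axis=1, ddof=1).mean()
        df = k * (n - 1)
        for _, row in comp.pairs.iterrows():
            g1, g2 = int(row["group1"]), int(row["group2"])
            q = abs(groups[g1].mean() - groups[g2].mean()) / np.sqrt(mse / n)
            p_hsd = stats.studentized_range.sf(q, k, df)
            assert row["p-adj"] == pytest.approx(p_hsd, abs=1e-4)
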