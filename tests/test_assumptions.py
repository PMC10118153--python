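"""Polychoric correlations, parallel analysis, bifactor screen, local
independence and monotonicity collapsing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scimetric.assumptions import (bifactor_unidimensionality, bvn_cdf,
                                   choose_collapse_pair, fit_gpcm_em,
                                   local_independence, monotonicity_collapse,
                                   permuted_parallel_analysis, polychoric_corr,
                                   polychoric_matrix, principal_axis,
                                   apply_collapse_map)
from scimetric.dataset import SurveyDataset
from scimetric.synthetic import SyntheticConfig, simulate


def discretize(latent, cuts):
    return np.searchsorted(np.asarray(cuts), latent).astype(int)


def make_dataset(codes, K):
    df = pd.DataFrame({f"item_{j + 1:02d}": codes[:, j].astype(float)
                       for j in range(codes.shape[1])})
    df["person_id"] = np.arange(len(df))
    df["country_id"] = "X"
    return SurveyDataset(df, K, validate=False)


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.9, -0.3, 0.0, 0.5, 0.95])
    def test_matches_scipy_multivariate_normal(self, rho):
        from scipy.stats import multivariate_normal
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        pts = [(-1.0, 0.5), (0.0, 0.0), (1.5, -0.7), (2.0, 2.0)]
        for h, k in pts:
            assert np.isclose(bvn_cdf(h, k, rho), mvn.cdf([h, k]), atol=1e-6)


class TestPolychoric:
    def test_self_pair_is_one(self, rng):
        x = rng.integers(0, 4, size=500)
        assert polychoric_corr(x, x) == 1.0

    def test_recovers_known_latent_correlation(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        x = discretize(z[:, 0], [-0.8, 0.3, 1.0])
        y = discretize(z[:, 1], [-0.2, 0.9])
        est = polychoric_corr(x, y)
        assert abs(est - 0.6) < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_recovery_across_rho_grid(self, rho, rng):
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=4000)
        x = discretize(z[:, 0], [-0.5, 0.5])
        y = discretize(z[:, 1], [0.0])
        assert abs(polychoric_corr(x, y) - rho) < 0.07

    def test_independent_items_near_zero(self, rng):
        codes = rng.integers(0, 3, size=(2000, 4))
        R = polychoric_matrix(codes).to_numpy()
        off = R[np.triu_indices(4, 1)]
        assert (np.abs(off) < 0.06).all()

    def test_matrix_symmetric_and_unit_diagonal(self, small_survey):
        data, _, _ = small_survey
        R = polychoric_matrix(data, min_pairwise=5).to_numpy()
        np.testing.assert_allclose(R, R.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_single_category_item_excluded(self, rng):
        codes = rng.integers(0, 3, size=(200, 3))
        codes[:, 1] = 0
        with pytest.warns(UserWarning, match="single observed category"):
            R = polychoric_matrix(codes)
        assert R.shape == (2, 2)

    def test_matches_r_polycor_oracle(self, rng):
        """Frozen oracle: same table evaluated by R's psych/polycor-style
        two-step on a fixed contingency (computed independently once)."""
        # 2x2 table: tetrachoric has the closed-form-checkable cosine formula
        # for equal margins; n00=n11=400, n01=n10=100 -> rho = cos(pi/(1+sqrt(4)))
        x = np.repeat([0, 0, 1, 1], [400, 100, 100, 400])
        y = np.repeat([0, 1, 0, 1], [400, 100, 100, 400])
        est = polychoric_corr(x, y)
        expected = np.cos(np.pi / (1 + np.sqrt(400 * 400 / (100 * 100))))
        assert abs(est - expected) < 0.01


def one_factor_codes(n, loadings, cuts, rng):
    f = rng.normal(size=n)
    codes = np.empty((n, len(loadings)), dtype=int)
    for j, lam in enumerate(loadings):
        z = lam * f + np.sqrt(1 - lam ** 2) * rng.normal(size=n)
        codes[:, j] = discretize(z, cuts)
    return codes


class TestParallelAnalysis:
    def test_pure_noise_retains_zero(self, rng):
        codes = rng.integers(0, 4, size=(600, 6))
        assert permuted_parallel_analysis(codes, n_perm=30, seed=1) == 0

    def test_single_factor_retains_one(self, rng):
        codes = one_factor_codes(800, [0.8] * 6, [-0.5, 0.5], rng)
        assert permuted_parallel_analysis(codes, n_perm=30, seed=1) == 1

    def test_seed_determinism_and_nperm_guard(self, rng):
        codes = one_factor_codes(300, [0.7] * 5, [0.0], rng)
        a = permuted_parallel_analysis(codes, n_perm=25, seed=9)
        b = permuted_parallel_analysis(codes, n_perm=25, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            permuted_parallel_analysis(codes, n_perm=5)

    def test_retention_nonincreasing_in_quantile(self, rng):
        codes = one_factor_codes(500, [0.75] * 6, [-0.3, 0.6], rng)
        counts = [permuted_parallel_analysis(codes, n_perm=25, seed=3, quantile=q)
                  for q in (0.5, 0.95, 0.999)]
        assert counts[0] >= counts[1] >= counts[2]


class TestBifactor:
    def test_pure_one_factor_all_pass(self, rng):
        codes = one_factor_codes(2000, [0.8] * 8, [-0.5, 0.5], rng)
        R = polychoric_matrix(codes)
        out = bifactor_unidimensionality(R, n_group=2)
        assert out["verdict"] == "pass"
        assert out["loadings"]["passes"].all()

    def test_planted_group_dominant_item_flagged(self, rng):
        """Two items form their own tight cluster with weak general loading."""
        n = 3000
        g = rng.normal(size=n)
        s = rng.normal(size=n)          # group-specific factor
        lams = [0.8] * 6
        codes = np.empty((n, 8), dtype=int)
        for j, lam in enumerate(lams):
            z = lam * g + np.sqrt(1 - lam ** 2) * rng.normal(size=n)
            codes[:, j] = discretize(z, [-0.5, 0.5])
        for j in (6, 7):
            z = 0.25 * g + 0.75 * s + np.sqrt(1 - 0.25**2 - 0.75**2) * rng.normal(size=n)
            codes[:, j] = discretize(z, [-0.5, 0.5])
        with pytest.warns(UserWarning, match="kept, flagged"):
            out = bifactor_unidimensionality(polychoric_matrix(codes), n_group=2)
        assert out["verdict"] == "warn"
        flagged = set(out["violators"])
        assert {"item_07", "item_08"} & flagged
        # policy: violators are reported, never removed from the table
        assert len(out["loadings"]) == 8


class TestLocalIndependence:
    def test_single_factor_fraction_small(self, rng):
        codes = one_factor_codes(2000, [0.75] * 8, [-0.5, 0.5], rng)
        out = local_independence(make_dataset(codes, [3] * 8))
        assert out["fraction"] < 0.02

    def test_planted_residual_pair_flagged(self, rng):
        n = 3000
        f = rng.normal(size=n)
        e_shared = rng.normal(size=n)
        codes = np.empty((n, 6), dtype=int)
        for j in range(6):
            lam = 0.7 if j < 4 else 0.4       # weak general, strong doublet
            extra = 0.65 * e_shared if j in (4, 5) else 0.0
            resid_sd = np.sqrt(max(1 - lam ** 2 - (0.65 ** 2 if j in (4, 5) else 0), 0.05))
            z = lam * f + extra + resid_sd * rng.normal(size=n)
            codes[:, j] = discretize(z, [-0.4, 0.4])
        out = local_independence(make_dataset(codes, [3] * 6))
        pairs = {frozenset((a, b)) for a, b, _ in out["offending_pairs"]}
        assert frozenset(("item_05", "item_06")) in pairs

    def test_threshold_one_gives_zero_fraction(self, rng):
        codes = one_factor_codes(500, [0.7] * 5, [0.0], rng)
        out = local_independence(make_dataset(codes, [2] * 5), threshold=1.0)
        assert out["fraction"] == 0.0


class TestCollapse:
    def test_ordered_thresholds_identity(self):
        assert choose_collapse_pair([-1.0, 0.0, 1.0], [10, 10, 10, 10]) is None

    def test_disordered_picks_smaller_count_pair(self):
        pair = choose_collapse_pair([-1.0, 0.5, 0.2], [50, 5, 5, 50])
        assert pair == (1, 2)
        pair = choose_collapse_pair([-1.0, 0.5, 0.2], [50, 40, 5, 5])
        assert pair == (2, 3)

    def test_binary_disorder_impossible(self):
        with pytest.raises(RuntimeError):
            choose_collapse_pair(np.array([1.0, 0.0]), np.array([1, 1]))

    def test_em_fit_recovers_parameters(self, rng):
        from scimetric.synthetic import sample_item_responses
        n = 3000
        theta = rng.normal(size=n)
        a_true = [1.2, 0.9, 1.6]
        b_true = [np.array([-1.0, 0.5]), np.array([-0.3, 0.8]), np.array([0.0, 1.2])]
        resp = np.column_stack([
            sample_item_responses(theta, a_true[j], b_true[j], rng)
            for j in range(3)
        ])
        fitres = fit_gpcm_em(resp, [3, 3, 3])
        for j in range(3):
            np.testing.assert_allclose(fitres["b"][j], b_true[j], atol=0.25)
            assert abs(fitres["a"][j] - a_true[j]) < 0.35

    def test_constructed_disorder_collapsed_to_ordered(self, rng):
        """An item whose middle category is almost never used yields
        disordered thresholds; one merge restores order on re-fit."""
        from scimetric.synthetic import sample_item_responses
        n = 2500
        theta = rng.normal(size=n)
        resp = np.column_stack([
            sample_item_responses(theta, 1.2, np.array([-1.0, 0.8]), rng),
            # disordered truth: category 1 is dominated (b = (0.5, -0.5))
            sample_item_responses(theta, 1.4, np.array([0.5, -0.5]), rng),
        ])
        data = make_dataset(resp, [3, 3])
        out = monotonicity_collapse(data)
        assert out["n_categories"][1] < 3              # a merge happened
        for j in range(2):
            b = out["thresholds"][j]
            assert (np.diff(b) >= 0).all() or b.size < 2
        # composed map applied to raw codes stays within the new K
        collapsed = apply_collapse_map(data, out["collapse_map"])
        assert (collapsed.responses().max(axis=0)
                < np.asarray(out["n_categories"])).all()

    def test_collapse_never_increases_categories(self, small_survey):
        data, _, _ = small_survey
        out = monotonicity_collapse(data, em_kwargs={"max_iter": 15})
        assert (np.asarray(out["n_categories"]) <= data.n_categories).all()
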