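"""MCMC fitting, convergence diagnostics, model checks and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scimetric.dataset import SurveyDataset
from scimetric.gpcm import PriorSpec, apply_identification
from scimetric.inference import (InsufficientDrawsError, MCMCConfig,
                                 PosteriorChains, ability_to_score, fit,
                                 functioning_scores, gelman_rubin, split_psrf,
                                 posterior_predictive_pvalues, _tail_pvalue)


class TestSplitPSRF:
    def test_same_distribution_segments_near_one(self, rng):
        segs = rng.normal(size=(2, 5000))
        assert 0.99 <= split_psrf(segs) <= 1.01

    def test_shifted_segments_match_hand_formula(self):
        rng = np.random.default_rng(1)
        segs = np.stack([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        got = split_psrf(segs)
        n = 50
        W = segs.var(axis=1, ddof=1).mean()
        B_over_n = segs.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert got > 2.0
        assert np.isclose(got, expected, rtol=1e-12)

    def test_constant_chain_flags_nan(self):
        assert np.isnan(split_psrf(np.ones((2, 100))))

    def test_too_few_draws_raises(self):
        with pytest.raises(InsufficientDrawsError):
            split_psrf(np.zeros((2, 5)))

    def test_matches_arviz_split_rhat(self, rng):
        arviz = pytest.importorskip("arviz")
        draws = rng.normal(size=4000) + np.linspace(0, 0.3, 4000)
        chains2 = draws.reshape(2, 2000)
        ours = split_psrf(draws.reshape(4, 1000))   # same segments arviz splits to
        theirs = float(arviz.rhat(chains2, method="identity"))
        assert np.isclose(ours, theirs, atol=0.01)


def _fake_chains(theta_draws, seed=0, extra=None):
    n_kept, N = theta_draws.shape
    draws = {"theta": theta_draws[None]}
    if extra:
        draws.update({k: v[None] for k, v in extra.items()})
    return PosteriorChains(
        draws=draws,
        n_categories=np.array([3]),
        countries=["X"],
        person_id=np.arange(N),
        person_country=np.zeros(N, int),
        config=MCMCConfig(n_warmup=1, n_iterations=n_kept, seed=seed),
    )


class TestPPPConventions:
    def test_hand_counted_example(self):
        # predicted totals {2,3,3,7,9} vs observed 3 -> (2 + 0.5*2)/5
        pred = np.array([2, 3, 3, 7, 9])
        p = _tail_pvalue((pred > 3).sum(), (pred == 3).sum(), pred.size)
        assert p == pytest.approx(0.6)

    def test_exact_ties_give_half(self):
        p = _tail_pvalue(np.zeros(3), np.full(3, 10), 10)
        np.testing.assert_allclose(p, 0.5)


class TestScores:
    def test_probit_map_fixed_points(self):
        assert ability_to_score(0.0) == pytest.approx(50.0)
        s_hi, s_lo = ability_to_score(1.0), ability_to_score(-1.0)
        assert s_hi + s_lo == pytest.approx(100.0)
        assert 0 < s_lo < 50 < s_hi < 100

    def test_score_strictly_increasing(self):
        grid = np.linspace(-5, 5, 201)
        assert (np.diff(ability_to_score(grid)) > 0).all()

    def test_centered_prior_mean_is_50(self):
        rng = np.random.default_rng(7)
        scores = ability_to_score(rng.normal(size=100_000))
        assert abs(scores.mean() - 50.0) < 0.2

    def test_functioning_scores_frame(self):
        rng = np.random.default_rng(3)
        th = rng.normal(size=(200, 10))
        ch = _fake_chains(th)
        out = functioning_scores(ch)
        assert list(out.columns) == ["person_id", "country_id", "score",
                                     "score_sd", "theta_mean"]
        np.testing.assert_allclose(
            out["score"], ability_to_score(th.mean(axis=0)), rtol=1e-12)
        assert ((out["score"] > 0) & (out["score"] < 100)).all()


@pytest.fixture(scope="module")
def small_fit(small_survey_module=None):
    from scimetric.synthetic import SyntheticConfig, simulate

    cfg = SyntheticConfig(
        n_countries=2, n_per_country=[150, 150], n_items=8,
        categories_per_item=[4] * 8, missing_rate_items=0.05, seed=17,
    )
    data, truth = simulate(cfg)
    chains = fit(data, cfg=MCMCConfig(n_warmup=500, n_iterations=600, seed=17))
    return data, truth, chains


class TestFit:
    def test_prior_only_limit_reproduces_prior(self):
        """With no respondents the mu draws must match their N(0,1) prior."""
        df = pd.DataFrame(columns=["person_id", "country_id", "item_01"])
        data = SurveyDataset(df, [3], countries=["A", "B"], validate=False)
        ch = fit(data, cfg=MCMCConfig(n_warmup=200, n_iterations=4000, seed=8))
        mu = ch.draws["_mu_raw"][0]   # pre-gauge draws target the prior directly
        se = 1.0 / np.sqrt(mu.shape[0])          # conservative iid bound
        assert np.abs(mu.mean(axis=0)).max() < 4 * se * 3
        assert np.allclose(mu.std(axis=0), 1.0, atol=0.1)

    def test_recovery_on_small_synthetic(self, small_fit):
        data, truth, chains = small_fit
        ident = apply_identification(truth)
        r_theta = np.corrcoef(chains.posterior_mean("theta"), ident.theta)[0, 1]
        r_a = np.corrcoef(chains.posterior_mean("a"), truth.a)[0, 1]
        assert r_theta > 0.85
        assert r_a > 0.5

    def test_stored_draws_satisfy_identification(self, small_fit):
        _, _, chains = small_fit
        mask = chains.threshold_mask()
        d = chains.draws
        bstar = d["b"][:, :, None, :, :] + d["delta"]    # (c, i, C, J, V)
        sums = np.nansum(np.where(mask[None, None, None], bstar, 0.0), axis=(3, 4))
        assert np.abs(sums).max() < 1e-9

    def test_seed_determinism(self):
        from scimetric.synthetic import SyntheticConfig, simulate
        cfg = SyntheticConfig(n_countries=2, n_per_country=[40, 40], n_items=4,
                              categories_per_item=[3] * 4, seed=5)
        data, _ = simulate(cfg)
        mc = MCMCConfig(n_warmup=50, n_iterations=50, seed=99)
        c1 = fit(data, cfg=mc)
        c2 = fit(data, cfg=mc)
        np.testing.assert_array_equal(c1.draws["theta"], c2.draws["theta"])
        np.testing.assert_array_equal(c1.draws["tau"], c2.draws["tau"])

    def test_posterior_contraction_with_more_data(self):
        """Doubling country sizes shrinks the posterior SD of mu."""
        from scimetric.synthetic import SyntheticConfig, simulate
        sds = []
        for npc in (60, 240):
            cfg = SyntheticConfig(n_countries=2, n_per_country=[npc] * 2,
                                  n_items=6, categories_per_item=[3] * 6, seed=23)
            data, _ = simulate(cfg)
            ch = fit(data, cfg=MCMCConfig(n_warmup=300, n_iterations=400, seed=23))
            sds.append(ch.draws["mu"][0].std(axis=0).mean())
        assert sds[1] < sds[0]


class TestDiagnosticsOnFit:
    def test_psrf_reasonable_and_ppp_centered(self, small_fit):
        data, _, chains = small_fit
        diag = posterior_predictive_pvalues(chains, data, max_draws=400)
        assert ((diag.ppp_items >= 0) & (diag.ppp_items <= 1)).all()
        # well-specified fit: item-level p-values concentrate near 0.5
        assert np.mean((diag.ppp_items >= 0.2) & (diag.ppp_items <= 0.8)) >= 0.75
        flat = diag.psrf_flat().dropna()
        assert (flat <= 1.2).mean() > 0.9

    def test_gelman_rubin_shapes(self, small_fit):
        _, _, chains = small_fit
        psrf = gelman_rubin(chains)
        assert psrf["theta"].shape == chains.draws["theta"].shape[2:]
        assert np.isfinite(psrf["tau"])
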