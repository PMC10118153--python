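"""Bayesian fitting of the hierarchical GPCM and its model checks.

The sampler is an adaptive Metropolis-within-Gibbs over parameter
blocks (abilities | item parameters | country deviations | country
means and SDs | deviation SD).  Ability, discrimination, threshold and
deviation proposals are vectorized across persons / items / countries,
so a full sweep costs a fixed small number of (N x J) likelihood
evaluations.  Country means are updated by their exact conjugate
Gibbs draw.  Step sizes adapt by Robbins-Monro during warmup
(target acceptance 0.44) and are frozen afterwards.

Every stored draw is re-centered to the identification gauge
(per-country threshold sums = 0), which leaves the likelihood exactly
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr
from scipy.stats import norm, rankdata

from .dataset import SurveyDataset
from .gpcm import GPCMParameters, PriorSpec

__all__ = [
    "MCMCConfig",
    "PosteriorChains",
    "DiagnosticsReport",
    "fit",
    "gelman_rubin",
    "posterior_predictive_pvalues",
    "functioning_scores",
    "ability_to_score",
]


@dataclass
class MCMCConfig:
    """Sampler settings.  ``n_iterations`` counts kept (post-warmup)
    draws; the single-chain default mirrors common practice for this
    model class (>= 2 chains recommended when runtime allows)."""

    n_warmup: int = 1500
    n_iterations: int = 5000
    n_chains: int = 1
    seed: int = 0
    thin: int = 1
    adapt_target: float = 0.44
    identification: str = "per_country"

    def __post_init__(self):
        if min(self.n_warmup, self.n_iterations, self.n_chains, self.thin) < 1:
            raise ValueError("MCMC counts must be positive")


@dataclass
class PosteriorChains:
    """MCMC draws, indexed (chain, iteration, ...parameter shape)."""

    draws: Dict[str, np.ndarray]
    n_categories: np.ndarray
    countries: list
    person_id: np.ndarray
    person_country: np.ndarray
    config: MCMCConfig
    acceptance: Dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=(0, 1))

    def threshold_mask(self) -> np.ndarray:
        vmax = self.draws["b"].shape[-1]
        return np.arange(vmax)[None, :] < (self.n_categories - 1)[:, None]


@dataclass
class DiagnosticsReport:
    psrf: Dict[str, np.ndarray]
    ppp_options: np.ndarray      # (J, Kmax) NaN-padded per-option p-values
    ppp_items: np.ndarray        # (J,) p-values of per-item score totals

    def psrf_flat(self) -> pd.Series:
        vals = {}
        for name, arr in self.psrf.items():
            flat = np.ravel(arr)
            if flat.size == 1:
                vals[name] = float(flat[0])
            else:
                for i, v in enumerate(flat):
                    vals[f"{name}[{i}]"] = float(v)
        return pd.Series(vals)


# ---------------------------------------------------------------------------
# likelihood core (sampler fast path)
# ---------------------------------------------------------------------------

def _loglik_matrix(resp, cidx, theta, a, b, delta, cat_mask, kgrid):
    """(N, J) per-response log-likelihood; 0 where resp == -1."""
    filled = np.nan_to_num(b[None, :, :] + delta, nan=0.0)         # (C,J,V)
    C, J, V = filled.shape
    T = np.concatenate([np.zeros((C, J, 1)), np.cumsum(filled, axis=2)], axis=2)
    logits = a[None, :, None] * (kgrid * theta[:, None, None] - T[cidx])
    logits = np.where(cat_mask[None, :, :], logits, -np.inf)
    lse = logsumexp(logits, axis=2)
    obs = np.take_along_axis(logits, np.clip(resp, 0, None)[:, :, None], axis=2)[:, :, 0]
    return np.where(resp >= 0, obs - lse, 0.0)


def _init_state(resp, cidx, C, K, vmax, rng):
    """Moment-based starting values: rank-normalized sum scores for
    abilities, adjacent-category log-odds for thresholds."""
    N, J = resp.shape
    if N:
        frac = np.ma.masked_less(resp, 0) / (K - 1)[None, :]
        score = np.asarray(frac.mean(axis=1))
        r = rankdata(score, method="average")
        theta = norm.ppf((r - 0.5) / N)
    else:
        theta = np.zeros(0)
    b = np.full((J, vmax), np.nan)
    for j in range(J):
        counts = np.bincount(resp[resp[:, j] >= 0, j], minlength=K[j]) + 1.0 if N else \
            np.ones(K[j])
        counts = counts / counts.sum()
        for v in range(K[j] - 1):
            b[j, v] = np.log(counts[v] / counts[v + 1])
    state = {
        "theta": theta,
        "a": np.ones(J),
        "b": b,
        "delta": np.broadcast_to(np.where(np.isnan(b), np.nan, 0.0), (C, J, vmax)).copy(),
        "mu": np.array([theta[cidx == c].mean() if (cidx == c).any() else 0.0
                        for c in range(C)]),
        "sigma": np.ones(C),
        "tau": 0.3,
    }
    return state


def _rm_update(log_step, accepted, target, t, rate=0.8):
    """Robbins-Monro step-size adaptation on the log scale."""
    gamma = rate / (t + 1) ** 0.6
    return log_step + gamma * (accepted - target)


def fit(
    data: SurveyDataset,
    priors: Optional[PriorSpec] = None,
    cfg: Optional[MCMCConfig] = None,
    progress: bool = False,
) -> PosteriorChains:
    """Sample the posterior of the hierarchical GPCM.

    Targets the density proportional to ``exp(log_likelihood +
    log_prior)``.  Deterministic given ``cfg.seed``.  A dataset with
    zero rows is allowed (prior-only sampling), in which case the
    country set must be declared on the dataset.
    """
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    resp = data.responses()
    N, J = resp.shape
    cidx = data.country_index() if N else np.zeros(0, dtype=int)
    C = data.n_countries
    K = data.n_categories
    vmax = int(K.max()) - 1
    cat_mask = np.arange(vmax + 1)[None, :] < K[:, None]
    thr_mask = np.arange(vmax)[None, :] < (K - 1)[:, None]
    kgrid = np.arange(vmax + 1)[None, None, :].astype(float)
    n_sweeps = cfg.n_warmup + cfg.n_iterations * cfg.thin
    n_valid_thr = int(thr_mask.sum())

    all_draws = []
    acc_totals: Dict[str, list] = {}
    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 777, chain]))
        st = _init_state(resp, cidx, C, K, vmax, rng)
        theta, a, b = st["theta"], st["a"], st["b"]
        delta, mu, sigma, tau = st["delta"], st["mu"], st["sigma"], st["tau"]
        loga = np.log(a)
        LL = _loglik_matrix(resp, cidx, theta, a, b, delta, cat_mask, kgrid)
        if not np.isfinite(LL.sum()):
            raise RuntimeError("non-finite log-likelihood at initialization "
                               "(item-parameter block)")
        if N and not np.isfinite(norm.logpdf(theta, mu[cidx], sigma[cidx]).sum()):
            raise RuntimeError("non-finite ability prior at initialization")

        # per-coordinate log step sizes
        ls_theta = np.full(N, np.log(0.8))
        ls_a = np.full(J, np.log(0.15))
        ls_b = np.full((J, vmax), np.log(0.15))
        ls_delta = np.full((C, J, vmax), np.log(0.25))
        ls_sigma = np.full(C, np.log(0.3))
        ls_tau = np.log(0.3)
        ls_scale = np.log(0.05)
        ls_bd = np.full((J, vmax), np.log(0.2))

        def _prior_terms(loga_, b_, d_, mu_, sig_, tau_, th_):
            """Joint log prior of all blocks (in sampling variables)."""
            lp = norm.logpdf(loga_, priors.a_log_loc, priors.a_log_scale).sum()
            lp += norm.logpdf(b_[thr_mask], priors.b_loc, priors.b_scale).sum()
            lp += norm.logpdf(d_[:, thr_mask], 0.0, tau_).sum()
            lp += norm.logpdf(mu_, priors.mu_loc, priors.mu_scale).sum()
            lp += norm.logpdf(sig_, scale=priors.sigma_scale).sum()
            lp += norm.logpdf(tau_, scale=priors.tau_scale)
            if N:
                lp += norm.logpdf(th_, mu_[cidx], sig_[cidx]).sum()
            return lp

        # Jacobian exponent of the scale gauge move: every scaled variable
        # contributes +log k (theta, mu, sigma, b, delta, tau); log a shifts.
        scale_dim = N + 2 * C + n_valid_thr * (1 + C) + 1

        kept = {
            "theta": np.empty((cfg.n_iterations, N)),
            "a": np.empty((cfg.n_iterations, J)),
            "b": np.empty((cfg.n_iterations, J, vmax)),
            "delta": np.empty((cfg.n_iterations, C, J, vmax)),
            "mu": np.empty((cfg.n_iterations, C)),
            "_mu_raw": np.empty((cfg.n_iterations, C)),
            "sigma": np.empty((cfg.n_iterations, C)),
            "tau": np.empty(cfg.n_iterations),
        }
        acc_ct = {k: 0.0 for k in ("theta", "a", "b", "delta", "sigma", "tau",
                                   "scale")}
        n_kept = 0

        for t in range(n_sweeps):
            adapting = t < cfg.n_warmup

            # ---- abilities -------------------------------------------------
            if N:
                prop = theta + np.exp(ls_theta) * rng.standard_normal(N)
                LLp = _loglik_matrix(resp, cidx, prop, a, b, delta, cat_mask, kgrid)
                logr = (LLp.sum(axis=1) - LL.sum(axis=1)
                        + norm.logpdf(prop, mu[cidx], sigma[cidx])
                        - norm.logpdf(theta, mu[cidx], sigma[cidx]))
                acc = np.log(rng.random(N)) < logr
                theta = np.where(acc, prop, theta)
                LL = np.where(acc[:, None], LLp, LL)
                if adapting:
                    ls_theta = _rm_update(ls_theta, acc, cfg.adapt_target, t)
                else:
                    acc_ct["theta"] += acc.mean()

            # ---- discriminations (log scale) ------------------------------
            loga_p = loga + np.exp(ls_a) * rng.standard_normal(J)
            a_p = np.exp(loga_p)
            LLp = _loglik_matrix(resp, cidx, theta, a_p, b, delta, cat_mask, kgrid)
            logr = (LLp.sum(axis=0) - LL.sum(axis=0)
                    + norm.logpdf(loga_p, priors.a_log_loc, priors.a_log_scale)
                    - norm.logpdf(loga, priors.a_log_loc, priors.a_log_scale))
            acc = np.log(rng.random(J)) < logr
            loga = np.where(acc, loga_p, loga)
            a = np.exp(loga)
            LL = np.where(acc[None, :], LLp, LL)
            if adapting:
                ls_a = _rm_update(ls_a, acc, cfg.adapt_target, t)
            else:
                acc_ct["a"] += acc.mean()

            # ---- overall thresholds, one level at a time -------------------
            for v in range(vmax):
                valid = thr_mask[:, v]
                if not valid.any():
                    continue
                b_p = b.copy()
                step = np.exp(ls_b[:, v]) * rng.standard_normal(J)
                b_p[valid, v] = b[valid, v] + step[valid]
                LLp = _loglik_matrix(resp, cidx, theta, a, b_p, delta, cat_mask, kgrid)
                logr = (LLp.sum(axis=0) - LL.sum(axis=0)
                        + norm.logpdf(b_p[:, v], priors.b_loc, priors.b_scale)
                        - norm.logpdf(b[:, v], priors.b_loc, priors.b_scale))
                acc = valid & (np.log(rng.random(J)) < np.nan_to_num(logr, nan=-np.inf))
                b = np.where(acc[:, None] & (np.arange(vmax) == v)[None, :], b_p, b)
                LL = np.where(acc[None, :], LLp, LL)
                if adapting:
                    ls_b[:, v] = _rm_update(ls_b[:, v], acc, cfg.adapt_target, t)
                else:
                    acc_ct["b"] += acc[valid].mean() / vmax

            # ---- country threshold deviations ------------------------------
            for v in range(vmax):
                valid = thr_mask[:, v]
                if not valid.any():
                    continue
                d_p = delta.copy()
                step = np.exp(ls_delta[:, :, v]) * rng.standard_normal((C, J))
                d_p[:, valid, v] = delta[:, valid, v] + step[:, valid]
                LLp = _loglik_matrix(resp, cidx, theta, a, b, d_p, cat_mask, kgrid)
                diff = np.zeros((C, J))
                if N:
                    np.add.at(diff, cidx, LLp - LL)
                logr = (diff
                        + norm.logpdf(d_p[:, :, v], 0.0, tau)
                        - norm.logpdf(delta[:, :, v], 0.0, tau))
                accm = (np.log(rng.random((C, J))) < np.nan_to_num(logr, nan=-np.inf)) \
                    & valid[None, :]
                delta = np.where(accm[:, :, None] & (np.arange(vmax) == v)[None, None, :],
                                 d_p, delta)
                if N:
                    accrows = accm[cidx, :]
                    LL = np.where(accrows, LLp, LL)
                if adapting:
                    ls_delta[:, :, v] = _rm_update(ls_delta[:, :, v], accm,
                                                   cfg.adapt_target, t)
                else:
                    acc_ct["delta"] += accm[:, valid].mean() / vmax

            # ---- country means: exact conjugate Gibbs ----------------------
            for c in range(C):
                rows = cidx == c
                n_c = int(rows.sum())
                prec = 1.0 / priors.mu_scale ** 2 + n_c / sigma[c] ** 2
                mean = (priors.mu_loc / priors.mu_scale ** 2
                        + (theta[rows].sum() if n_c else 0.0) / sigma[c] ** 2) / prec
                mu[c] = mean + rng.standard_normal() / np.sqrt(prec)

            # ---- country SDs (log scale) -----------------------------------
            logs = np.log(sigma)
            logs_p = logs + np.exp(ls_sigma) * rng.standard_normal(C)
            sig_p = np.exp(logs_p)
            logr = np.zeros(C)
            for c in range(C):
                rows = cidx == c
                if rows.any():
                    logr[c] = (norm.logpdf(theta[rows], mu[c], sig_p[c]).sum()
                               - norm.logpdf(theta[rows], mu[c], sigma[c]).sum())
            # Half-Normal prior + Jacobian of the log transform
            logr += (norm.logpdf(sig_p, scale=priors.sigma_scale)
                     - norm.logpdf(sigma, scale=priors.sigma_scale)
                     + logs_p - logs)
            acc = np.log(rng.random(C)) < logr
            sigma = np.where(acc, sig_p, sigma)
            if adapting:
                ls_sigma = _rm_update(ls_sigma, acc, cfg.adapt_target, t)
            else:
                acc_ct["sigma"] += acc.mean()

            # ---- deviation SD ----------------------------------------------
            logt_p = np.log(tau) + np.exp(ls_tau) * rng.standard_normal()
            tau_p = np.exp(logt_p)
            dvals = delta[:, thr_mask]
            logr = (norm.logpdf(dvals, 0.0, tau_p).sum()
                    - norm.logpdf(dvals, 0.0, tau).sum()
                    + norm.logpdf(tau_p, scale=priors.tau_scale)
                    - norm.logpdf(tau, scale=priors.tau_scale)
                    + logt_p - np.log(tau))
            acc = np.log(rng.random()) < logr
            if acc:
                tau = tau_p
            if adapting:
                ls_tau = _rm_update(ls_tau, float(acc), cfg.adapt_target, t)
            else:
                acc_ct["tau"] += float(acc)

            # ---- threshold gauge move (likelihood-invariant) ---------------
            # b_jv -> b_jv + eps with delta_cjv -> delta_cjv - eps for all c
            # leaves every country threshold b + delta unchanged; only the
            # priors arbitrate the split, so this mixes b against delta.
            eps = np.exp(ls_bd) * rng.standard_normal((J, vmax))
            logr = (norm.logpdf(b + eps, priors.b_loc, priors.b_scale)
                    - norm.logpdf(b, priors.b_loc, priors.b_scale)
                    + (norm.logpdf(delta - eps[None], 0.0, tau)
                       - norm.logpdf(delta, 0.0, tau)).sum(axis=0))
            accm = thr_mask & (np.log(rng.random((J, vmax)))
                               < np.nan_to_num(logr, nan=-np.inf))
            b = np.where(accm, b + eps, b)
            delta = np.where(accm[None], delta - eps[None], delta)
            if adapting:
                ls_bd = _rm_update(ls_bd, accm, cfg.adapt_target, t)

            # ---- scale gauge move (likelihood-invariant) -------------------
            # a_j (theta - b*) is unchanged under theta,b,delta,mu,sigma,tau
            # -> k * (...), a -> a / k; this mixes the softly-identified
            # common-scale direction that couples a with sigma and tau.
            eps = np.exp(ls_scale) * rng.standard_normal()
            k_sc = np.exp(eps)
            logr = (_prior_terms(loga - eps, b * k_sc, delta * k_sc, mu * k_sc,
                                 sigma * k_sc, tau * k_sc, theta * k_sc)
                    - _prior_terms(loga, b, delta, mu, sigma, tau, theta)
                    + scale_dim * eps)
            acc = np.log(rng.random()) < logr
            if acc:
                loga = loga - eps
                a = np.exp(loga)
                b = b * k_sc
                delta = delta * k_sc
                mu = mu * k_sc
                sigma = sigma * k_sc
                tau = tau * k_sc
                theta = theta * k_sc
            if adapting:
                ls_scale = _rm_update(ls_scale, float(acc), cfg.adapt_target, t)
            else:
                acc_ct["scale"] += float(acc)

            # ---- second ability refresh ------------------------------------
            if N:
                prop = theta + np.exp(ls_theta) * rng.standard_normal(N)
                LLp = _loglik_matrix(resp, cidx, prop, a, b, delta, cat_mask, kgrid)
                logr = (LLp.sum(axis=1) - LL.sum(axis=1)
                        + norm.logpdf(prop, mu[cidx], sigma[cidx])
                        - norm.logpdf(theta, mu[cidx], sigma[cidx]))
                accv = np.log(rng.random(N)) < logr
                theta = np.where(accv, prop, theta)
                LL = np.where(accv[:, None], LLp, LL)

            # ---- store identified draw -------------------------------------
            if not adapting and (t - cfg.n_warmup + 1) % cfg.thin == 0:
                bstar = b[None, :, :] + delta
                m_c = np.array([bstar[c][thr_mask].sum() for c in range(C)]) / n_valid_thr
                i = n_kept
                kept["theta"][i] = theta - (m_c[cidx] if N else 0.0)
                kept["a"][i] = a
                kept["b"][i] = b
                d_id = delta.copy()
                d_id[:, thr_mask] -= m_c[:, None]
                kept["delta"][i] = d_id
                kept["mu"][i] = mu - m_c
                kept["_mu_raw"][i] = mu       # pre-gauge, for prior-limit checks
                kept["sigma"][i] = sigma
                kept["tau"][i] = tau
                n_kept += 1
            if progress and (t + 1) % 500 == 0:
                print(f"chain {chain}: sweep {t + 1}/{n_sweeps}", flush=True)

        all_draws.append(kept)
        denom = max(n_sweeps - cfg.n_warmup, 1)
        for k, vv in acc_ct.items():
            acc_totals.setdefault(k, []).append(vv / denom)

    draws = {k: np.stack([d[k] for d in all_draws]) for k in all_draws[0]}
    return PosteriorChains(
        draws=draws,
        n_categories=K,
        countries=list(data.countries),
        person_id=data.df["person_id"].to_numpy() if N else np.zeros(0, dtype=int),
        person_country=cidx,
        config=cfg,
        acceptance={k: float(np.mean(v)) for k, v in acc_totals.items()},
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

class InsufficientDrawsError(ValueError):
    pass


def split_psrf(segments: np.ndarray) -> float:
    """Classical potential scale reduction factor on (m, n) segments.

    NaN (with no exception) when all segments are constant."""
    m, n = segments.shape
    if n < 10:
        raise InsufficientDrawsError(f"need >= 10 draws per segment, got {n}")
    seg_means = segments.mean(axis=1)
    W = segments.var(axis=1, ddof=1).mean()
    B_over_n = seg_means.var(ddof=1)
    if W == 0:
        return np.nan
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def gelman_rubin(chains: PosteriorChains) -> Dict[str, np.ndarray]:
    """Split-chain PSRF for every scalar parameter.

    Single chains are split in half so the statistic stays computable;
    with >= 2 chains each chain is still split (the split-R-hat
    convention).  Constant parameters yield NaN and a warning.
    """
    out: Dict[str, np.ndarray] = {}
    n_flagged = 0
    for name, arr in chains.draws.items():
        if name.startswith("_"):      # auxiliary (gauge-free) traces
            continue
        nc, ni = arr.shape[:2]
        half = ni // 2
        if half < 10:
            raise InsufficientDrawsError("need >= 20 kept draws for split PSRF")
        flat = arr.reshape(nc, ni, -1)[:, : 2 * half]
        segs = np.concatenate([flat[:, :half], flat[:, half: 2 * half]], axis=0)
        vals = np.empty(flat.shape[2])
        for p in range(flat.shape[2]):
            vals[p] = split_psrf(segs[:, :, p])
        n_flagged += int(np.isnan(vals).sum())
        out[name] = vals.reshape(arr.shape[2:]) if arr.ndim > 2 else float(vals[0])
        out[name] = np.asarray(out[name])
    if n_flagged:
        warnings.warn(f"{n_flagged} constant parameter(s) flagged NaN in PSRF")
    return out


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def _tail_pvalue(greater: np.ndarray, equal: np.ndarray, n: int) -> np.ndarray:
    """Half-tie convention: p = P(pred > obs) + 0.5 P(pred = obs)."""
    return (greater + 0.5 * equal) / n


def posterior_predictive_pvalues(
    chains: PosteriorChains,
    data: SurveyDataset,
    max_draws: Optional[int] = None,
) -> DiagnosticsReport:
    """Posterior predictive p-values of item response-option totals.

    At each retained draw a replicate dataset is simulated from that
    draw's parameters with the observed missingness pattern; the
    replicated per-item response-option counts (and per-item response
    totals) are compared with the observed ones.  p approx 0.5 for all
    items indicates the totals are neither under- nor over-predicted.
    """
    resp = data.responses()
    N, J = resp.shape
    cidx = data.country_index()
    K = chains.n_categories
    vmax = int(K.max()) - 1
    cat_mask = np.arange(vmax + 1)[None, :] < K[:, None]
    kgrid = np.arange(vmax + 1)[None, None, :].astype(float)
    obs_mask = resp >= 0

    opt_grid = np.arange(vmax + 1)
    obs_counts = ((resp[:, :, None] == opt_grid) & obs_mask[:, :, None]).sum(axis=0)
    obs_totals = np.where(obs_mask, resp, 0).sum(axis=0)

    d = chains.draws
    nc, ni = d["theta"].shape[:2]
    idx = [(c, i) for c in range(nc) for i in range(ni)]
    if max_draws is not None and len(idx) > max_draws:
        sel = np.linspace(0, len(idx) - 1, max_draws).astype(int)
        idx = [idx[i] for i in sel]
    rng = np.random.default_rng(np.random.SeedSequence([chains.config.seed, 424242]))

    gt_opt = np.zeros((J, vmax + 1))
    eq_opt = np.zeros((J, vmax + 1))
    gt_item = np.zeros(J)
    eq_item = np.zeros(J)
    for c, i in idx:
        filled = np.nan_to_num(d["b"][c, i][None] + d["delta"][c, i], nan=0.0)
        T = np.concatenate([np.zeros((filled.shape[0], J, 1)),
                            np.cumsum(filled, axis=2)], axis=2)
        logits = d["a"][c, i][None, :, None] * (
            kgrid * d["theta"][c, i][:, None, None] - T[cidx]
        )
        logits = np.where(cat_mask[None], logits, -np.inf)
        p = np.exp(logits - logsumexp(logits, axis=2, keepdims=True))
        u = rng.random((N, J, 1))
        sim = (u >= np.cumsum(p, axis=2)).sum(axis=2)
        sim_counts = ((sim[:, :, None] == opt_grid) & obs_mask[:, :, None]).sum(axis=0)
        gt_opt += sim_counts > obs_counts
        eq_opt += sim_counts == obs_counts
        sim_tot = np.where(obs_mask, sim, 0).sum(axis=0)
        gt_item += sim_tot > obs_totals
        eq_item += sim_tot == obs_totals

    n_used = len(idx)
    ppp_opt = _tail_pvalue(gt_opt, eq_opt, n_used)
    ppp_opt = np.where(cat_mask, ppp_opt, np.nan)
    ppp_item = _tail_pvalue(gt_item, eq_item, n_used)
    psrf = gelman_rubin(chains)
    return DiagnosticsReport(psrf=psrf, ppp_options=ppp_opt, ppp_items=ppp_item)


# ---------------------------------------------------------------------------
# 0-100 functioning scores
# ---------------------------------------------------------------------------

def ability_to_score(theta, scale: float = 1.0) -> np.ndarray:
    """Probit map of latent ability to the 0-100 functioning scale.

    ``score = 100 * Phi(theta / scale)``: strictly increasing, bounded
    in (0, 100), and equal to 50 at the centered-prior mean, so scores
    drawn from the standard-normal population prior average 50.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 100.0 * ndtr(np.asarray(theta, dtype=float) / scale)


def functioning_scores(chains: PosteriorChains, scale: float = 1.0) -> pd.DataFrame:
    """Per-person functioning scores from posterior-mean abilities.

    Returns person_id, country, score (= 100 Phi(mean theta / scale))
    and the posterior SD of the per-draw score.
    """
    th = chains.draws["theta"]                     # (chains, iter, N)
    mean_theta = th.mean(axis=(0, 1))
    score = ability_to_score(mean_theta, scale=scale)
    per_draw = ability_to_score(th, scale=scale)
    sd = per_draw.reshape(-1, th.shape[-1]).std(axis=0, ddof=1)
    countries = np.asarray(chains.countries, dtype=object)[chains.person_country]
    return pd.DataFrame({
        "person_id": chains.person_id,
        "country_id": countries,
        "score": score,
        "score_sd": sd,
        "theta_mean": mean_theta,
    })
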