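"""Hierarchical Generalized Partial Credit Model: probability law,
likelihood, priors and the identification constraint.

Model
-----
Person i in country c answers item j (K_j ordered categories) with

    P(X_ij = k | theta_i) = exp( sum_{v<=k} a_j (theta_i - b*_{c,j,v}) )
                            / sum_m exp( sum_{v<=m} a_j (theta_i - b*_{c,j,v}) )

where the empty sum (k = 0) is 0, ``a_j > 0`` is the item
discrimination and the country-specific threshold decomposes as the
overall threshold plus a country deviation,

    b*_{c,j,v} = b_{j,v} + delta_{c,j,v},   delta_{c,j,v} ~ N(0, tau^2).

Abilities are hierarchical, theta_i ~ N(mu_c, sigma_c^2).  The latent
scale is fixed by re-centering so that each country's thresholds sum to
zero (a pure gauge transformation: the likelihood is invariant).

Items with different K_j are held in arrays padded with NaN beyond
K_j - 1 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "GPCMParameters",
    "PriorSpec",
    "category_probabilities",
    "log_likelihood",
    "log_prior",
    "apply_identification",
]


class InvalidItemError(ValueError):
    pass


@dataclass
class GPCMParameters:
    """Full parameter record of the hierarchical GPCM.

    Arrays are padded with NaN where item j has fewer than the maximum
    number of thresholds.

    a : (J,) positive discriminations
    b : (J, Vmax) overall thresholds, row j valid for v < K_j - 1
    delta : (C, J, Vmax) country threshold deviations
    mu, sigma : (C,) country ability means / SDs
    tau : shared SD of the threshold deviations
    theta : (N,) person abilities (optional until a dataset exists)
    person_country : (N,) country index of each person (with theta)
    n_categories : (J,) category counts K_j
    """

    a: np.ndarray
    b: np.ndarray
    delta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    tau: float
    n_categories: np.ndarray
    theta: Optional[np.ndarray] = None
    person_country: Optional[np.ndarray] = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if (self.n_categories < 2).any():
            raise InvalidItemError("items need >= 2 categories")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
        if self.person_country is not None:
            self.person_country = np.asarray(self.person_country, dtype=int)

    @property
    def n_items(self) -> int:
        return self.a.shape[0]

    @property
    def n_countries(self) -> int:
        return self.mu.shape[0]

    @property
    def v_max(self) -> int:
        return self.b.shape[1]

    def threshold_mask(self) -> np.ndarray:
        """(J, Vmax) bool: True where a threshold exists (v < K_j - 1)."""
        return np.arange(self.v_max)[None, :] < (self.n_categories - 1)[:, None]

    def country_thresholds(self) -> np.ndarray:
        """(C, J, Vmax) country-specific thresholds b + delta."""
        return self.b[None, :, :] + self.delta

    def copy(self) -> "GPCMParameters":
        return replace(
            self,
            a=self.a.copy(), b=self.b.copy(), delta=self.delta.copy(),
            mu=self.mu.copy(), sigma=self.sigma.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            person_country=(None if self.person_country is None
                            else self.person_country.copy()),
        )


@dataclass
class PriorSpec:
    """Weakly informative prior hyperparameters (all scales positive).

    log a_j ~ N(a_log_loc, a_log_scale^2); b_{j,v} ~ N(b_loc, b_scale^2);
    delta ~ N(0, tau^2) with tau ~ HalfNormal(tau_scale) shared across
    items; mu_c ~ N(mu_loc, mu_scale^2); sigma_c ~ HalfNormal(sigma_scale).
    """

    a_log_loc: float = 0.0
    a_log_scale: float = 0.5
    b_loc: float = 0.0
    b_scale: float = 2.0
    tau_scale: float = 1.0
    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 1.0

    def __post_init__(self):
        for name in ("a_log_scale", "b_scale", "tau_scale", "mu_scale", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# probability law
# ---------------------------------------------------------------------------

def category_probabilities(theta, a, thresholds) -> np.ndarray:
    """GPCM category probabilities for one item.

    Parameters
    ----------
    theta : scalar or (n,) abilities
    a : discrimination (a = 0 is admitted as the uniform boundary case)
    thresholds : (K-1,) item thresholds (NaN padding is stripped)

    Returns
    -------
    (K,) or (n, K) probabilities, strictly positive, rows sum to 1.
    Overflow-safe via log-sum-exp.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[~np.isnan(thresholds)]
    K = thresholds.size + 1
    if K < 2:
        raise InvalidItemError("an item needs >= 2 categories (>= 1 threshold)")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    # cumulative logits: L_k = sum_{v<=k} a (theta - b_v), L_0 = 0
    steps = a * (theta_arr[:, None] - thresholds[None, :])        # (n, K-1)
    cum = np.concatenate([np.zeros((theta_arr.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    logp = cum - logsumexp(cum, axis=1, keepdims=True)
    p = np.exp(logp)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return p[0]
    return p


def _cumulative_thresholds(params: GPCMParameters) -> tuple[np.ndarray, np.ndarray]:
    """Precompute T[c, j, k] = sum_{v<=k} (b+delta)_{c,j,v} (T[..,0] = 0)
    and the (J, Kmax) category-validity mask."""
    bstar = params.country_thresholds()           # (C, J, Vmax)
    filled = np.nan_to_num(bstar, nan=0.0)
    C, J, V = filled.shape
    T = np.concatenate(
        [np.zeros((C, J, 1)), np.cumsum(filled, axis=2)], axis=2
    )                                             # (C, J, Kmax) with Kmax = V+1
    cat_mask = np.arange(V + 1)[None, :] < params.n_categories[:, None]
    return T, cat_mask


def response_loglik_matrix(
    resp: np.ndarray,
    country_idx: np.ndarray,
    params: GPCMParameters,
    theta: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(N, J) log P(x_ij | theta_i) with 0 where x_ij is missing (-1).

    The sampler's workhorse: fully vectorized over persons, items and
    categories.
    """
    theta = params.theta if theta is None else theta
    T, cat_mask = _cumulative_thresholds(params)
    kgrid = np.arange(T.shape[2])[None, None, :]                   # (1,1,K)
    logits = params.a[None, :, None] * (
        kgrid * theta[:, None, None] - T[country_idx]
    )                                                              # (N,J,K)
    logits = np.where(cat_mask[None, :, :], logits, -np.inf)
    lse = logsumexp(logits, axis=2)
    obs = np.take_along_axis(logits, np.clip(resp, 0, None)[:, :, None], axis=2)[:, :, 0]
    ll = obs - lse
    return np.where(resp >= 0, ll, 0.0)


def log_likelihood(data, params: GPCMParameters, theta: Optional[np.ndarray] = None) -> float:
    """Total log-likelihood of a :class:`~scimetric.dataset.SurveyDataset`.

    Missing responses contribute 0.  Raises on codes >= K_j.
    """
    resp = data.responses()
    if (resp >= params.n_categories[None, :]).any():
        raise ValueError("response code out of range for its item")
    if resp.shape[0] == 0:
        return 0.0
    cidx = data.country_index()
    return float(response_loglik_matrix(resp, cidx, params, theta=theta).sum())


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _half_normal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.log(2.0) + norm.logpdf(x, scale=scale)
    return np.where(x > 0, out, -np.inf)


def log_prior(params: GPCMParameters, priors: PriorSpec) -> float:
    """Sum of log prior densities over every parameter block.

    Returns -inf (never raises) when a scale parameter leaves its
    support, so samplers can simply reject.
    """
    if (params.a <= 0).any():
        return -np.inf
    if (params.sigma <= 0).any() or params.tau <= 0:
        return -np.inf
    mask = params.threshold_mask()
    lp = 0.0
    lp += norm.logpdf(np.log(params.a), priors.a_log_loc, priors.a_log_scale).sum()
    lp -= np.log(params.a).sum()  # Jacobian: density of a, not log a
    lp += norm.logpdf(params.b[mask], priors.b_loc, priors.b_scale).sum()
    lp += norm.logpdf(params.delta[:, mask], 0.0, params.tau).sum()
    lp += float(_half_normal_logpdf(params.tau, priors.tau_scale))
    lp += norm.logpdf(params.mu, priors.mu_loc, priors.mu_scale).sum()
    lp += _half_normal_logpdf(params.sigma, priors.sigma_scale).sum()
    if params.theta is not None:
        if params.person_country is None:
            raise ValueError("theta present but person_country missing")
        c = params.person_country
        lp += norm.logpdf(params.theta, params.mu[c], params.sigma[c]).sum()
    return float(lp)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def apply_identification(params: GPCMParameters, mode: str = "per_country") -> GPCMParameters:
    """Fix the latent-scale gauge so country threshold sums are zero.

    ``per_country`` (default): for each country c the mean m_c of its
    thresholds (b + delta over all items and levels) is subtracted from
    that country's deviations and likewise from mu_c and from the theta
    of its residents (theta - b is untouched) — the likelihood is
    exactly unchanged and afterwards sum_{j,v} (b + delta)_{c,j,v} = 0
    for every c.

    ``per_item``: alternative reading — deviations are centered across
    countries within each (item, level), with the removed mean folded
    into the overall thresholds b.
    """
    out = params.copy()
    mask = params.threshold_mask()
    if mode == "per_country":
        bstar = out.country_thresholds()              # (C, J, V)
        m_c = np.array([bstar[c][mask].mean() for c in range(out.n_countries)])
        out.delta[:, mask] -= m_c[:, None]
        out.mu = out.mu - m_c
        if out.theta is not None:
            if out.person_country is None:
                raise ValueError("theta present but person_country missing")
            out.theta = out.theta - m_c[out.person_country]
    elif mode == "per_item":
        mean_c = np.where(mask[None, :, :], out.delta, 0.0).mean(axis=0)
        out.delta = out.delta - mean_c[None, :, :]
        out.b = out.b + mean_c
    else:
        raise ValueError(f"unknown identification mode: {mode}")
    return out
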