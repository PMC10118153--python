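"""Pre-fit IRT assumption battery.

Three assumptions are screened before fitting the hierarchical GPCM:

* **Unidimensionality** — a bifactor (Schmid-Leiman) solution on the
  polychoric correlation matrix must show every item loading high on
  the general factor and higher there than on any group factor, with
  the number of group factors chosen by permuted parallel analysis.
* **Local independence** — residual correlations after removing a
  single factor must stay below 0.25 in absolute value.
* **Monotonicity** — estimated GPCM thresholds of each item must be
  ordered; items with disordered thresholds have adjacent response
  options collapsed (smaller-count pair first) and are re-fit until
  ordered.

Items failing the bifactor screen are flagged and *kept* — the checks
warn, they never silently drop items.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .dataset import SurveyDataset

__all__ = [
    "AssumptionReport",
    "polychoric_matrix",
    "polychoric_corr",
    "permuted_parallel_analysis",
    "bifactor_unidimensionality",
    "local_independence",
    "monotonicity_collapse",
    "fit_gpcm_em",
    "run_assumptions",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF (vectorized; Plackett's identity)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses Phi(h)Phi(k) + integral_0^rho phi2(h, k, r) dr evaluated by
    32-point Gauss-Legendre; accurate to ~1e-7 for |rho| <= 0.99.
    """
    h = np.clip(np.asarray(h, dtype=float), -8.5, 8.5)
    k = np.clip(np.asarray(k, dtype=float), -8.5, 8.5)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)            # map [-1,1] -> [0, rho]
    w = 0.5 * rho * _GL_WEIGHTS
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - r ** 2
    pdf2 = np.exp(-(hh ** 2 - 2.0 * r * hh * kk + kk ** 2) / (2.0 * om)) \
        / (2.0 * np.pi * np.sqrt(om))
    return base + (pdf2 * w).sum(axis=-1)


def _cell_probabilities(cuts1: np.ndarray, cuts2: np.ndarray, rho: float) -> np.ndarray:
    """(K1, K2) rectangle probabilities from cutpoint vectors (incl +/-inf)."""
    g1, g2 = np.meshgrid(cuts1, cuts2, indexing="ij")
    F = bvn_cdf(g1, g2, rho)
    cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def _cutpoints(codes: np.ndarray, k_max: Optional[int] = None) -> np.ndarray:
    """Normal quantile cutpoints from marginal ordinal frequencies."""
    counts = np.bincount(codes, minlength=k_max or codes.max() + 1).astype(float)
    cum = np.cumsum(counts) / counts.sum()
    inner = norm.ppf(np.clip(cum[:-1], 1e-10, 1 - 1e-10))
    return np.concatenate([[-np.inf], inner, [np.inf]])


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation of two ordinal code vectors.

    Step 1: cutpoints from each margin via Normal quantiles; step 2:
    ML over the latent correlation of the discretized bivariate normal.
    Pairwise-complete observations only (codes < 0 treated as missing).
    """
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return np.nan
    if np.array_equal(x, y):
        return 1.0
    kx, ky = x.max() + 1, y.max() + 1
    if kx < 2 or ky < 2:
        return np.nan
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    cuts1, cuts2 = _cutpoints(x), _cutpoints(y)

    def neg_ll(rho):
        return -(table * np.log(_cell_probabilities(cuts1, cuts2, rho))).sum()

    res = minimize_scalar(neg_ll, bounds=(-0.995, 0.995), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def _nearest_pd(R: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Eigenvalue-clipping repair to the nearest PD correlation matrix."""
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-10:
        return R, False
    w = np.clip(w, 1e-8, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def polychoric_matrix(
    data,
    min_pairwise: int = 30,
) -> pd.DataFrame:
    """Polychoric correlation matrix of a dataset's functioning items.

    Items with a single observed category are excluded with a warning;
    pairs below the pairwise-complete floor are estimated anyway but
    warned about; a non-PD result is repaired by eigenvalue clipping
    (and warned about).

    Accepts a :class:`SurveyDataset` or an (N, J) integer code matrix
    (-1 = missing).  Returns a DataFrame labelled by item columns.
    """
    if isinstance(data, SurveyDataset):
        resp = data.responses()
        labels = data.item_columns
    else:
        resp = np.asarray(data, dtype=int)
        labels = [f"item_{j + 1:02d}" for j in range(resp.shape[1])]
    J = resp.shape[1]
    keep = []
    for j in range(J):
        obs = resp[resp[:, j] >= 0, j]
        if np.unique(obs).size < 2:
            warnings.warn(f"{labels[j]} has a single observed category; excluded")
        else:
            keep.append(j)
    R = np.eye(len(keep))
    for ii, j1 in enumerate(keep):
        for jj in range(ii + 1, len(keep)):
            j2 = keep[jj]
            ok = (resp[:, j1] >= 0) & (resp[:, j2] >= 0)
            if ok.sum() < min_pairwise:
                warnings.warn(
                    f"pair ({labels[j1]}, {labels[j2]}) has only {int(ok.sum())} "
                    f"pairwise-complete observations (< {min_pairwise})"
                )
            R[ii, jj] = R[jj, ii] = polychoric_corr(resp[:, j1], resp[:, j2])
    R, repaired = _nearest_pd(R)
    if repaired:
        warnings.warn("polychoric matrix was not positive definite; repaired")
    names = [labels[j] for j in keep]
    return pd.DataFrame(R, index=names, columns=names)


# ---------------------------------------------------------------------------
# factor machinery (least squares)
# ---------------------------------------------------------------------------

def principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 200,
                   tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis (least-squares) factoring; (p, k) loadings."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))   # squared multiple correlations
        h2 = np.clip(h2, 0.05, 0.98)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1][:n_factors]
        L = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
        h2_new = np.clip((L ** 2).sum(axis=1), 0.0, 0.995)
        if np.abs(h2_new - h2).max() < tol:
            h2 = h2_new
            break
        h2 = h2_new
    # orient each factor positively
    sign = np.sign(L.sum(axis=0))
    sign[sign == 0] = 1.0
    return L * sign[None, :]


def varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    p, k = L.shape
    if k < 2:
        return L.copy()
    Rm = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lam = L @ Rm
        u, s, vt = np.linalg.svd(
            L.T @ (Lam ** 3 - Lam @ np.diag((Lam ** 2).sum(axis=0)) / p)
        )
        Rm = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ Rm


def promax(L: np.ndarray, power: int = 4) -> Tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation; returns (pattern loadings, factor corr)."""
    V = varimax(L)
    if V.shape[1] < 2:
        return V, np.eye(1)
    P = V * np.abs(V) ** (power - 1)
    U = np.linalg.lstsq(V, P, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d[None, :]
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def bifactor_unidimensionality(
    R,
    n_group: int,
    general_cutoff: float = 0.4,
) -> dict:
    """Bifactor screen of unidimensionality on a correlation matrix.

    A Schmid-Leiman solution is built from least-squares factoring:
    ``n_group`` first-order factors, promax-rotated, with a single
    second-order factor of their correlations; general loadings are the
    first-order pattern times the second-order loadings, group loadings
    the residualized first-order pattern.  An item passes when its
    general loading is at least ``general_cutoff`` *and* not exceeded
    by any group loading.  Violators are flagged and kept.

    Returns a dict with ``loadings`` (DataFrame: general, group_*,
    passes), ``verdict`` ("pass" | "warn") and ``violators``.
    """
    if n_group < 1:
        raise ValueError("n_group must be >= 1")
    if isinstance(R, pd.DataFrame):
        names = list(R.index)
        Rm = R.to_numpy()
    else:
        Rm = np.asarray(R, dtype=float)
        names = [f"item_{j + 1:02d}" for j in range(Rm.shape[0])]
    Rm, _ = _nearest_pd(Rm)
    L1 = principal_axis(Rm, n_group)
    pattern, phi = promax(L1)
    if n_group == 1:
        general = pattern[:, 0]
        group = np.zeros_like(pattern)
    else:
        gamma = principal_axis(phi, 1)[:, 0]
        gamma = np.clip(np.abs(gamma), 0.0, 0.999)
        general = pattern @ gamma
        group = pattern * np.sqrt(1.0 - gamma ** 2)[None, :]
    if general.sum() < 0:      # factor direction is arbitrary; orient positively
        general = -general
    max_group = np.abs(group).max(axis=1)
    passes = (general >= general_cutoff) & (general >= max_group)
    table = pd.DataFrame(
        {"general": general, **{f"group_{k + 1}": group[:, k] for k in range(n_group)},
         "passes": passes},
        index=names,
    )
    violators = [n for n, ok in zip(names, passes) if not ok]
    if violators:
        warnings.warn(
            "items loading higher on a group factor than the general factor "
            f"(kept, flagged): {violators}"
        )
    return {
        "loadings": table,
        "verdict": "pass" if not violators else "warn",
        "violators": violators,
    }


def permuted_parallel_analysis(
    data,
    n_perm: int = 100,
    seed: int = 0,
    quantile: float = 0.95,
    min_pairwise: int = 2,
) -> int:
    """Factor count retained by permuted parallel analysis.

    Observed polychoric eigenvalues are compared position-wise with the
    ``quantile`` of eigenvalues obtained after permuting each item
    column independently (which destroys inter-item structure while
    preserving margins); the retained count is the number of leading
    observed eigenvalues exceeding their permutation benchmark.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    resp = data.responses() if isinstance(data, SurveyDataset) else np.asarray(data, int)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R_obs = polychoric_matrix(resp, min_pairwise=min_pairwise).to_numpy()
        eig_obs = np.sort(np.linalg.eigvalsh(R_obs))[::-1]
        eig_perm = np.empty((n_perm, eig_obs.size))
        for s in range(n_perm):
            perm = np.column_stack(
                [rng.permutation(resp[:, j]) for j in range(resp.shape[1])]
            )
            Rp = polychoric_matrix(perm, min_pairwise=min_pairwise).to_numpy()
            eig_perm[s] = np.sort(np.linalg.eigvalsh(Rp))[::-1]
    bench = np.quantile(eig_perm, quantile, axis=0)
    above = eig_obs > bench
    # leading run: retention stops at the first non-exceeding eigenvalue
    n_keep = 0
    for flag in above:
        if not flag:
            break
        n_keep += 1
    return n_keep


def local_independence(
    data,
    threshold: float = 0.25,
    R: Optional[pd.DataFrame] = None,
) -> dict:
    """Residual-correlation screen of local independence.

    Fits a single factor to the polychoric matrix by least squares and
    reports the fraction of off-diagonal residual correlations
    (R - lambda lambda') exceeding ``threshold`` in absolute value,
    plus the offending pairs.
    """
    if R is None:
        R = polychoric_matrix(data)
    names = list(R.index)
    Rm = R.to_numpy()
    lam = principal_axis(Rm, 1)[:, 0]
    resid = Rm - np.outer(lam, lam)
    iu = np.triu_indices(len(names), k=1)
    vals = resid[iu]
    bad = np.abs(vals) > threshold
    pairs = [(names[i], names[j], float(resid[i, j]))
             for i, j in zip(*iu) for _ in [0] if abs(resid[i, j]) > threshold]
    return {
        "fraction": float(bad.mean()) if vals.size else 0.0,
        "offending_pairs": pairs,
        "threshold": threshold,
        "loadings": pd.Series(lam, index=names),
        "residuals": pd.DataFrame(resid, index=names, columns=names),
    }


# ---------------------------------------------------------------------------
# single-group GPCM (EM over Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

def _gh_nodes(n: int = 31) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _item_logprobs(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(Q, K) log category probabilities at the quadrature nodes."""
    steps = a * (nodes[:, None] - b[None, :])
    cum = np.concatenate([np.zeros((nodes.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    from scipy.special import logsumexp as _lse
    return cum - _lse(cum, axis=1, keepdims=True)


def fit_gpcm_em(
    resp: np.ndarray,
    n_categories: np.ndarray,
    n_quad: int = 31,
    max_iter: int = 60,
    tol: float = 1e-4,
) -> dict:
    """Quick marginal-ML GPCM fit for a single group (EM algorithm).

    Abilities are integrated over a fixed N(0,1) population via
    Gauss-Hermite quadrature; the M-step maximizes each item's expected
    complete-data log-likelihood over (log a_j, b_j).  Used as the
    pre-fit behind the monotonicity check (thresholds are *not*
    order-constrained, so disorder can surface).

    Returns dict with 'a' (J,), 'b' (list of (K_j - 1,) arrays),
    'loglik'.
    """
    resp = np.asarray(resp, dtype=int)
    N, J = resp.shape
    K = np.asarray(n_categories, dtype=int)
    nodes, wq = _gh_nodes(n_quad)
    Q = nodes.size
    a = np.ones(J)
    b = [np.linspace(-1.0, 1.0, K[j] - 1) for j in range(J)]
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step: posterior over nodes per person
        logw = np.broadcast_to(np.log(wq), (N, Q)).copy()
        for j in range(J):
            lp = _item_logprobs(a[j], b[j], nodes)       # (Q, K_j)
            obs = resp[:, j]
            ok = obs >= 0
            logw[ok] += lp[:, obs[ok]].T
        from scipy.special import logsumexp as _lse
        norm_c = _lse(logw, axis=1)
        ll = float(norm_c.sum())
        W = np.exp(logw - norm_c[:, None])               # (N, Q)
        # M-step: per item on expected Q x K count tables
        for j in range(J):
            obs = resp[:, j]
            ok = obs >= 0
            counts = np.zeros((Q, K[j]))
            oh = np.eye(K[j])[obs[ok]]                   # (n_ok, K)
            counts += W[ok].T @ oh

            def neg(params, counts=counts, Kj=K[j]):
                aa = np.exp(params[0])
                bb = params[1:]
                lp = _item_logprobs(aa, bb, nodes)
                return -(counts * lp).sum()

            x0 = np.concatenate([[np.log(a[j])], b[j]])
            res = minimize(neg, x0, method="L-BFGS-B")
            a[j] = np.exp(res.x[0])
            b[j] = res.x[1:]
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return {"a": a, "b": b, "loglik": ll}


# ---------------------------------------------------------------------------
# monotonicity / collapsing
# ---------------------------------------------------------------------------

def choose_collapse_pair(thresholds: np.ndarray, counts: np.ndarray) -> Optional[Tuple[int, int]]:
    """Adjacent category pair to merge for a disordered threshold vector.

    Returns None when thresholds are ordered.  The first descent
    b[v+1] < b[v] involves categories (v, v+1, v+2); of the two
    adjacent pairs the one with the smaller combined count is merged.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    counts = np.asarray(counts, dtype=float)
    K = counts.size
    diffs = np.diff(thresholds)
    disordered = thresholds.size >= 2 and (diffs < 0).any()
    if K == 2 and disordered:
        raise RuntimeError("a 2-category item cannot have disordered thresholds")
    if not disordered:
        return None
    v = int(np.argmax(diffs < 0))       # first descent, between thresholds v and v+1
    pair_lo = (v, v + 1)
    pair_hi = (v + 1, v + 2)
    if counts[list(pair_lo)].sum() <= counts[list(pair_hi)].sum():
        return pair_lo
    return pair_hi


def monotonicity_collapse(
    data: SurveyDataset,
    max_rounds: int = 10,
    n_quad: int = 31,
    em_kwargs: Optional[dict] = None,
) -> dict:
    """Iteratively collapse response options until thresholds are ordered.

    A single-group GPCM is fit by EM; any item with non-increasing...
    strictly decreasing adjacent thresholds is collapsed by merging the
    smaller-count adjacent category pair at the first disorder, the
    model is re-fit, and the loop repeats until every item's thresholds
    are ordered or only two categories remain.

    Returns a dict with ``collapse_map`` (item column -> old-code ->
    new-code, identity where nothing happened), the collapsed response
    matrix, final category counts and the final fitted thresholds.
    """
    resp = data.responses().copy()
    K = data.n_categories.copy()
    J = data.n_items
    cmap = {data.item_columns[j]: {k: k for k in range(K[j])} for j in range(J)}
    em_kwargs = em_kwargs or {}
    fitres = None
    for _ in range(max_rounds):
        fitres = fit_gpcm_em(resp, K, n_quad=n_quad, **em_kwargs)
        changed = False
        for j in range(J):
            counts = np.bincount(resp[resp[:, j] >= 0, j], minlength=K[j])
            pair = choose_collapse_pair(fitres["b"][j], counts)
            if pair is None:
                continue
            lo, hi = pair
            obs = resp[:, j] >= 0
            resp[obs & (resp[:, j] >= hi), j] -= 1
            K[j] -= 1
            col = data.item_columns[j]
            for old, new in cmap[col].items():
                if new >= hi:
                    cmap[col][old] = new - 1
            changed = True
        if not changed:
            break
    return {
        "collapse_map": cmap,
        "responses": resp,
        "n_categories": K,
        "thresholds": fitres["b"] if fitres else None,
        "discriminations": fitres["a"] if fitres else None,
    }


def apply_collapse_map(data: SurveyDataset, cmap: Dict[str, Dict[int, int]]) -> SurveyDataset:
    """Recode a dataset's item columns through a collapse map."""
    df = data.df.copy()
    new_K = []
    for j, col in enumerate(data.item_columns):
        mapping = cmap.get(col, {})
        if mapping:
            df[col] = df[col].map(lambda v: mapping.get(int(v), v) if pd.notna(v) else v)
            new_K.append(max(mapping.values()) + 1)
        else:
            new_K.append(data.n_categories[j])
    return SurveyDataset(df, new_K, countries=data.countries, validate=False,
                         truth=data.truth)


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@dataclass
class AssumptionReport:
    polychoric: pd.DataFrame
    n_factors_retained: int
    bifactor: dict
    local_independence: dict
    collapse_map: Dict[str, Dict[int, int]]
    collapsed_categories: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "polychoric": self.polychoric.round(6).to_dict(),
            "n_factors_retained": int(self.n_factors_retained),
            "bifactor_verdict": self.bifactor["verdict"],
            "bifactor_violators": self.bifactor["violators"],
            "bifactor_loadings": self.bifactor["loadings"].round(6).to_dict(),
            "local_independence_fraction": self.local_independence["fraction"],
            "local_independence_pairs": self.local_independence["offending_pairs"],
            "collapse_map": {k: {str(o): int(n) for o, n in v.items()}
                             for k, v in self.collapse_map.items()},
            "collapsed_categories": [int(k) for k in self.collapsed_categories],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_assumptions(
    data: SurveyDataset,
    n_perm: int = 100,
    seed: int = 0,
    general_cutoff: float = 0.4,
    li_threshold: float = 0.25,
) -> AssumptionReport:
    """Run the whole battery and return a serializable report."""
    R = polychoric_matrix(data)
    n_keep = permuted_parallel_analysis(data, n_perm=n_perm, seed=seed)
    bif = bifactor_unidimensionality(R, n_group=max(n_keep, 1),
                                     general_cutoff=general_cutoff)
    li = local_independence(data, threshold=li_threshold, R=R)
    col = monotonicity_collapse(data)
    return AssumptionReport(
        polychoric=R,
        n_factors_retained=n_keep,
        bifactor=bif,
        local_independence=li,
        collapse_map=col["collapse_map"],
        collapsed_categories=col["n_categories"],
    )
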