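"""Instrument recoding, age grouping and functioning-trend regressions.

For each country and lesion level (paraplegia / tetraplegia) the
functioning score is regressed on one continuous predictor at a time —
chronological age, age at injury or time since injury — by ordinary
least squares with no further adjustment.  For plotting, scores are
summarized per age bin with t-based 95% confidence intervals
(single-member bins report the mean only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendFit",
    "dichotomize_items",
    "age_bins",
    "trend_regression",
    "fit_all_trends",
    "DEFAULT_AGE_SCHEME",
]

#: Default 15-year age grouping: 16-30, 31-45, 46-60, 61-75, 76+.
DEFAULT_AGE_SCHEME = (30, 45, 60, 75)

PREDICTORS = ("chronological_age", "age_at_injury", "time_since_injury")

# SCIM self-report / secondary-condition items: code 0 = full
# independence / never a problem; anything above indicates a problem.
_DICHOTOMIZERS = {
    "SCIM": lambda codes, k: (codes < k - 1).astype(float),      # top code = independent
    "SCS-SCI": lambda codes, k: (codes > 0).astype(float),       # 0 = never a problem
    "intensity": lambda codes, k: codes.astype(float),           # no recode
}


def dichotomize_items(codes, instrument: str, n_categories: Optional[int] = None):
    """Map ordinal instrument codes to {0 = no problem, 1 = problem}.

    SCIM items (independence scales, highest code = fully independent)
    become 0 only at the top code; SCS-SCI items (problem frequency,
    0 = never) become 1 for any nonzero code; ``intensity`` items are
    passed through unchanged.  Missing entries (NaN or -1) stay missing.
    """
    if instrument not in _DICHOTOMIZERS:
        raise ValueError(f"unknown instrument tag: {instrument!r}")
    arr = np.asarray(codes, dtype=float)
    missing = np.isnan(arr) | (arr < 0)
    k = n_categories if n_categories is not None else int(np.nanmax(np.where(missing, np.nan, arr)) + 1)
    out = _DICHOTOMIZERS[instrument](np.nan_to_num(arr, nan=0).astype(int), k)
    out = out.astype(float)
    out[missing] = np.nan
    return out


def age_bins(values, scheme: Sequence[float] = DEFAULT_AGE_SCHEME) -> pd.Categorical:
    """Bin nonnegative ages into labelled groups (upper bound closed).

    Under the default scheme 45 falls in "31-45" and 46 in "46-60";
    the last bin is open-ended ("76+").
    """
    values = np.asarray(values, dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("negative ages are invalid")
    edges = [0.0, *scheme, np.inf]
    labels = []
    prev = 0
    for e in scheme:
        labels.append(f"{prev + 1 if prev else 16}-{int(e)}" if not prev else f"{int(prev) + 1}-{int(e)}")
        prev = e
    labels.append(f"{int(prev) + 1}+")
    return pd.cut(values, bins=edges, labels=labels, right=True, include_lowest=True)


@dataclass
class TrendFit:
    country: str
    lesion_level: str
    predictor: str
    slope: float
    intercept: float
    p_value: float
    n: int
    bin_summary: Optional[pd.DataFrame] = None
    note: str = ""

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.slope)


def _bin_summary(scores, predictor, scheme) -> pd.DataFrame:
    g = pd.DataFrame({"bin": age_bins(predictor, scheme), "score": scores})
    rows = []
    for label, grp in g.groupby("bin", observed=False):
        n = len(grp)
        if n == 0:
            continue
        m = grp["score"].mean()
        if n == 1:
            rows.append((label, n, m, np.nan, np.nan))
        else:
            se = grp["score"].std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            rows.append((label, n, m, m - tcrit * se, m + tcrit * se))
    return pd.DataFrame(rows, columns=["bin", "n", "mean", "ci_lo", "ci_hi"])


def trend_regression(
    scores,
    predictor_values,
    subgroup_mask=None,
    country: str = "",
    lesion_level: str = "",
    predictor: str = "",
    age_scheme: Sequence[float] = DEFAULT_AGE_SCHEME,
) -> TrendFit:
    """OLS of functioning score on one predictor within a subgroup.

    Subgroups with fewer than 3 complete observations or zero
    predictor variance yield an NA fit (flagged, never dropped).
    """
    scores = np.asarray(scores, dtype=float)
    x = np.asarray(predictor_values, dtype=float)
    mask = np.ones(scores.shape, bool) if subgroup_mask is None else np.asarray(subgroup_mask, bool)
    mask = mask & np.isfinite(scores) & np.isfinite(x)
    n = int(mask.sum())
    if n < 3 or np.var(x[mask]) == 0:
        note = "n < 3" if n < 3 else "zero predictor variance"
        warnings.warn(f"trend fit skipped ({country}/{lesion_level}/{predictor}): {note}")
        return TrendFit(country, lesion_level, predictor,
                        np.nan, np.nan, np.nan, n, None, note)
    res = stats.linregress(x[mask], scores[mask])
    pval = res.pvalue if np.isfinite(res.pvalue) else 1.0
    summary = _bin_summary(scores[mask], x[mask], age_scheme)
    return TrendFit(country, lesion_level, predictor,
                    float(res.slope), float(res.intercept), float(pval), n, summary)


def fit_all_trends(
    scores_df: pd.DataFrame,
    data,
    age_scheme: Sequence[float] = DEFAULT_AGE_SCHEME,
) -> pd.DataFrame:
    """Per-country, per-lesion-level trend fits for all three predictors.

    ``scores_df`` is the output of
    :func:`scimetric.inference.functioning_scores`; demographics come
    from the survey dataset.  Persons with missing lesion level are
    excluded from the stratified fits (and counted in the ``excluded``
    attribute of the result).  Every (country x lesion x predictor)
    cell appears in the output, NA-flagged when unfittable.
    """
    df = data.df.merge(scores_df[["person_id", "score"]], on="person_id", how="inner")
    excluded = int(df["lesion_level"].isna().sum())
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for country in data.countries:
            for lesion in ("paraplegia", "tetraplegia"):
                sub = df[(df["country_id"] == country) & (df["lesion_level"] == lesion)]
                for pred in PREDICTORS:
                    tf = trend_regression(
                        sub["score"], sub[pred],
                        country=country, lesion_level=lesion, predictor=pred,
                        age_scheme=age_scheme,
                    )
                    rows.append({
                        "country": country, "lesion_level": lesion, "predictor": pred,
                        "slope": tf.slope, "intercept": tf.intercept,
                        "p_value": tf.p_value, "n": tf.n, "note": tf.note,
                    })
    out = pd.DataFrame(rows)
    out.attrs["excluded_missing_lesion"] = excluded
    return out


def bin_summaries(
    scores_df: pd.DataFrame,
    data,
    age_scheme: Sequence[float] = DEFAULT_AGE_SCHEME,
) -> pd.DataFrame:
    """Tidy per-bin score means with 95% CIs for every country x lesion
    x predictor stratum (the numbers behind trend plots)."""
    df = data.df.merge(scores_df[["person_id", "score"]], on="person_id", how="inner")
    rows = []
    for country in data.countries:
        for lesion in ("paraplegia", "tetraplegia"):
            sub = df[(df["country_id"] == country) & (df["lesion_level"] == lesion)]
            for pred in PREDICTORS:
                ok = sub[[pred, "score"]].dropna()
                if ok.empty:
                    continue
                summ = _bin_summary(ok["score"].to_numpy(),
                                    ok[pred].to_numpy(), age_scheme)
                summ.insert(0, "predictor", pred)
                summ.insert(0, "lesion_level", lesion)
                summ.insert(0, "country", country)
                rows.append(summ)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
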