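"""Reading, validation and descriptive summaries of survey tables.

The interchange format is plain CSV: one row per person, ``item_XX``
columns for ordinal functioning responses (empty cell = missing),
``ef_XX`` columns for environmental factors, plus demographics.  Item
metadata (category counts, reverse-scoring flags, instrument tags)
travels in a separate small CSV.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import SchemaError, SurveyDataset, item_column

__all__ = ["read_survey_csv", "read_item_metadata", "write_item_metadata",
           "summarize_dataset", "default_item_metadata"]

log = logging.getLogger("scimetric")


def default_item_metadata(n_categories) -> pd.DataFrame:
    """Metadata frame for items already oriented with the latent trait."""
    n_categories = np.asarray(n_categories, int)
    return pd.DataFrame({
        "item_id": [item_column(j) for j in range(len(n_categories))],
        "n_categories": n_categories,
        "reverse_scored": False,
        "instrument": ["intensity"] * len(n_categories),
    })


def read_item_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"item_id", "n_categories"}
    if not required <= set(meta.columns):
        raise SchemaError(f"item metadata needs columns {sorted(required)}")
    if "reverse_scored" not in meta.columns:
        meta["reverse_scored"] = False
    if "instrument" not in meta.columns:
        meta["instrument"] = "intensity"
    meta["reverse_scored"] = meta["reverse_scored"].astype(bool)
    return meta


def write_item_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_survey_csv(
    path,
    item_metadata: Optional[pd.DataFrame] = None,
    skip_bad: bool = False,
) -> SurveyDataset:
    """Load and validate a survey CSV.

    Persons with no functioning-item answer are excluded (the survey
    inclusion rule) and logged on the returned dataset's
    ``exclusion_log``.  Reverse-scored items are flipped at ingestion
    so that a higher code always means better functioning.  Rows with
    out-of-range codes abort the run with a row/column diagnostic
    unless ``skip_bad`` drops them instead.
    """
    df = pd.read_csv(path)
    item_cols = sorted(c for c in df.columns if c.startswith("item_"))
    if not item_cols:
        raise SchemaError("no item_* columns found")
    if item_metadata is None:
        n_cat = [int(df[c].max()) + 1 if df[c].notna().any() else 2 for c in item_cols]
        meta = default_item_metadata(n_cat)
    else:
        meta = item_metadata.set_index("item_id")
        missing = [c for c in item_cols if c not in meta.index]
        if missing:
            raise SchemaError(f"items without metadata: {missing}")
        n_cat = [int(meta.loc[c, "n_categories"]) for c in item_cols]
        for c in item_cols:
            if meta.loc[c, "reverse_scored"]:
                k = int(meta.loc[c, "n_categories"])
                df[c] = (k - 1) - df[c]

    exclusions = []
    # out-of-range screen before constructing the dataset
    for j, c in enumerate(item_cols):
        vals = df[c]
        bad = vals.notna() & ((vals < 0) | (vals >= n_cat[j]))
        if bad.any():
            rows = df.index[bad].tolist()
            msg = (f"code out of range in column {c}, rows {rows[:10]} "
                   f"(K={n_cat[j]})")
            if not skip_bad:
                raise SchemaError(msg)
            log.warning("%s -- dropping rows", msg)
            exclusions += [{"person_id": df.loc[r, "person_id"],
                            "reason": f"bad code in {c}"} for r in rows]
            df = df[~bad]
    all_missing = df[item_cols].isna().all(axis=1)
    if all_missing.any():
        for r in df.index[all_missing]:
            exclusions.append({"person_id": df.loc[r, "person_id"],
                               "reason": "no functioning-item answer"})
        log.info("excluded %d person(s) with no functioning answer",
                 int(all_missing.sum()))
        df = df[~all_missing]
    ds = SurveyDataset(df.reset_index(drop=True), n_cat)
    ds.exclusion_log = pd.DataFrame(exclusions, columns=["person_id", "reason"])
    return ds


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

_MEDIAN_VARS = {
    "chronological_age": "age",
    "years_education": "education",
    "time_since_injury": "time_since_injury",
    "age_at_injury": "age_at_injury",
}
_BINARY_VARS = {
    "gender": ("female", "male"),
    "lesion_level": ("paraplegia", "tetraplegia"),
    "completeness": ("complete", "incomplete"),
    "etiology": ("traumatic", "non-traumatic"),
}


def _pct(num: float, den: float) -> float:
    return round(100.0 * num / den, 1) if den else np.nan


def _describe_group(sub: pd.DataFrame, total_n: int) -> dict:
    row: dict = {"n": len(sub), "pct_of_total": _pct(len(sub), total_n)}
    for var, (lvl_a, lvl_b) in _BINARY_VARS.items():
        if var not in sub.columns:
            continue
        obs = sub[var].dropna()
        # percentages among non-missing; missing tallied separately
        for lvl in (lvl_a, lvl_b):
            row[f"{lvl}_n"] = int((obs == lvl).sum())
            row[f"{lvl}_pct"] = _pct((obs == lvl).sum(), len(obs))
    for var, short in _MEDIAN_VARS.items():
        if var not in sub.columns:
            continue
        obs = sub[var].dropna()
        if len(obs):
            row[f"{short}_median"] = float(obs.median())
            row[f"{short}_q1"] = float(obs.quantile(0.25))
            row[f"{short}_q3"] = float(obs.quantile(0.75))
        else:
            row[f"{short}_median"] = row[f"{short}_q1"] = row[f"{short}_q3"] = np.nan
    return row


def summarize_dataset(data: SurveyDataset) -> pd.DataFrame:
    """Basic sociodemographic and lesion descriptives, per country and
    total.

    Percentages are computed among non-missing values; the ``Missing``
    row counts missing entries per variable (with their share of the
    total sample), following the usual survey-table convention — e.g.,
    a female share of 1812 among 6614 classified is reported as 27.4%
    even though the sample holds 6635 persons.
    """
    df = data.df
    total_n = len(df)
    if total_n == 0:
        return pd.DataFrame()
    rows = {}
    missing_row: dict = {"n": np.nan, "pct_of_total": np.nan}
    for var, (lvl_a, lvl_b) in _BINARY_VARS.items():
        if var in df.columns:
            n_miss = int(df[var].isna().sum())
            missing_row[f"{lvl_a}_n"] = n_miss
            missing_row[f"{lvl_a}_pct"] = _pct(n_miss, total_n)
            missing_row[f"{lvl_b}_n"] = n_miss
            missing_row[f"{lvl_b}_pct"] = _pct(n_miss, total_n)
    for var, short in _MEDIAN_VARS.items():
        if var in df.columns:
            missing_row[f"{short}_median"] = int(df[var].isna().sum())
    rows["Missing"] = missing_row
    rows["Total"] = _describe_group(df, total_n)
    for country in data.countries:
        rows[str(country)] = _describe_group(df[df["country_id"] == country], total_n)
    return pd.DataFrame(rows).T
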