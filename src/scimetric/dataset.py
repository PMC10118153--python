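"""Person-level survey container used by every stage of the pipeline.

A :class:`SurveyDataset` wraps a pandas DataFrame with one row per
respondent: country membership, demographics, ordinal functioning-item
responses (heterogeneous category counts, missing allowed) and the 14
environmental-factor (EF) items.  Functioning items are coded
``0 .. K_j - 1``; EF items use the four-option coding below.  Missing
entries are NaN in the frame and ``-1`` in the integer matrices the
model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: EF response coding (column values in ``ef_*`` columns).
EF_NOT_APPLICABLE = 0
EF_NO_INFLUENCE = 1
EF_LITTLE_HARDER = 2
EF_LOT_HARDER = 3

N_EF_ITEMS = 14

DEMOGRAPHIC_COLUMNS = [
    "person_id",
    "country_id",
    "gender",
    "chronological_age",
    "age_at_injury",
    "time_since_injury",
    "lesion_level",
    "completeness",
    "etiology",
    "years_education",
]


def item_column(j: int) -> str:
    return f"item_{j + 1:02d}"


def ef_column(k: int) -> str:
    return f"ef_{k + 1:02d}"


class SchemaError(ValueError):
    """Raised when a survey table violates the declared schema."""


@dataclass
class SurveyDataset:
    """Typed view over a respondent-level survey table.

    Parameters
    ----------
    df:
        One row per person.  Must contain ``person_id``, ``country_id``
        and the ``item_XX`` columns; demographics and ``ef_XX`` columns
        are optional but expected by the trend / EF stages.
    n_categories:
        Number of response categories K_j of each functioning item
        (all >= 2).
    countries:
        Ordered country labels.  Defaults to the sorted unique
        ``country_id`` values; passing it explicitly allows empty
        datasets (prior-only fits) and stable ordering.
    validate:
        Check codes are within range and that every person answered at
        least one functioning item (the survey inclusion rule).
    """

    df: pd.DataFrame
    n_categories: np.ndarray
    countries: Sequence = None
    validate: bool = True
    truth: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if (self.n_categories < 2).any():
            raise SchemaError("every functioning item needs >= 2 categories")
        if self.countries is None:
            self.countries = list(pd.unique(self.df["country_id"].dropna().sort_values()))
        else:
            self.countries = list(self.countries)
        missing_cols = [item_column(j) for j in range(self.n_items)
                        if item_column(j) not in self.df.columns]
        if missing_cols:
            raise SchemaError(f"missing item columns: {missing_cols}")
        if self.validate:
            self._validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.n_categories)

    @property
    def n_persons(self) -> int:
        return len(self.df)

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def item_columns(self) -> list:
        return [item_column(j) for j in range(self.n_items)]

    @property
    def ef_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("ef_")]

    # -- matrices consumed by the model ---------------------------------
    def responses(self) -> np.ndarray:
        """(N, J) int matrix of item codes, -1 for missing."""
        arr = self.df[self.item_columns].to_numpy(dtype=float)
        out = np.where(np.isnan(arr), -1, arr).astype(int)
        return out

    def ef_codes(self) -> np.ndarray:
        """(N, 14) int matrix of EF codes, -1 for missing."""
        arr = self.df[self.ef_columns].to_numpy(dtype=float)
        return np.where(np.isnan(arr), -1, arr).astype(int)

    def country_index(self) -> np.ndarray:
        """(N,) int index into :attr:`countries`."""
        lookup = {c: i for i, c in enumerate(self.countries)}
        try:
            return self.df["country_id"].map(lookup).to_numpy(dtype=int)
        except (TypeError, ValueError) as exc:
            raise SchemaError("country_id outside declared country list") from exc

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        resp = self.responses()
        over = resp >= self.n_categories[None, :]
        if over.any():
            i, j = np.argwhere(over)[0]
            raise SchemaError(
                f"response code {resp[i, j]} >= K={self.n_categories[j]} "
                f"at row {i}, column {item_column(j)}"
            )
        if (resp < -1).any():
            raise SchemaError("negative response codes")
        if self.n_persons and not (resp >= 0).any(axis=1).all():
            bad = np.flatnonzero(~(resp >= 0).any(axis=1))
            raise SchemaError(
                f"{bad.size} person(s) with no functioning-item answer "
                f"(first row {bad[0]}); the inclusion rule requires >= 1"
            )
        self.country_index()

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def subset(self, mask: np.ndarray) -> "SurveyDataset":
        return SurveyDataset(
            self.df.loc[np.asarray(mask)].reset_index(drop=True),
            self.n_categories,
            countries=self.countries,
            validate=False,
        )
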