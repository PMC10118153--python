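"""Synthetic multi-country SCI survey generator with known ground truth.

Emulates the structure of a cross-national spinal-cord-injury community
survey: a handful of country samples of very unequal size, ordinal
functioning items following a hierarchical GPCM with country-deviated
thresholds (differential item functioning), age-related latent
gradients that differ by lesion level, and 14 environmental-factor
items whose "made my life harder" responses associate with lower
functioning.  Every dataset carries its generating parameters so each
downstream stage has a recoverable target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    EF_LITTLE_HARDER,
    EF_LOT_HARDER,
    EF_NO_INFLUENCE,
    EF_NOT_APPLICABLE,
    N_EF_ITEMS,
    SurveyDataset,
    ef_column,
    item_column,
)
from .gpcm import GPCMParameters, category_probabilities

__all__ = ["SyntheticConfig", "generate_item_bank", "generate_dataset", "simulate"]

# Table-1-like default country sample sizes (11 countries, n 199..1617).
_DEFAULT_COUNTRY_SIZES = [606, 217, 967, 1617, 256, 410, 1527, 203, 417, 199, 216]

# Default item categories: dichotomized ADL / secondary-condition items
# plus 4- and 5-level problem-intensity items.
_DEFAULT_CATEGORIES = [2] * 7 + [4] * 4 + [5] * 4

# Default EF effect sizes: a few strong accessibility/transport barriers,
# a mid tail, two null items.
_DEFAULT_EF_COEFS = [0.8, 0.7, 0.6, 0.5, 0.4, 0.35, 0.3, 0.25,
                     0.2, 0.15, 0.1, 0.05, 0.0, 0.0]

# Small demographic missingness, of the order seen in community surveys.
_DEMOG_MISSING = {
    "gender": 0.003,
    "lesion_level": 0.027,
    "completeness": 0.042,
    "etiology": 0.014,
    "years_education": 0.066,
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the survey's study conditions."""

    n_countries: int = 11
    n_per_country: Sequence[int] = field(default_factory=lambda: list(_DEFAULT_COUNTRY_SIZES))
    n_items: int = 15
    categories_per_item: Sequence[int] = field(default_factory=lambda: list(_DEFAULT_CATEGORIES))
    discrimination_range: tuple = (0.8, 2.0)
    threshold_spread: float = 1.0
    dif_sd: float = 0.3
    country_mean_sd: float = 0.5
    country_ability_sd_range: tuple = (0.8, 1.2)
    age_effect_paraplegia: float = -0.012   # latent units per year
    age_effect_tetraplegia: float = -0.006
    ef_coefficients: Sequence[float] = field(default_factory=lambda: list(_DEFAULT_EF_COEFS))
    ef_na_rate: float = 0.05
    missing_rate_items: float = 0.03
    missing_rate_ef: float = 0.10
    missingness: str = "mcar"               # "mcar" | "mar_age"
    seed: int = 0

    def __post_init__(self):
        self.n_per_country = list(self.n_per_country)
        self.categories_per_item = list(self.categories_per_item)
        self.ef_coefficients = list(self.ef_coefficients)
        if len(self.n_per_country) != self.n_countries:
            raise InvalidConfigError("n_per_country length != n_countries")
        if len(self.categories_per_item) != self.n_items:
            raise InvalidConfigError("categories_per_item length != n_items")
        if any(k < 2 for k in self.categories_per_item):
            raise InvalidConfigError("all category counts must be >= 2")
        if len(self.ef_coefficients) != N_EF_ITEMS:
            raise InvalidConfigError(f"ef_coefficients must have {N_EF_ITEMS} entries")
        for name in ("missing_rate_items", "missing_rate_ef", "ef_na_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1)")
        if self.dif_sd < 0 or self.country_mean_sd < 0:
            raise InvalidConfigError("SDs must be nonnegative")
        lo, hi = self.discrimination_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("discrimination_range must be a positive interval")
        lo, hi = self.country_ability_sd_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("country_ability_sd_range must be a positive interval")
        if self.missingness not in ("mcar", "mar_age"):
            raise InvalidConfigError("missingness must be 'mcar' or 'mar_age'")

    @classmethod
    def recovery_demo(cls, seed: int = 1) -> "SyntheticConfig":
        """Small balanced design used for parameter-recovery checks:
        5 countries x 300 persons, 15 four-category items."""
        return cls(
            n_countries=5,
            n_per_country=[300] * 5,
            n_items=15,
            categories_per_item=[4] * 15,
            seed=seed,
        )


def generate_item_bank(cfg: SyntheticConfig) -> GPCMParameters:
    """Draw the ground-truth item bank and country parameters.

    Discriminations are uniform on ``discrimination_range``; overall
    thresholds are sorted Normal(0, threshold_spread^2) draws; country
    deviations are Normal(0, dif_sd^2), centered so that for every
    (item, level) the country-specific thresholds average to the
    overall threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    J, C = cfg.n_items, cfg.n_countries
    K = np.asarray(cfg.categories_per_item)
    vmax = int(K.max()) - 1

    a = rng.uniform(*cfg.discrimination_range, size=J)
    b = np.full((J, vmax), np.nan)
    delta = np.full((C, J, vmax), np.nan)
    for j in range(J):
        v = K[j] - 1
        b[j, :v] = np.sort(rng.normal(0.0, cfg.threshold_spread, size=v))
        d = rng.normal(0.0, cfg.dif_sd, size=(C, v))
        d -= d.mean(axis=0, keepdims=True)   # centering identity across countries
        delta[:, j, :v] = d

    mu = rng.normal(0.0, cfg.country_mean_sd, size=C)
    sigma = rng.uniform(*cfg.country_ability_sd_range, size=C)
    return GPCMParameters(
        a=a, b=b, delta=delta, mu=mu, sigma=sigma,
        tau=max(cfg.dif_sd, 1e-12), n_categories=K,
    )


def sample_item_responses(theta: np.ndarray, a: float, thresholds: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample one item's responses for each ability in ``theta``."""
    p = category_probabilities(theta, a, thresholds)
    p = np.atleast_2d(p)
    u = rng.random(p.shape[0])
    return (u[:, None] >= np.cumsum(p, axis=1)).sum(axis=1)


def _sample_demographics(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = int(np.sum(cfg.n_per_country))
    country = np.repeat(np.arange(cfg.n_countries), cfg.n_per_country)
    age = np.clip(rng.normal(53.0, 15.0, size=n), 18.0, 90.0)
    tsi = np.clip(rng.lognormal(np.log(11.0), 0.95, size=n), 0.5, None)
    tsi = np.minimum(tsi, age - 16.0)
    aai = age - tsi
    female = rng.random(n) < 0.274
    lesion = np.where(rng.random(n) < 0.609, "paraplegia", "tetraplegia")
    complete = np.where(rng.random(n) < 0.373, "complete", "incomplete")
    etiology = np.where(rng.random(n) < 0.797, "traumatic", "non-traumatic")
    edu = np.clip(np.round(rng.normal(13.0, 3.0, size=n)), 5, 22)
    return pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "country_id": [f"C{c + 1:02d}" for c in country],
        "_country_idx": country,
        "gender": np.where(female, "female", "male"),
        "chronological_age": np.round(age, 1),
        "age_at_injury": np.round(aai, 1),
        "time_since_injury": np.round(tsi, 1),
        "lesion_level": lesion,
        "completeness": complete,
        "etiology": etiology,
        "years_education": edu,
    })


def generate_dataset(cfg: SyntheticConfig, truth: Optional[GPCMParameters] = None) -> SurveyDataset:
    """Simulate a full survey table under the hierarchical GPCM truth.

    Abilities follow theta_i ~ N(mu_c + slope_lesion * (age_i - 40),
    sigma_c^2); responses follow the GPCM at the person's country
    thresholds; EF responses follow an ordinal-logistic law on -theta
    scaled by ``ef_coefficients``; missingness is injected at the
    configured rates (MCAR by default, optionally MAR on age) while
    honoring the inclusion rule that every person keeps at least one
    functioning answer.  The returned dataset carries ``truth`` with
    the generating parameters including the simulated theta.
    """
    if truth is None:
        truth = generate_item_bank(cfg)
    if truth.n_items != cfg.n_items or truth.n_countries != cfg.n_countries:
        raise InvalidConfigError("truth dimensions inconsistent with config")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1001]))

    demog = _sample_demographics(cfg, rng)
    cidx = demog.pop("_country_idx").to_numpy()
    n = len(demog)

    slope = np.where(
        demog["lesion_level"].to_numpy() == "paraplegia",
        cfg.age_effect_paraplegia, cfg.age_effect_tetraplegia,
    )
    age = demog["chronological_age"].to_numpy()
    theta = truth.mu[cidx] + slope * (age - 40.0) + rng.normal(0.0, truth.sigma[cidx], size=n)

    # --- functioning items ------------------------------------------------
    bstar = truth.country_thresholds()
    resp = np.empty((n, cfg.n_items), dtype=float)
    for j in range(cfg.n_items):
        v = cfg.categories_per_item[j] - 1
        for c in range(cfg.n_countries):
            rows = cidx == c
            if rows.any():
                resp[rows, j] = sample_item_responses(
                    theta[rows], truth.a[j], bstar[c, j, :v], rng
                )
    if cfg.missing_rate_items > 0:
        if cfg.missingness == "mar_age":
            # older respondents skip more items (logistic in age)
            p = cfg.missing_rate_items * np.exp((age - 53.0) / 30.0)
            p = np.clip(p, 0.0, 0.95)[:, None]
        else:
            p = cfg.missing_rate_items
        miss = rng.random(resp.shape) < p
        # inclusion rule: keep >= 1 answer per person
        all_gone = miss.all(axis=1)
        if all_gone.any():
            keep = rng.integers(0, cfg.n_items, size=int(all_gone.sum()))
            miss[np.flatnonzero(all_gone), keep] = False
        resp[miss] = np.nan

    # --- environmental factors -------------------------------------------
    gamma = np.asarray(cfg.ef_coefficients)
    ef = np.empty((n, N_EF_ITEMS), dtype=float)
    cuts = (0.0, 1.5)  # ordinal-logistic cuts -> roughly 50/30/20 splits at gamma=0
    for k in range(N_EF_ITEMS):
        u = gamma[k] * (-theta) + rng.logistic(0.0, 1.0, size=n)
        codes = np.full(n, EF_NO_INFLUENCE)
        codes[u > cuts[0]] = EF_LITTLE_HARDER
        codes[u > cuts[1]] = EF_LOT_HARDER
        codes[rng.random(n) < cfg.ef_na_rate] = EF_NOT_APPLICABLE
        ef[:, k] = codes
    if cfg.missing_rate_ef > 0:
        ef[rng.random(ef.shape) < cfg.missing_rate_ef] = np.nan

    # --- demographic missingness -----------------------------------------
    for col, rate in _DEMOG_MISSING.items():
        mask = rng.random(n) < rate
        if mask.any():
            demog.loc[mask, col] = np.nan

    df = demog.copy()
    for j in range(cfg.n_items):
        df[item_column(j)] = resp[:, j]
    for k in range(N_EF_ITEMS):
        df[ef_column(k)] = ef[:, k]

    truth_with_theta = truth.copy()
    truth_with_theta.theta = theta
    truth_with_theta.person_country = cidx
    countries = [f"C{c + 1:02d}" for c in range(cfg.n_countries)]
    return SurveyDataset(df, cfg.categories_per_item, countries=countries,
                         truth=truth_with_theta)


def simulate(cfg: SyntheticConfig) -> tuple[SurveyDataset, GPCMParameters]:
    """Convenience wrapper: item bank + dataset in one call."""
    truth = generate_item_bank(cfg)
    data = generate_dataset(cfg, truth)
    return data, data.truth


def dataset_from_marginals(n_total: int, **marginals) -> SurveyDataset:
    """Build a survey table honoring exact per-variable marginal counts.

    Each keyword maps a demographic column to ``{value: count, ...,
    None: missing_count}``; counts must sum to ``n_total``.  Variables
    are filled independently (no joint structure), which is all a
    marginal descriptive table needs.  A single always-answered binary
    functioning item keeps the inclusion rule satisfied.
    """
    df = pd.DataFrame({
        "person_id": np.arange(1, n_total + 1),
        "country_id": "ALL",
        "item_01": 0.0,
    })
    for col, counts in marginals.items():
        if sum(counts.values()) != n_total:
            raise InvalidConfigError(f"{col} counts sum to {sum(counts.values())}, "
                                     f"expected {n_total}")
        values: list = []
        for val, k in counts.items():
            values += [np.nan if val is None else val] * k
        df[col] = values
    return SurveyDataset(df, [2], countries=["ALL"])


def write_truth_json(truth: GPCMParameters, path) -> None:
    """Persist the ground-truth parameter record as a JSON sidecar."""
    payload = {
        "a": truth.a.tolist(),
        "b": truth.b.tolist(),
        "delta": truth.delta.tolist(),
        "mu": truth.mu.tolist(),
        "sigma": truth.sigma.tolist(),
        "tau": truth.tau,
        "n_categories": truth.n_categories.tolist(),
        "theta": None if truth.theta is None else truth.theta.tolist(),
        "person_country": (None if truth.person_country is None
                           else truth.person_country.tolist()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
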