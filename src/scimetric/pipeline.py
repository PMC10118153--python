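"""End-to-end pipeline: recode -> assumption checks -> fit -> diagnose
-> score -> trends -> EF importance, with per-stage artifacts, config
and seed stamped into every output, and cached MCMC draws for resuming.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assumptions import apply_collapse_map, run_assumptions
from .dataset import SurveyDataset
from .gpcm import PriorSpec
from .importance import pmvd_for_country, rank_barriers
from .inference import (MCMCConfig, PosteriorChains, fit, functioning_scores,
                        posterior_predictive_pvalues)
from .io import read_survey_csv, read_item_metadata, summarize_dataset
from .synthetic import SyntheticConfig, generate_dataset, write_truth_json
from .trends import DEFAULT_AGE_SCHEME, bin_summaries, fit_all_trends

log = logging.getLogger("scimetric")

STAGES = ("data", "describe", "assumptions", "fit", "diagnose", "score",
          "trends", "importance")


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serializable."""

    out_dir: str = "run"
    data_path: Optional[str] = None            # None -> simulate
    items_path: Optional[str] = None
    seed: int = 0
    synthetic: dict = field(default_factory=dict)     # SyntheticConfig overrides
    priors: dict = field(default_factory=dict)        # PriorSpec overrides
    mcmc: dict = field(default_factory=dict)          # MCMCConfig overrides
    score_scale: float = 1.0
    assumption_n_perm: int = 100
    general_cutoff: float = 0.4
    li_threshold: float = 0.25
    age_scheme: Sequence[float] = DEFAULT_AGE_SCHEME
    pmvd_forced: Sequence[str] = ("chronological_age", "lesion_level",
                                  "time_since_injury")
    pmvd_complete_cases: bool = False
    stages: Sequence[str] = STAGES
    apply_collapse: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def fit_hash(self) -> str:
        """Hash of everything the MCMC draws depend on."""
        key = json.dumps({
            "data": self.data_path, "items": self.items_path, "seed": self.seed,
            "synthetic": self.synthetic, "priors": self.priors, "mcmc": self.mcmc,
            "apply_collapse": self.apply_collapse,
            "version": __version__,
        }, sort_keys=True, default=str)
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def _save_chains(chains: PosteriorChains, path: Path) -> None:
    """Columnar CSV: one column per scalar parameter plus chain/iter."""
    cols = {"chain": np.repeat(np.arange(chains.n_chains), chains.n_kept),
            "iter": np.tile(np.arange(chains.n_kept), chains.n_chains)}
    frames = [pd.DataFrame(cols)]
    for name, arr in chains.draws.items():
        flat = arr.reshape(chains.n_chains * chains.n_kept, -1)
        if flat.shape[1] == 1:
            frames.append(pd.DataFrame({name: flat[:, 0]}))
        else:
            frames.append(pd.DataFrame(
                flat, columns=[f"{name}[{i}]" for i in range(flat.shape[1])]))
    pd.concat(frames, axis=1).to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, data: Optional[SurveyDataset] = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Each artifact directory carries ``meta.json`` with the config, the
    seed, the package version and per-stage wall times.  If cached
    draws matching the current fit hash exist in the run directory the
    fit stage reuses them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed,
            "config": asdict(config), "stages": {}}
    stages = list(config.stages)

    def stamp(stage, t0):
        meta["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    try:
        # ---- data --------------------------------------------------------
        t0 = time.time()
        if data is None:
            if config.data_path:
                meta_items = (read_item_metadata(config.items_path)
                              if config.items_path else None)
                data = read_survey_csv(config.data_path, meta_items)
            else:
                scfg = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
                data = generate_dataset(scfg)
                data.to_csv(out / "data.csv")
                write_truth_json(data.truth, out / "truth.json")
        stamp("data", t0)

        if "describe" in stages:
            t0 = time.time()
            summarize_dataset(data).to_csv(out / "summary.csv")
            stamp("describe", t0)

        if "assumptions" in stages:
            t0 = time.time()
            report = run_assumptions(
                data, n_perm=config.assumption_n_perm, seed=config.seed,
                general_cutoff=config.general_cutoff,
                li_threshold=config.li_threshold,
            )
            report.to_json(out / "assumptions.json")
            cm_rows = [(col, old, new)
                       for col, m in report.collapse_map.items()
                       for old, new in m.items()]
            pd.DataFrame(cm_rows, columns=["item_id", "old_code", "new_code"]) \
                .to_csv(out / "collapse_map.csv", index=False)
            if config.apply_collapse:
                data = apply_collapse_map(data, report.collapse_map)
            stamp("assumptions", t0)

        chains = None
        if "fit" in stages:
            t0 = time.time()
            fhash = config.fit_hash()
            cache = out / "draws.npz"
            if cache.exists():
                cached = np.load(cache, allow_pickle=True)
                if str(cached["fit_hash"]) == fhash:
                    log.info("reusing cached draws (%s)", fhash)
                    chains = PosteriorChains(
                        draws={k[6:]: cached[k] for k in cached.files
                               if k.startswith("draws_")},
                        n_categories=cached["n_categories"],
                        countries=list(cached["countries"]),
                        person_id=cached["person_id"],
                        person_country=cached["person_country"],
                        config=MCMCConfig(**{"seed": config.seed, **config.mcmc}),
                    )
            if chains is None:
                priors = PriorSpec(**config.priors)
                mcfg = MCMCConfig(**{"seed": config.seed, **config.mcmc})
                chains = fit(data, priors, mcfg)
                np.savez_compressed(
                    cache, fit_hash=fhash,
                    n_categories=chains.n_categories,
                    countries=np.asarray(chains.countries),
                    person_id=chains.person_id,
                    person_country=chains.person_country,
                    **{f"draws_{k}": v for k, v in chains.draws.items()},
                )
                _save_chains(chains, out / "draws.csv")
            stamp("fit", t0)

        if "diagnose" in stages and chains is not None:
            t0 = time.time()
            diag = posterior_predictive_pvalues(chains, data)
            psrf = diag.psrf_flat()
            payload = {
                "psrf_max": float(np.nanmax(psrf.to_numpy())),
                "psrf_frac_below_1.05": float((psrf.dropna() <= 1.05).mean()),
                "ppp_items": [round(float(v), 4) for v in diag.ppp_items],
                "ppp_options": [[None if np.isnan(v) else round(float(v), 4)
                                 for v in row] for row in diag.ppp_options],
                "acceptance": chains.acceptance,
            }
            with open(out / "diagnostics.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            psrf.to_csv(out / "psrf.csv", header=["psrf"])
            stamp("diagnose", t0)

        scores = None
        if "score" in stages and chains is not None:
            t0 = time.time()
            scores = functioning_scores(chains, scale=config.score_scale)
            scores.to_csv(out / "scores.csv", index=False)
            stamp("score", t0)

        if "trends" in stages and scores is not None:
            t0 = time.time()
            tr = fit_all_trends(scores, data, age_scheme=tuple(config.age_scheme))
            tr.to_csv(out / "trends.csv", index=False)
            bin_summaries(scores, data, age_scheme=tuple(config.age_scheme)) \
                .to_csv(out / "trend_bins.csv", index=False)
            stamp("trends", t0)

        if "importance" in stages and scores is not None:
            t0 = time.time()
            for country in [None, *data.countries]:
                label = "all" if country is None else str(country)
                try:
                    res = pmvd_for_country(
                        data, scores, country=country,
                        forced=tuple(config.pmvd_forced), seed=config.seed,
                        complete_cases=config.pmvd_complete_cases,
                    )
                except ValueError as exc:
                    log.warning("importance skipped for %s: %s", label, exc)
                    continue
                rank_barriers(res).to_csv(out / f"barriers_{label}.csv", index=False)
                with open(out / f"importance_{label}.json", "w") as fh:
                    json.dump({
                        "shares": {k: float(v) for k, v in res.shares.items()},
                        "block_r2": res.block_r2, "full_r2": res.full_r2,
                        "forced_r2": res.forced_r2, "n": res.n,
                        "imputed": res.imputed, "method": res.method,
                    }, fh, indent=2)
            stamp("importance", t0)
    except Exception as exc:
        meta["failed_stage"] = str(exc)
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        raise
    return out
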