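# scimetric

A cross-national **functioning metric** for spinal-cord-injury (SCI)
community surveys, for epidemiologists and rehabilitation researchers
who need country-comparable scores from heterogeneous ordinal
questionnaire items.

The package builds a 0–100 functioning score with a Bayesian
**hierarchical Generalized Partial Credit Model** (GPCM).  Person *i*
in country *c* answers item *j* (K_j ordered categories) with

```
P(X_ij = k | θ_i) ∝ exp( Σ_{v≤k} a_j (θ_i − b_jv − δ_cjv) )
```

where a_j is the item discrimination, b_jv the overall threshold and
δ_cjv ~ N(0, τ²) a country deviation that absorbs differential item
functioning (DIF); abilities are hierarchical, θ_i ~ N(μ_c, σ_c²),
and the scale is identified by setting each country's threshold sum to
zero.  Posterior-mean abilities are mapped to scores by
`100 · Φ(θ̄)`, so scores live in (0, 100) and average 50 under the
centered population prior.

Around the metric, the package provides the full analysis pipeline:

* **IRT assumption battery** — polychoric correlations,
  permuted parallel analysis, a Schmid–Leiman bifactor screen of
  unidimensionality, a 0.25 residual-correlation screen of local
  independence, and monotonicity checking with automatic collapsing of
  disordered response options;
* **MCMC inference** — an adaptive Metropolis-within-Gibbs sampler
  with split-chain Gelman–Rubin diagnostics and posterior-predictive
  p-values of item response-option totals;
* **ageing trends** — per-country, per-lesion-level OLS of the score
  on chronological age, age at injury and time since injury, with
  15-year age-bin summaries;
* **environmental barriers** — PMVD (proportional marginal variance
  decomposition) shares of the 14 environmental-factor items in the
  score's variance, after random-forest imputation of missing EF
  responses, controlling for age and injury covariates;
* **a synthetic survey generator** with full ground truth, emulating
  the multi-country structure (5–11 countries of very unequal size,
  country DIF, age gradients by lesion level, EF effects), so every
  stage has a recoverable target.

See `docs/methods.md` for the model, priors, numerical choices and
limitations.

## Worked example

```python
from scimetric import SyntheticConfig, MCMCConfig, fit, functioning_scores
from scimetric.synthetic import simulate
from scimetric.trends import fit_all_trends
from scimetric.importance import pmvd_for_country, rank_barriers

cfg = SyntheticConfig(n_countries=3, n_per_country=[400, 250, 150],
                      n_items=10, categories_per_item=[2]*4 + [4]*3 + [5]*3,
                      seed=7)
data, truth = simulate(cfg)
chains = fit(data, cfg=MCMCConfig(n_warmup=800, n_iterations=1000, seed=7))
scores = functioning_scores(chains)
print(scores.groupby("country_id")["score"].agg(["mean", "std"]).round(1))
```

```
            mean   std
country_id
C01         73.5  30.6
C02         66.3  33.1
C03         38.5  37.4
```

Countries differ in mean functioning because the generator drew
different country ability means; the scores are on the common 0–100
scale, so the gaps are directly comparable.  Ageing trends:

```python
trends = fit_all_trends(scores, data)
print(trends[trends.predictor == "chronological_age"]
      [["country", "lesion_level", "slope", "p_value", "n"]].round(3))
```

```
country lesion_level  slope  p_value   n
    C01   paraplegia -0.437    0.002 226
    C01  tetraplegia -0.224    0.157 158
    C02   paraplegia -0.148    0.413 137
    C02  tetraplegia -0.016    0.937 105
    C03   paraplegia  0.013    0.965  76
    C03  tetraplegia -0.359    0.205  70
```

Slopes are score points per year: the largest stratum shows the
generator's planted decline clearly (−0.44 points per year of age,
p ≈ 0.002), while the smaller strata are noisier — exactly the
sample-size behaviour such stratified trend plots show in practice.
Barrier ranking:

```python
res = pmvd_for_country(data, scores, seed=7)
print(rank_barriers(res).head(5).round(4))
print("block R2:", round(res.block_r2, 3))
```

```
                         ef  share  share_of_block  rank
                    climate 0.0725          0.2579     1
accessibility_friends_homes 0.0609          0.2165     2
         accessibility_home 0.0533          0.1895     3
   short_distance_transport 0.0462          0.1643     4
       access_public_places 0.0140          0.0499     5
block R2: 0.281
```

The EF block explains 28.1% of score variance beyond the forced
covariates, and PMVD concentrates that on the items the generator gave
the largest coefficients — the shares sum to the block R² and a
zero-coefficient EF receives a vanishing share even when correlated
with a real barrier.

A command-line interface mirrors the library
(`scimetric simulate | describe | check-assumptions | fit | diagnose |
score | trends | importance | run`), e.g.

```bash
scimetric run --seed 3 --out demo_run
```

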