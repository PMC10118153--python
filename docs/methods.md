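# Methods

## The problem

Cross-national community surveys of people living with spinal cord
injury (SCI) ask heterogeneous ordinal questions about everyday
functioning — dichotomized activities-of-daily-living items, secondary
health-condition frequencies, problem-intensity ratings.  To compare
countries, track ageing and rank environmental barriers, these need to
be condensed into one interval-scaled score that means the same thing
in every country even when respondents in different countries use the
response options differently.  `scimetric` implements that pipeline:
an item-response-theory (IRT) metric with country-level differential
item functioning (DIF), the assumption checks that justify it, the
trend regressions run on its output, and a variance-decomposition
ranking of environmental barriers.

## Measurement model

Person *i* in country *c* answers item *j* with one of
K_j ≥ 2 ordered categories.  The generalized partial credit model
(GPCM) gives

P(X_ij = k | θ_i) = exp( Σ_{v≤k} a_j (θ_i − b*_{c,j,v}) ) / Σ_m exp( Σ_{v≤m} a_j (θ_i − b*_{c,j,v}) ),

with the empty (k = 0) sum defined as 0.  a_j > 0 is the item's
discrimination; b*_{c,j,v} is the threshold at which category v+1
overtakes category v.  The hierarchy enters twice:

* **thresholds** — b*_{c,j,v} = b_{j,v} + δ_{c,j,v} with
  δ_{c,j,v} ~ N(0, τ²): each country may use the response scale
  differently (DIF), but deviations are shrunk toward a common
  threshold.  τ is shared across items and levels, which keeps the
  parameter count manageable at survey scale;
* **abilities** — θ_i ~ N(μ_c, σ_c²): a person's functioning is the
  country mean plus an individual deviation.

Missing responses contribute nothing to the likelihood (valid under
MCAR and MAR; the generator can produce both).

### Identification

Latent location is a gauge freedom: adding a constant to every
threshold and ability of a country changes nothing observable.  We fix
it by re-centering every posterior draw so that each country's
thresholds sum to zero; the removed constant is subtracted from the
country's μ_c and abilities as well, so θ − b* (and hence the
likelihood) is untouched.  The centering is applied per country across
items.  An alternative reading — centering deviations across countries
within each item-level — is available via
`apply_identification(..., mode="per_item")`; the per-country form is
the default because it pins every country's scale, which is what makes
country means comparable.

### Priors

Hyperparameters are weakly informative and overridable:
log a_j ~ N(0, 0.5²), b_{j,v} ~ N(0, 2²), δ ~ N(0, τ²) with
τ ~ Half-Normal(1), μ_c ~ N(0, 1), σ_c ~ Half-Normal(1).  The N(0,1)
prior on μ_c centers the population so the 0–100 transform (below)
averages 50 by construction.

### Sampler

`inference.fit` is an adaptive Metropolis-within-Gibbs sampler.
Blocks: all abilities at once (independent per-person random-walk
proposals), all discriminations at once (log scale), overall
thresholds one level at a time across items, country deviations one
level at a time across (country, item) cells, exact conjugate Gibbs
draws for μ_c, and log-scale random walks for σ_c and τ.  Two
likelihood-invariant "gauge" moves handle the softly identified
directions that plain coordinate updates mix poorly: a *scale* move
proposing (θ, μ, σ, b, δ, τ) → k·(…) with a → a/k (the common-scale
trade-off between discriminations and ability spread, pinned only by
the priors), and a *threshold* move shifting each b_{j,v} against its
country deviations (their split is likewise prior-determined).  Both
are Metropolis steps on the prior alone and cost no likelihood
evaluations.  Each sweep costs nine vectorized (N × J × K) likelihood
evaluations.  Step sizes
adapt by Robbins-Monro toward 0.44 acceptance during warmup and are
frozen afterwards, so kept draws form a genuine Markov chain.  The
default is a single chain with split-half convergence checks; with no
gradient information the sampler asks nothing of the model beyond the
log-density, which is also what makes the prior-only limit (an empty
dataset) exactly samplable for validation.

Starting values matter for wall time, not correctness: abilities start
at rank-based inverse-normal scores of the person's mean response
fraction, thresholds at adjacent-category log-odds of the pooled
margins.

### Diagnostics

* **Split PSRF** — the classical Gelman-Rubin potential scale
  reduction factor on half-chains (or on halves of each chain when
  several are run).  Constant traces yield NaN with a warning rather
  than an error.  Cross-checked against `arviz.rhat(method="identity")`
  in the test suite.
* **Posterior predictive p-values** — at every kept draw a replicate
  dataset is simulated under that draw's parameters with the observed
  missingness pattern; replicated per-item response-option counts (and
  per-item response totals) are compared with the observed ones,
  p = P(T_rep > T_obs) + ½ P(T_rep = T_obs).  The half-tie convention
  makes p exactly 0.5 when replicates always equal the observation,
  which is the right degenerate answer for discrete totals.  Values
  near 0.5 mean the totals are neither under- nor over-predicted.

### The 0–100 score

score_i = 100 · Φ(θ̄_i / s), with θ̄_i the posterior-mean ability, Φ
the standard normal CDF and s = 1 by default.  The probit map is used
rather than min-max scaling because it delivers both published
properties of the metric without data-dependent anchors: scores are
strictly increasing in ability, confined to (0, 100), and average 50
when abilities follow the centered population prior
(E[Φ(Z)] = ½ for Z ~ N(0,1)).

## Assumption battery

Run before fitting, on the polychoric correlation matrix of the items.

* **Polychoric correlations** — two-step estimator: cutpoints from
  marginal frequencies via normal quantiles, then univariate ML of the
  latent correlation.  The bivariate normal CDF is evaluated by
  Plackett's identity (Φ(h)Φ(k) plus a 32-point Gauss-Legendre
  integral of the bivariate density over the correlation), which is
  vectorized, smooth in ρ and accurate to ~1e-6 — enough for a
  screening statistic.  Non-positive-definite matrices are repaired by
  eigenvalue clipping and flagged.  Items with a single observed
  category are excluded with a warning; pairs with fewer than 30
  pairwise-complete observations (configurable) are flagged.
* **Unidimensionality** — a Schmid-Leiman bifactor solution built
  from least-squares (principal-axis) factoring: `n_group` first-order
  factors, promax-rotated, a single second-order factor of their
  correlations, then the usual orthogonalization into one general and
  `n_group` group factors.  `n_group` defaults to the permuted
  parallel-analysis retention count.  An item passes when its general
  loading is ≥ 0.4 (configurable; "loads high" is not a standardized
  number) *and* at least its largest group loading.  Violators are
  flagged and kept — dropping items is an analyst's decision, not the
  screen's.
* **Permuted parallel analysis** — observed polychoric eigenvalues
  against the 95th percentile (configurable) of eigenvalues from
  column-wise independently permuted data; retention stops at the
  first eigenvalue that fails to exceed its benchmark.
* **Local independence** — residual correlations R − λλᵀ after a
  single least-squares factor; the screen reports the fraction of
  off-diagonal entries above 0.25 and the offending pairs.
* **Monotonicity** — thresholds of a quick single-group GPCM (EM over
  31 Gauss-Hermite nodes, thresholds unconstrained so disorder can
  surface) must be ordered.  Disordered items have adjacent response
  options collapsed — at the first descent, the adjacent category pair
  with the smaller combined count is merged, preserving information in
  well-populated categories — then the model is re-fit until every
  item is ordered or binary.  The old→new code map is emitted and can
  be applied to the data before the hierarchical fit.

## Trend regressions

Per country and lesion level (paraplegia / tetraplegia), the score is
regressed by OLS on one predictor at a time — chronological age, age
at injury, time since injury — with no further adjustment, matching
how such trends are usually displayed.  Subgroups with n < 3 or a
constant predictor are NA-flagged, never silently dropped; persons
with missing lesion level are excluded from the stratified fits and
counted.  For plotting, scores are summarized in 15-year age bins
(16–30, …, 76+, upper bounds closed; configurable) with t-based 95%
confidence intervals; single-member bins report the mean only.

## Environmental-factor importance

The 14 EF items ("not applicable / no influence / made my life a
little harder / a lot harder") become numeric severities 0/1/2, with
"not applicable" mapped to "no influence" by default (a listwise
alternative exists; the survey instrument does not dictate one).
Missing EF responses are imputed by iterative random forests (each
column regressed on the others until stable — the missForest scheme),
deterministic given the seed; a complete-case mode supports
sensitivity analysis.  Scores, age and lesion variables are never
imputed: rows missing them are excluded.

Relative importance uses PMVD.  With forced covariates partialled out
(included in every submodel, excluded from shares), the share of EF k
is the weighted average over orderings r of its sequential R²
increment, with weights w(r) ∝ Π_{i=1}^{p−1} [R²(full) − R²(first i
of r)]⁻¹.  Shares are nonnegative and sum to the EF-block R²
(full-model R² minus covariates-only R²).  Orderings are enumerated
exactly for ≤ 8 EFs and importance-sampled (uniform proposals,
self-normalized weights) above; the subset R² values come from one
precomputed cross-product matrix.  Degenerate weights (a prefix
already attaining the full R²) are handled by capping the denominator
at 1e-12, which reproduces the limit where orderings deferring
irrelevant regressors dominate.  Correctness is anchored in the test
suite by an independent brute-force re-derivation straight from raw
OLS fits, the orthogonal-design closed form (shares = squared
semipartial correlations), and the exclusion property (a
zero-coefficient regressor correlated 0.7 with a real determinant
receives < 1% of the block).

## Synthetic-data generator

`synthetic.generate_dataset` is first-class, tested code: it simulates
the multi-country survey the pipeline expects, with full ground truth
attached so every stage has a recoverable target.  Defaults emulate
the survey's structure: 11 countries of very unequal size (199–1,617,
6,635 persons total), ~27% female, ~61% paraplegia, ~80% traumatic
etiology, ages centered near 53, item bank of 15 items mixing binary
and 4–5-category responses, country-threshold DIF of SD 0.3, country
ability means of SD 0.5, small demographic missingness, 3% item and
10% EF missingness.  Age gradients enter the latent scale linearly
(θ shifted by slope × (age − 40)), with a steeper default decline for
paraplegia than tetraplegia, the simplest mechanism that produces
lesion-specific ageing curves of tunable strength.  EF responses
follow an ordinal-logistic law on −θ scaled by per-item coefficients
(two of the 14 are null by default), which induces the
barrier-functioning associations PMVD must recover without committing
to any particular real-world dependence structure.  A smaller balanced
design (5 × 300 persons, 15 four-category items) is provided as
`SyntheticConfig.recovery_demo()` and is the reference condition for
the recovery and calibration checks; at that size the full fit (1,500
warmup + 2,500 kept sweeps) runs in about five minutes on one CPU.

What the generator does *not* emulate: real countries' demographic
distributions, response-rate patterns, informative missingness beyond
the optional MAR-on-age switch, or any joint EF-demographics
structure.  Passing recovery tests on this generator shows the
pipeline estimates the model it claims to estimate; it does not
certify conclusions about any real survey population.

## Numerical choices and degenerate inputs

* All category-probability computations are log-sum-exp based; a = 0
  (uniform response) is admitted in the probability law for oracle
  tests but excluded by the prior.
* Thresholds are *not* order-constrained during sampling (the GPCM
  tolerates disorder); ordering is the monotonicity check's concern.
* Empty datasets are legal in `fit` (prior-only sampling, used to
  validate the sampler against the known prior); persons must
  otherwise have ≥ 1 non-missing item (the survey inclusion rule,
  enforced at ingestion with an exclusion log).
* PSRF needs ≥ 20 kept draws (10 per half-chain); fewer raise an
  explicit error.
* Polychoric optimization is bounded to |ρ| ≤ 0.995; item pairs are
  estimated from their contingency table, so cost is independent of n.
* Seeds: every stochastic component (generator, sampler, permutations,
  imputation, ordering sampling) takes an explicit seed; pipeline
  stages derive theirs from the single run seed.

## Known limitations

* The Metropolis-within-Gibbs sampler mixes more slowly than a
  gradient-based sampler would; with the default single chain the
  split-half PSRF is a necessary, not sufficient, convergence check.
* The score uses the posterior-mean ability; posterior score SDs are
  reported but downstream regressions treat scores as fixed, as is
  standard for this kind of two-stage analysis.
* Bifactor screening via Schmid-Leiman on least-squares factors is a
  screening device, not a fitted SEM; no fit indices are produced.
* PMVD shares are descriptive variance allocations; they support
  prioritization, not causal claims about barriers.
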