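# Methods

## Model and estimand

`acce` estimates total residual confounding — measured and unmeasured — of
a binary-treatment, binary-outcome cohort estimate, and from it an
unconfounded treatment effect, by exploiting confounding amplification.
All arithmetic is on the natural-log risk-ratio scale (β = ln RR); risk
ratios are accepted and emitted at the boundary.

The decomposition is `β_M1 = x + y + k`:

* `x` — confounding from confounders absent from **both** nested
  propensity models (the *amplifiable fraction*);
* `y` — confounding from the Introduced Variable's Model 1 imbalance
  (`Conf_IntV_M1`), which does not amplify because the variable joins
  Model 2's score;
* `k` — the genuine treatment effect, assumed identical under both models.

Model 2 (Model 1's covariates plus the Introduced Variables) yields
`β_M2 = A·x + y′ + k`, where `A = (1/(1−R²_M2))/(1/(1−R²_M1))` is the
between-model amplification predicted from the linear-probability exposure
fits, and `y′` is the (smaller) Introduced-Variable confounding remaining
after Model 2 balances it.  Solving for the only unknown,

`x = [(β_M2 − β_M1) − (y′ − y)] / (A − 1)`,  `k = β_M1 − x − y`.

`y` and `y′` come from the Bross bias factor for a binary confounder,
`ln B = ln[(1 + p_t(RR−1)) / (1 + p_c(RR−1))]`, with the Introduced
Variable's outcome RR taken from within-arm multivariate regressions and
its prevalences measured within propensity strata.

### Assumptions the algebra inherits

1. Amplification follows `1/(1−R²)` (simulation-supported for stratified
   or matched linear propensity scores over R² 0.04–0.56; a non-fatal
   warning marks results outside that band).
2. Different confounders amplify (near-)uniformly.
3. Differences between the models other than amplification — covariate
   balance, sample, dose — are negligible.
4. The regression coefficient + Bross factor capture the Introduced
   Variable's confounding contribution, including (imperfectly) that of
   its correlates.
5. Risk-ratio outcome model (collapsible); `k` common to both models.

## Estimation pipeline

* **Propensity scores** — OLS linear-probability fits (`treatment ~ 1 +
  covariates`); R² is the plain coefficient of determination.  Rank
  deficiency raises an error naming the collinear columns; R² = 1 refuses
  extrapolation.
* **Treatment effects** — subjects binned into `n_strata` (default 10)
  strata at empirical quantile cut points of the score; binning is by
  score *value*, so tied scores share a stratum and a constant score
  collapses to the crude estimate.  Per-stratum 2×2 tables are pooled as
  a Mantel–Haenszel risk ratio; strata lacking an arm are dropped with a
  logged count; all strata degenerate is an error.
* **Introduced-Variable outcome coefficient** — log-link Poisson working
  model (the standard modified-Poisson route to adjusted risk ratios) on
  the IV plus all other Model 2 covariates, fitted separately within each
  arm; arm coefficients pooled by sample-size weights.  If the GLM fails,
  a linear-risk OLS fit is converted to log-RR at the mean risk
  (first-order delta method) and flagged.  An IV constant within an arm
  falls back to a pooled regression with treatment and IV×treatment
  interaction, with a warning.
* **IV balance** — `Conf_IntV_M1` uses the stratum-size-weighted
  prevalences within Model 1's strata by default (`iv_balance_m1="raw"`
  switches to crude prevalences); the Model 2 term always uses Model 2's
  strata.  The Bross formula referenced to 50%/50% balance is exactly
  `ln B`, since balanced prevalences give `B = 1`.
* **Multiple Introduced Variables** — Bross terms are computed per
  variable from its marginal balance and summed; a joint treatment would
  need the joint distribution, which marginal balances do not determine.
  A warning marks the additive approximation.
* **Internal marker** — the ratio of a withheld covariate's
  stratum-weighted standardized imbalance under Model 2 to that under
  Model 1 can replace the R²-based `A`.  In this package's synthetic
  cohorts the marker ratio runs a stable ~10–15% *above* the R²
  prediction; it is a usable proxy, not a precision instrument, and its
  use always logs a caution.
* **Extrapolation floor** — OLS nesting makes the fitted increment
  `A − 1` mechanically positive even for a worthless Introduced Variable,
  so `ACCE.fit` refuses increments below `min_increment` (default 0.01)
  rather than divide a treatment-effect difference by sampling noise.

### Qualitative probe

`direction` is *away from the null* when the Model 1 → Model 2 change has
the sign of β_M1 (amplification pushes the estimate further in the
direction of its residual confounding), *toward the null* otherwise, and
*no change* below the negligible threshold.  Default |Δβ| cutoffs —
negligible < 0.01, small < 0.05, sizeable ≥ 0.05 — bracket the published
probe readings (≈ 0.024 "small", ≈ 0.097 "sizeable"); no canonical values
exist and both are configurable.

### Bootstrap

Percentile intervals from case-resampling of whole subjects (optionally
within arms), re-running the entire pipeline per replicate.  Replicates
failing the extrapolation floor are dropped and counted; > 20% failures
refuses the interval.  Percentile rather than BCa: it is the auditable
baseline, and the estimator's distribution is well-behaved at the sample
sizes where the method is usable at all.  Empirical coverage of a 95%
interval in the reference null scenario is ≈ 0.95–0.98 (measured by the
test suite's 120-repetition study at n = 2,000, B = 200).

## Synthetic validation cohorts

The generator draws the small-world structure the method's validation
calls for: standard-normal measured confounder `x`, binary Introduced
Variable `z` (prevalence 0.5), zero to two standard-normal unmeasured
confounders `u1`, `u2`.  Treatment is Bernoulli from a linear-probability
index clipped to [0.02, 0.98]; the outcome is Bernoulli from a log-risk
index (baseline risk 0.10, clipped above at 0.95) so the estimand is
exactly a risk ratio and `k` enters additively.  The IV–unmeasured
correlation is imposed on `z`'s latent Gaussian (Gaussian copula; the
stated correlation is latent-scale).  Clipping beyond 5% of subjects logs
a scenario warning; beyond 25% is an error.

Two generator facts shaped the default scenarios, both measured during
design:

1. **Clipping breaks the amplification law.**  Where the index saturates,
   the OLS score mis-ranks the true (clipped) propensity, leaving
   persistent within-stratum confounding.  A Bernoulli treatment with
   mean 0.5 pins var(T) = 1/4, so fitted R² pairs as high as (0.25, 0.5)
   *require* heavy clipping (≈ 40% of subjects) and cannot coexist with
   the generator's own validity limits.  The R²-calibrated reference
   scenario therefore targets fitted R² (0.10, 0.40) — the same 50%
   between-model increment as the worked examples at ≈ 10% clipping (the
   numeric pre-solve lives in `simulate.calibrate_exposure_weights`; the
   stored weights are 0.1856, 0.5745) — and the recovery scenario uses
   (0.04, 0.25) at < 1% clipping.
2. **Stratum geometry must match between models.**  A strong binary IV
   dominates Model 2's score, so ten score deciles resolve `x` only about
   half as finely as Model 1's, inflating the between-model change beyond
   the amplification law — precisely the "other differences between the
   models" the method requires be minimized.  Validation runs therefore
   stratify at `n_strata = 20` (2,500 subjects per stratum at n = 50,000);
   the package default for real analyses stays 10.

Under the no-correlation, true-instrument recovery scenario
(n = 50,000, 200 replicates, k = 0.0953) the pipeline's mean unconfounded
estimate sits within 0.01 of k (test-suite measurement; the acceptance
bound is ±0.02).  With an Introduced Variable that *does* carry an outcome
RR of 1.05 but no unmeasured-confounder correlation, the Bross terms
absorb the association and recovery still holds (±0.04 at n = 400,000).

### What the generator does *not* emulate

Real cohorts have many correlated, non-Gaussian covariates, measurement
error, missingness, time-varying exposure and hazard-type outcomes; the
generator has none of these.  Passing recovery tests therefore shows the
*algebra and estimation chain* are faithful under the method's own
assumptions — not that the method is accurate on real data, which the
method's authorship itself lists as open.  Two failure modes are
reproducible here and deliberately left uncorrected: (a) when the IV
correlates with an unmeasured confounder, the within-arm coefficient is
collider-biased (in the example-4-like scenario β̂_z ≈ −0.13 against a
true +0.049, flipping the Bross correction's sign and wrecking the
quantitative estimate, while the qualitative probe still reads correctly);
(b) heavy clipping (strong IVs) breaks the 1/(1−R²) extrapolation.

## Numerical and reporting choices

* Quantile ties: value-based cut points (deterministic, seed-free).
* Seeds: a scenario seed spawns per-replicate `SeedSequence` children by
  a fixed counter scheme; bootstrap and recovery runs are exactly
  reproducible.
* Reports serialize full-precision terms plus a 4-decimal display block;
  `core.worked_chain` additionally recomputes the summary equation with
  each intermediate rounded to 4 decimals before the next step — the desk
  convention in which the method's worked examples are printed — so
  reports can be audited line-by-line against a hand calculation.
* Probe thresholds, stratum count, minimum increment, bootstrap level and
  resampling mode are the configurable knobs; everything else is fixed by
  the method.

## Known limitations

No matching or IPTW estimators; no logistic-PS pseudo-R² (its relation to
amplification is unestablished); no odds-ratio or hazard-ratio Bross
variants and no noncollapsibility handling; no analytic (delta-method)
variance; confounding arising after treatment initiation is out of scope.
The c statistic is *not* accepted as an amplification index.
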