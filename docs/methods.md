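# Methods

## Model and estimands

The package measures socioeconomic inequality in a binary health outcome
observed in a complex cross-sectional survey (person-level sampling weights
`w_i`, design strata, PSU clusters, and a continuous household wealth
score). All estimands are defined on the weighted population.

**Fractional rank.** Weights are normalised to sum to one and records
ordered by wealth score. Each tie group of equal scores receives the rank
`r = (cumulative weight of strictly poorer records) + w_group/2`; every
member of a tie group shares that midpoint value. This makes the weighted
mean of the ranks equal to ½ *exactly* (not just in expectation), which the
downstream algebra relies on. Tie-group midpoints were chosen over
arbitrary within-tie ordering because they are permutation-invariant and
reproducible.

**Concentration index.** `C = 2 cov_w(h, r) / μ_h`, estimated two ways:

* *direct*: the plug-in covariance formula (used as the oracle in tests);
* *convenient regression*: WLS of `2 σ_r² h_i / μ_h` on `(1, r_i)` with the
  sampling weights. The slope is algebraically identical to the direct
  estimator when `σ_r²` is the weighted population variance of the ranks
  (no small-sample correction) — the package computes it that way, so the
  two routes agree to ~1e-15 and the test suite enforces 1e-10.

The regression route reports an HC1 sandwich SE for the slope. This SE is
advisory: it ignores the design and the estimated ranks; publication-grade
inference should come from the bootstrap. No binary-outcome normalisation
(Wagstaff or Erreygers) is applied: the standard index is the estimand, and
no age/sex standardisation is applied since the decomposition itself
accounts for covariates.

**Wagstaff decomposition.** A linear probability model
`h_i = α + Σ_k β_k x_ki + ε_i` is fitted by survey-weighted least squares
(statsmodels WLS). Then `C = Σ_k η_k C_k + GC_ε/μ_h` with
`η_k = β_k x̄_k / μ_h` evaluated at *weighted* column means (the weighting
of the means is not dictated by the identity; survey weighting keeps every
moment in the same population). `C_k` uses the *same* fractional ranks as
the outcome — one ranking per wave. A linear model for a binary outcome is
an acknowledged approximation; it is what makes the decomposition exact and
is retained deliberately (no logit/probit marginal-effects variant in the
main path).

**Residual as remainder.** The unexplained term is computed as
`C − Σ_k η_k C_k`, which equals `GC_ε/μ_h` algebraically; computing it as
the remainder guarantees exact additivity under floating point. The
`GC_ε/μ_h` identity is verified in tests at 1e-8 but is never the
computation path.

**Change decomposition.** `ΔC = Σ_k η_kt ΔC_k + Σ_k C_k,t−1 Δη_k + Δresidual`.
The weighting convention is fixed: current-period elasticities weight the
index changes; base-period indices weight the elasticity changes. The
reverse convention is available as an option (`reverse_weighting=True`) but
is not the default. The residual change is again the exact remainder. The
per-factor terms are *not* antisymmetric under swapping the waves (the
weighting is asymmetric by construction); only ΔC itself is. Urban/rural
subpopulation analyses filter the records first and recompute ranks within
the subpopulation.

## Data preparation conventions

* BMI (kg/m²) is computed as `1e4 · weight_kg / height_cm²` — algebraically
  identical to `kg/(m)²` but exact for records sitting precisely at a
  cutoff. Cutoffs are inclusive: overweight is BMI ≥ 25, obesity BMI ≥ 30.
* Cleaning flow, in fixed order so the exclusion log is deterministic:
  (1) age outside [15, 49] years; (2) pregnant — and, by default, unknown
  pregnancy status (conservative complete-case; configurable); (3) missing
  BMI; (4) BMI outside [12, 60] kg/m². The plausibility bounds are
  conventional anthropometric limits, configurable; a record failing
  several rules is counted at the first.
* Dummy coding omits one reference level per categorical factor. Defaults
  follow the usual convention of the largest/most disadvantaged category
  (race = black African, education = no schooling, employment = unemployed,
  marital = single/never married, residence = rural, smoking = non-smoker,
  SES = poorest quintile); all configurable, with the most frequent level
  as fallback. Age enters linearly in years.
* Wealth quintiles: cutpoints at weighted cumulative shares 0.2/0.4/0.6/0.8
  of the score; ties at a cutpoint all fall in the lower quintile, so each
  quintile's weighted share is 20% up to tie-induced deviation.

## Bootstrap

Each replicate resamples the data and re-runs the full pipeline — ranks,
quintiles, model fit, decomposition — because the ranks are themselves
estimates. Default resampling is PSUs with replacement within strata,
respecting the survey design; record-level resampling is available for
simple random samples and calibration studies. Intervals are percentile
intervals at 2.5/97.5% (simplest defensible choice; BCa was not needed for
SE reporting). B = 1,000 by default. Replicates that fail (e.g. a
rank-deficient design after resampling) are dropped and counted; more than
5% failures is an error. A fixed seed yields bit-identical results.

## Synthetic data generator

The generator emulates the structure this methodology is applied to,
without access to restricted survey files:

* wealth score ~ N(0, 1), optionally with an intra-PSU variance share
  (`wealth_icc`); the population rank is `u = Φ(score)`;
* categorical covariates drawn from multinomial-logistic level
  probabilities `P(level l | u) ∝ exp(a_l + b_l (u − ½))` — the slopes `b_l`
  give controllable monotone rank gradients with a well-defined truth; age
  is Gaussian (truncated to 15–49) with a chosen rank correlation;
* outcome `h ~ Bernoulli(clip(α + Σ β_k x_k, 0.02, 0.98))`. Clipping keeps
  the linear model coherent; a config whose probabilities escape the clip
  bounds on more than 5% of records is rejected rather than silently
  distorted. Multiple outcomes can share one uniform draw so that nested
  outcomes (obesity ⇒ overweight) are consistent, and anthropometry
  (height/weight/BMI) is synthesised to reproduce the flags through the
  data-preparation path;
* sampling weights equal by default, or mean-one gamma (shape 4) for
  DHS-like dispersion.

**Ground truth** is computed by an independent brute-force oracle: a fresh
draw of 10⁶ records under a fixed oracle seed (a separate stream from any
data seed, so truth and dataset are uncorrelated), evaluated with the
direct covariance formula on the *conditional outcome probabilities*
(removing Bernoulli noise without changing any expectation) — never through
the estimators under test. Truth accuracy is ~1e-3 on C and ~1e-4 on
individual contributions; tests that resolve finer differences combine the
oracle's Monte-Carlo SE (estimated from independent oracle runs) with the
replication SE.

**The two-wave preset** (`sadhs_like_configs`) mirrors a DHS-style
two-round survey: sample sizes 4,939 and 3,144, covariate mixes
shifting between waves (rising secondary education, falling smoking,
growing black-African share), rising outcome prevalence, wealth clustered
within 9 strata × 30 PSUs, gamma weights. Its intercepts and SES-quintile
coefficients were calibrated once against the oracle so the preset's
population indices sit near C ≈ 0.02→0.04 (overweight) and 0.06→0.08
(obesity) with prevalences near 50%→62% and 24%→35%, then frozen. The
preset's truth is the generator's own, not any survey's.

**What passing tests do and do not show.** The generator reproduces survey
weighting, stratification/clustering, rank-graded covariates and a linear
outcome process. It does not emulate multistage selection probabilities,
nonresponse, anthropometric measurement error, or model misspecification.
Recovery results therefore validate the estimators under a correctly
specified linear model — they say nothing about substantive epidemiology on
real data.

## Numerical choices and degenerate inputs

* All-tied wealth scores, all-zero outcomes, nonpositive weights, single-
  level factors and rank-deficient designs raise errors naming the culprit.
* A design column with (numerically) zero weighted mean has an undefined
  factor index; its contribution is set to 0 with a warning and its effect
  lands in the residual. The zero test is `|x̄| < 1e-12 · max|x|`.
* Percent shares are reported but flagged unstable when `|C|` (or `|ΔC|`)
  is below 1e-4 — shares of a near-zero total are not interpretable.
* Multiplying all weights by a constant leaves every output unchanged
  (weights are normalised once, up front).
* Problem sizes in the statistical test suite — 200 replicates at
  n = 20,000 for recovery, 50 replicates per n ∈ {10³, 10⁴, 10⁵} for the
  consistency rate, 1,000 draws and B = 1,000 at n = 5,000 for bootstrap
  calibration, 200 datasets for CI coverage — were chosen so Monte-Carlo
  error is well below the tolerances being asserted.

## Known limitations

* The linear probability model can fit probabilities outside [0, 1] on
  real data; the decomposition remains exact but coefficients lose their
  probability interpretation in the tails.
* Elasticities are evaluated at the means, so grouped contributions of
  dummy blocks depend on the chosen reference level.
* The advisory regression SE understates uncertainty relative to the
  design-aware bootstrap.
* Complete-case analysis only; no imputation of missing covariates.
* The Oaxaca-type split of ΔC is weighting-convention dependent; both
  conventions are provided, and only the default is used in reported
  output.
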