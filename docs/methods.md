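# Methods note

This note records the statistical model behind the `canid` package, the
parameter choices and their rationale, the numerical decisions, and what
the simulator can and cannot stand in for.

## 1. Trial scoring

Scoring is a pure function of the validated trial sequence.

**Spatial Reversal.** A block ends when at least 3 of the trailing 4
scored trials are open-side approaches; detection uses a running window,
and the criterion-meeting trial index is the smallest `t >= 4` with that
property. The baseline block is capped at 20 scored trials; the reversal
phase shares a budget of 20 scored trials across at most 3 blocks. The
three dependent measures are blocks completed (0–4), longest block (4–20)
and reversal trials remaining (0–20). A dog that never meets the baseline
criterion receives the worst score (0, 20, 0). No-choice administrations
and their motivator repeats never count toward caps or block lengths; the
final administration of a trial slot is the scored one. Fear aborts leave
all three measures missing.

**Delayed Search.** Twelve trials — 4 no-delay, 2 each at 10 s, 10 s with
distraction, 20 s with distraction, 40 s with distraction — with baited
locations balanced 3× each and never consecutive. The measure is the
proportion of correct first searches per trial type; a type with no scored
trials is missing (later imputed). Four no-choice events discontinue the
task.

**Cylinder.** Four trials; success is responding without first touching
the cylinder's exterior. Dogs responding on three or fewer trials are
excluded (measure missing).

## 2. Composite scores

Fitted once on baseline, then frozen:

1. First principal component of the correlation matrix of the SR triple,
   and of the five DS proportions. Eigenvector signs are resolved so that
   `sr_blocks` / `ds_p_nodelay` load positively (higher = better). The
   Cylinder score is its single proportion.
2. Yeo-Johnson transformation of the SR and DS component scores.
   Lambda is the maximum-likelihood value, found by a 61-point grid on
   [−3, 3] plus golden-section refinement to 1e-6 — deterministic and
   platform-stable, verified against `scipy.stats.yeojohnson` and
   scikit-learn's `PowerTransformer`.
3. z-standardization of each task score by its baseline mean/SD.
4. First principal component of the three standardized task scores,
   sign-fixed so the loadings sum is positive, then z-standardized again:
   the overall score.

Projection of retest data applies only stored constants
(`CanidScorer.transform`); `transform(baseline)` reproduces the fitted
baseline scores exactly. The fitted model serializes to a versioned JSON
document.

**Missing data.** Missing DS trial-type proportions (when at least one
type is observed) are filled by predictive mean matching against the
baseline complete-case pool: regression of the missing type on the
observed types, k = 5 nearest donors by predicted value, one donor's
*observed* value copied in. The donor draw is seeded per
(dog, timepoint) via a CRC32 hash, so results are reproducible and
independent of row order. A session missing exactly one task score has it
filled by a deterministic linear regression (no noise) on the two observed
scores plus location indicators, and the `_imputed` flag is set; sessions
missing two or more task scores get no overall score. Imputed values feed
the composite only — repeatability and aging fits drop flagged rows.

## 3. Mixed models

All ICCs and aging models use a single-random-intercept linear mixed
model fitted by the package's own profiled ML/REML routine
(`canid.lmm`): the likelihood is profiled to one dimension over
θ = σ²_between/σ²_residual, using the closed-form inverse
(I + θJ)⁻¹ = I − θ/(1 + θn_i) J of the per-dog covariance blocks, and
optimized by bounded scalar search over log θ ∈ [−12, 10] with an explicit
θ = 0 boundary check (variance components are never negative). The test
suite verifies exact agreement with `statsmodels.MixedLM` (coefficients,
variance components and log-likelihood, both ML and REML). A fit costs a
few milliseconds, which is what makes the 1,000-replicate parametric
bootstrap and the simulation batteries affordable.

**Repeatability.** ICC = σ²_between / (σ²_between + σ²_residual), in
three flavors: pairwise (dogs measured at both of two timepoints,
intercept-only model), intercept-only over all timepoints, and adjusted
(fixed effects: timepoint, age polynomial, sex, location). Confidence
intervals are percentile intervals from a seeded parametric bootstrap
(dog-level re-simulation from the fitted model, 1,000 replicates by
default). Cohen's kappa uses the standard marginal-product formula; the
degenerate all-identical-constant case is defined as 1 and logged.

**Aging model.** For each score:
`y ~ 1 + tp_m6 + tp_m12 + P1(age) + P2(age) + sex_male + loc_CC + loc_SSP + (1|dog)`,
with P1/P2 an orthogonal quadratic polynomial built by the three-term
recurrence; the recurrence constants are stored so follow-up ages project
onto the same frozen columns. Coefficients and Wald 95% intervals come
from REML; the age likelihood-ratio test (df = 2) and the effect sizes use
full-ML refits of the nested models. Partial R² and Cohen's f² are
computed from the marginal (fixed-effects) R² of the nested fits:
`partial R² = (R²f − R²r)/(1 − R²r)`, `f² = (R²f − R²r)/(1 − R²f)`.

## 4. Simulator

Latent ability `a_it = β0 + β1·age + β2·age² + u_i + δ_t + ε_it`,
`u_i ~ N(0, τ²)`, `ε ~ N(0, σ²)`, drives trial outcomes through logistic
links per task. The response model is the package's own construction —
it exists to exercise the scorers and statistics against known truth, not
to claim behavioral realism.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_dogs` | 239 | study cohort size |
| age | mean 7, SD 4, truncated 1–16 y | study demographics; moment-matched truncated normal |
| locations | ACCC 0.49 / CC 0.13 / SSP 0.33 | study site mix (renormalized) |
| `retention_m6`, `retention_m12` | 0.59, 0.49 | study retest retention |
| `beta_age1`, `beta_age2` | 0.03, −0.014 | mild quadratic decline accelerating past mid-life |
| `tau`, `sigma` | 0.866, 0.5 | true latent ICC 0.75; after link + scoring noise the composite's intercept-only ICC lands near 0.6, the study's headline repeatability |
| `delta_m6`, `delta_m12` | 0.25, 0 | practice effect expressed in baseline latent-SD units (matching how standardized scores express it); 0.25 SD at the first retest |
| SR link | slope 1.0, base 1.3, perseveration 2.5 decaying ×0.7/trial | typical dogs pass baseline quickly but pay a reversal cost that criterion blocks can detect |
| DS penalties | 0, 0.5, 0.9, 1.2, 1.5 | accuracy decreases with delay/distraction |
| event rates | no-choice ~1.5–2%, aborts SR 1.2% / DS 0.4% / Cyl 0 | sparse, as in the study |

Practice deltas are scaled by the baseline latent SD (age-curve variance
+ τ² + σ²) before entering the latent model, so a configured
`delta_m6 = 0.25` is recovered as ≈ 0.25 by the standardized-score aging
model — this is what the end-to-end recovery acceptance test checks.

Every draw descends from a single `SeedSequence`, so cohorts are exactly
reproducible and CLI reruns are byte-identical.

**Scope and limits.** The simulator reproduces the protocol (caps,
criteria, repeats, discontinuation, balanced DS orders) and the study's
design (demographics, dropout), but not dog behavior per se: real
perseveration, motivation and site effects are richer than a logistic
link, location does not influence simulated ability, and dropout is
missing-completely-at-random while real attrition likely is not.

## 5. Numerical choices and problem sizes

- PCA by `numpy.linalg.eigh` of the explicit correlation matrix (3–5
  variables — no need for SVD); verified against scikit-learn's `PCA`.
- Yeo-Johnson lambda by grid + golden-section rather than generic
  quasi-Newton, for cross-platform determinism.
- LMM per fit: ~500 observations, ~240 groups, ≤ 8 fixed effects; the
  profiled closed form keeps a 1,000-replicate bootstrap under a few
  seconds.
- CSV round trips are bit-exact: floats serialized with `repr`, booleans
  lowercase, missing values as empty fields, `#` provenance comments.
- Typical validation sizes: 80–300 dogs per simulated cohort; 100
  end-to-end replicates for the recovery acceptance test (~90 s).

## 6. Limitations

- Confidence intervals for ICCs are parametric-bootstrap percentiles;
  they assume the fitted Gaussian random-intercept model.
- The adjusted ICC conditions on fixed covariates estimated on the same
  data; no uncertainty from the composite-score fitting step propagates
  into downstream intervals.
- Single-task imputation is deterministic regression (no posterior draws),
  appropriate for point scoring but not for multiple-imputation inference.
- The published-value benchmark suite requires the study's deposited
  dataset, which is not redistributable with this package; those checks
  fail until the data are placed at `data/deposited/merged_measures.csv`.
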