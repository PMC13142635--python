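# canid

Scoring, psychometrics and longitudinal analysis for **CANID** (Cognitive
Assessment for Neuropsychological Impairments in Dogs), a three-task
behavioral battery for companion dogs, plus a protocol-faithful behavioral
simulator with known ground truth.

## The problem

A dog's cognitive status is measured with three short behavioral tasks:

- **Spatial Reversal** — the open side of a V-shaped barrier alternates;
  the dog must flexibly re-learn which side is open. Scored as blocks
  completed under a 3-of-4 trailing-window criterion (0–4), the single
  longest block (4–20 trials), and unused reversal trials out of 20.
  A dog that never passes the baseline block is assigned the worst
  possible score (0 blocks, longest block 20, 0 trials remaining).
- **Delayed Search** — food is hidden at one of four locations and the dog
  searches after a delay (0/10/20/40 s), with or without distraction;
  scored as the proportion of correct first searches per trial type over
  12 trials.
- **Cylinder** — a transparent-detour inhibition task; success means
  retrieving food without first touching the cylinder's exterior, over
  4 trials.

These raw measures are combined into standardized task scores and one
**overall cognitive score** via a baseline-fitted chain of correlation-scale
PCA, Yeo-Johnson normalization, z-standardization and a second PCA. The
model is frozen after fitting: retest sessions are *projected* through the
stored constants, never refitted, so scores from different timepoints are
comparable. The package then answers the two study questions:

- **Repeatability** — pairwise, intercept-only and covariate-adjusted
  intraclass correlations (ICC) from random-intercept mixed models, with
  seeded parametric-bootstrap confidence intervals; Cohen's kappa for
  categorical rater agreement.
- **Aging and practice effects** — a linear mixed model of each score on an
  orthogonal quadratic age polynomial, timepoint contrasts (the practice
  effects), sex and test location, with a likelihood-ratio test and
  variance-explained effect sizes for age.

Because the real study data cannot ship with the package, a **simulator**
generates cohorts from a latent-ability model with configurable age
decline, between/within-dog variance, practice effects, dropout, no-choice
events and fear aborts — all protocol-correct and fully seeded — so every
statistical routine can be validated against known truth.

## Worked example

```python
import numpy as np
from canid import SimConfig, simulate_cohort, CanidScorer
from canid.simulator import cohort_measures
from canid import repeatability, aging

cohort = simulate_cohort(SimConfig(n_dogs=80), seed=7)   # 170 sessions
merged = cohort_measures(cohort)                          # measures + covariates

baseline = merged[merged["timepoint"] == "baseline"]
scorer = CanidScorer(random_state=11).fit(baseline)       # frozen on baseline
scores = scorer.transform(merged)                         # project all sessions

scorer.overall_pca_.loadings            # [0.606, 0.589, 0.535]
scorer.overall_pca_.explained_var_ratio # 0.803

icc = repeatability.model_icc(scores, "overall_score", seed=0, n_boot=200)
print(icc.estimate, icc.ci_low, icc.ci_high)
# 0.72 [0.60, 0.81] over 80 dogs

fit = aging.fit_aging_model(scores, "overall_score")
fit.params.loc["tp_m6", "estimate"]     # 0.25  (simulated practice effect 0.25)
fit.params.loc["tp_m12", "estimate"]    # -0.04 (simulated effect 0)

eff = aging.age_effect_size(scores, "overall_score", fit=fit)
eff.lrt_chi2                            # 52.5, p ~ 4e-12: age decline detected
```

The first scored rows look like:

```
 dog_id timepoint  sr_score  ds_score  cyl_score  overall_score
dog0000  baseline     -0.41     -0.62      -0.04          -0.41
dog0000        m6     -0.27      0.02      -0.88          -0.40
dog0000       m12     -1.24     -1.39      -0.88          -1.32
```

## Command line

Each pipeline stage is a subcommand; `pipeline` chains them:

```sh
canid simulate --seed 7 --out-dir run/            # trials + truth.json
canid score --trials-dir run/ --out run/measures.csv
canid composite --measures run/measures.csv --sessions run/sessions.csv \
    --dogs run/dogs.csv --out run/scores.csv --model-out run/model.json
canid repeatability --scores run/scores.csv --out run/icc_table.csv
canid aging --scores run/scores.csv --out run/aging_table.csv
# or everything at once:
canid pipeline --seed 7 --out-dir run/
```

All outputs are plain CSV with a `#` provenance comment (package version,
seed, config fingerprint). Exit codes: 0 success, 1 usage error, 2 data
validation error, 3 numerical failure. Reruns with the same seed are
byte-identical.

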