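"""Repeatability: intraclass correlations and inter-rater agreement.

Three ICC flavors are reported, mirroring how test-retest reliability is
summarized for the battery:

* pairwise — variance-components ICC on the subset of dogs measured at two
  given timepoints (equivalently a one-way agreement ICC);
* intercept-only — ICC from a random-intercept model with no covariates on
  all timepoints, comparable to R (repeatability) as reported in animal
  behavior studies;
* adjusted — ICC from a mixed model whose fixed effects (age polynomial,
  timepoint, sex, location) absorb systematic variance before partitioning.

In every case ICC = var_between / (var_between + var_residual), estimated
by REML; negative component estimates are truncated at zero by the
optimizer's boundary.  95% confidence intervals come from a parametric
bootstrap: responses are re-simulated at the dog level from the fitted
model and the ICC re-estimated (1,000 replicates by default, seeded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .lmm import fit_random_intercept

logger = logging.getLogger(__name__)

MIN_PAIRED_DOGS = 10
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str          # pairwise | intercept_only | adjusted
    n_dogs: int
    n_obs: int


def _icc_with_bootstrap(y, X, groups, method, n_boot, seed, exog_names=None):
    fit = fit_random_intercept(y, X, groups, reml=True, exog_names=exog_names)
    if fit.sigma2_b == 0:
        logger.warning("between-dog variance estimated at the zero boundary "
                       "(%s ICC)", method)
    est = fit.icc
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            yb = fit.simulate(rng)
            boot[b] = fit_random_intercept(yb, X, groups, reml=True).icc
        lo, hi = np.percentile(boot, [2.5, 97.5])
        lo, hi = min(lo, est), max(hi, est)
    return ICCResult(estimate=float(est), ci_low=float(lo), ci_high=float(hi),
                     method=method, n_dogs=fit.n_groups, n_obs=fit.n_obs)


def pairwise_icc(scores: pd.DataFrame, t1: str, t2: str, measure: str,
                 seed=None, n_boot: int = DEFAULT_N_BOOT) -> ICCResult:
    """Two-timepoint ICC for one score column.

    Only dogs observed (non-missing, non-imputed where a flag column exists)
    at both ``t1`` and ``t2`` contribute.
    """
    sub = _usable(scores, measure)
    sub = sub[sub["timepoint"].isin([t1, t2])]
    counts = sub.groupby("dog_id")["timepoint"].nunique()
    dogs = counts[counts == 2].index
    sub = sub[sub["dog_id"].isin(dogs)]
    if len(dogs) < MIN_PAIRED_DOGS:
        raise InsufficientDataError(
            f"need >= {MIN_PAIRED_DOGS} dogs measured at both {t1} and {t2}, "
            f"got {len(dogs)}")
    y = sub[measure].to_numpy(dtype=float)
    X = np.ones((len(sub), 1))
    return _icc_with_bootstrap(y, X, sub["dog_id"].to_numpy(), "pairwise",
                               n_boot, seed, exog_names=["intercept"])


def model_icc(scores: pd.DataFrame, measure: str, covariates=None,
              seed=None, n_boot: int = DEFAULT_N_BOOT) -> ICCResult:
    """ICC from a random-intercept model, optionally covariate-adjusted.

    ``covariates`` is a design matrix (DataFrame or 2-D array, no intercept
    column) aligned with the usable rows of ``scores`` after dropping
    missing/imputed values of ``measure`` — pass the output of
    :func:`canid.aging.build_design` for the adjusted ICC, or None for the
    unadjusted (intercept-only) model.
    """
    sub = _usable(scores, measure)
    if sub["timepoint"].nunique() < 2:
        raise InsufficientDataError("need >= 2 timepoints for a model ICC")
    y = sub[measure].to_numpy(dtype=float)
    if covariates is None:
        X = np.ones((len(sub), 1))
        names = ["intercept"]
        method = "intercept_only"
    else:
        C = np.asarray(covariates, dtype=float)
        if len(C) != len(sub):
            raise ValueError("covariates not aligned with usable score rows")
        X = np.column_stack([np.ones(len(sub)), C])
        names = ["intercept"] + (
            list(covariates.columns) if hasattr(covariates, "columns")
            else [f"x{j}" for j in range(C.shape[1])])
        method = "adjusted"
    return _icc_with_bootstrap(y, X, sub["dog_id"].to_numpy(), method,
                               n_boot, seed, exog_names=names)


def usable_scores(scores: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Rows where ``measure`` is observed and not imputed."""
    return _usable(scores, measure)


def _usable(scores, measure):
    sub = scores[scores[measure].notna()]
    flag = {"sr_score": "sr_imputed", "ds_score": "ds_imputed",
            "cyl_score": "cyl_imputed"}.get(measure)
    if flag is not None and flag in sub.columns:
        sub = sub[~sub[flag].astype(bool)]
    return sub.reset_index(drop=True)


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement between two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginal products.  When both raters are constant and identical
    (p_e = 1) agreement is perfect but the formula is 0/0; by convention 1
    is returned and the degenerate case logged.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 ratings")
    cats = np.union1d(a, b)
    n = len(a)
    p_o = np.mean(a == b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        logger.warning("both raters constant and identical; kappa defined as 1")
        return 1.0
    return float((p_o - p_e) / (1 - p_e))


def repeatability_table(scores: pd.DataFrame, design_builder=None,
                        seed=None, n_boot: int = DEFAULT_N_BOOT) -> pd.DataFrame:
    """Adjusted, intercept-only and pairwise ICCs for every score column.

    ``design_builder`` maps a usable score subset to the adjusted-model
    covariate matrix; when None the adjusted column is omitted.
    """
    from itertools import combinations
    measures = [("overall_score", "Overall Score"),
                ("sr_score", "Spatial Reversal"),
                ("ds_score", "Delayed Search"),
                ("cyl_score", "Cylinder")]
    tps = [t for t in ("baseline", "m6", "m12")
           if t in set(scores["timepoint"])]
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rows = []
    for measure, label in measures:
        child = iter(ss.spawn(8))
        row = {"measure": label}
        if design_builder is not None:
            sub = _usable(scores, measure)
            r = model_icc(scores, measure, covariates=design_builder(sub),
                          seed=next(child), n_boot=n_boot)
            row["adjusted"] = _fmt(r)
        r = model_icc(scores, measure, seed=next(child), n_boot=n_boot)
        row["intercept_only"] = _fmt(r)
        for t1, t2 in combinations(tps, 2):
            r = pairwise_icc(scores, t1, t2, measure, seed=next(child),
                             n_boot=n_boot)
            row[f"{t1}/{t2}"] = _fmt(r)
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(r: ICCResult) -> str:
    return f"{r.estimate:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
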