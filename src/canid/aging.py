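"""Longitudinal mixed-effects models of cognitive scores.

The working model for a standardized score y of dog i at visit t is

    y_it = b0 + b1 P1(age_it) + b2 P2(age_it)
           + d_m6 + d_m12 + b_male + b_CC + b_SSP + u_i + e_it

with a second-degree orthogonal age polynomial (P1, P2), timepoint
contrasts against baseline (the practice effects), sex against female,
test location against the Arizona Canine Cognition Center, and a random
intercept per dog.  Coefficients and Wald intervals come from REML fits;
the age likelihood-ratio test and the effect sizes use full-ML refits of
the nested models.

The orthogonal-polynomial basis is computed on all modeled observations
(all timepoints pooled) and frozen, so new ages can be projected onto the
same columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FittingError
from .lmm import RandomInterceptFit, fit_random_intercept

AGE_DF = 2  # degrees of freedom of the age polynomial


# ---------------------------------------------------------------------------
# Orthogonal polynomial basis
# ---------------------------------------------------------------------------

@dataclass
class OrthoPolyBasis:
    """Frozen discrete orthogonal polynomial basis of a given degree.

    Built by the three-term recurrence; ``alpha`` and ``norm2`` are the
    recurrence constants, stored so the same columns can be evaluated on
    new data (they are centered, mutually orthogonal and unit-norm on the
    fitting data only).
    """

    degree: int
    alpha: np.ndarray
    norm2: np.ndarray   # length degree + 1, starting with the constant term

    def columns(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f_prev = np.zeros_like(x)
        f = np.ones_like(x)
        cols = []
        for j in range(self.degree):
            if j == 0:
                f_next = (x - self.alpha[j]) * f
            else:
                f_next = (x - self.alpha[j]) * f \
                    - (self.norm2[j] / self.norm2[j - 1]) * f_prev
            f_prev, f = f, f_next
            cols.append(f / np.sqrt(self.norm2[j + 1]))
        return np.column_stack(cols)


def orthogonal_poly(x, degree: int = AGE_DF):
    """Orthonormal polynomial design columns plus the reusable basis.

    Returns ``(columns, basis)``: ``columns`` has shape (n, degree) with
    centered, mutually orthogonal, unit-norm columns; ``basis`` reproduces
    them (or evaluates the same polynomials) on any input.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise FittingError(
            f"need >= {degree + 1} distinct values for a degree-{degree} "
            "orthogonal polynomial")
    n = len(x)
    alpha = np.empty(degree)
    norm2 = np.empty(degree + 1)
    f_prev = np.zeros(n)
    f = np.ones(n)
    norm2[0] = n
    cols = []
    for j in range(degree):
        alpha[j] = np.sum(x * f * f) / np.sum(f * f)
        if j == 0:
            f_next = (x - alpha[j]) * f
        else:
            f_next = (x - alpha[j]) * f - (norm2[j] / norm2[j - 1]) * f_prev
        norm2[j + 1] = np.sum(f_next * f_next)
        f_prev, f = f, f_next
        cols.append(f / np.sqrt(norm2[j + 1]))
    basis = OrthoPolyBasis(degree=degree, alpha=alpha, norm2=norm2)
    return np.column_stack(cols), basis


# ---------------------------------------------------------------------------
# Design construction and fitting
# ---------------------------------------------------------------------------

FIXED_EFFECT_NAMES = ["intercept", "tp_m6", "tp_m12", "age_poly1", "age_poly2",
                      "sex_male", "loc_CC", "loc_SSP"]


def build_design(df: pd.DataFrame, basis: OrthoPolyBasis = None,
                 include_age: bool = True):
    """Covariate matrix (no intercept) for the aging model.

    Reference levels: baseline timepoint, female, ACCC location.  Returns
    ``(DataFrame, basis)``; pass a stored ``basis`` to project new ages
    onto frozen polynomial columns.
    """
    if basis is None:
        _, basis = orthogonal_poly(df["test_age_years"].to_numpy(), AGE_DF)
    cols = {
        "tp_m6": (df["timepoint"] == "m6").astype(float).to_numpy(),
        "tp_m12": (df["timepoint"] == "m12").astype(float).to_numpy(),
    }
    if include_age:
        P = basis.columns(df["test_age_years"].to_numpy())
        cols["age_poly1"] = P[:, 0]
        cols["age_poly2"] = P[:, 1]
    cols["sex_male"] = (df["sex"] == "male").astype(float).to_numpy()
    cols["loc_CC"] = (df["location"] == "CC").astype(float).to_numpy()
    cols["loc_SSP"] = (df["location"] == "SSP").astype(float).to_numpy()
    return pd.DataFrame(cols), basis


@dataclass
class AgingModelFit:
    """Fixed effects with Wald intervals plus the nested full-ML fits."""

    measure: str
    params: pd.DataFrame          # index: effect names; estimate, ci_low, ci_high, p
    sigma2_b: float
    sigma2_e: float
    llf_reml: float
    n_dogs: int
    n_obs: int
    basis: OrthoPolyBasis
    ml_full: RandomInterceptFit = field(repr=False)
    ml_no_age: RandomInterceptFit = field(repr=False)


@dataclass(frozen=True)
class AgeEffectSize:
    partial_r2: float
    cohens_f2: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float


def fit_aging_model(scores: pd.DataFrame, measure: str) -> AgingModelFit:
    """Fit the aging/practice model for one score column."""
    sub = scores.dropna(subset=[measure, "test_age_years", "sex", "location",
                                "timepoint"]).reset_index(drop=True)
    flag = {"sr_score": "sr_imputed", "ds_score": "ds_imputed",
            "cyl_score": "cyl_imputed"}.get(measure)
    if flag is not None and flag in sub.columns:
        sub = sub[~sub[flag].astype(bool)].reset_index(drop=True)
    if sub["timepoint"].nunique() < 2:
        raise FittingError("need >= 2 timepoints for the aging model")
    y = sub[measure].to_numpy(dtype=float)
    groups = sub["dog_id"].to_numpy()
    C, basis = build_design(sub)
    X = np.column_stack([np.ones(len(sub)), C.to_numpy()])
    names = ["intercept"] + list(C.columns)

    reml = fit_random_intercept(y, X, groups, reml=True, exog_names=names)
    if reml.sigma2_b == 0:
        import logging
        logging.getLogger(__name__).warning(
            "singular random effect (between-dog variance 0) for %s", measure)
    ci = reml.conf_int()
    params = pd.DataFrame({"estimate": reml.beta, "ci_low": ci[:, 0],
                           "ci_high": ci[:, 1], "p": reml.pvalues()},
                          index=names)

    ml_full = fit_random_intercept(y, X, groups, reml=False, exog_names=names)
    C0, _ = build_design(sub, basis=basis, include_age=False)
    X0 = np.column_stack([np.ones(len(sub)), C0.to_numpy()])
    ml_no_age = fit_random_intercept(y, X0, groups, reml=False,
                                     exog_names=["intercept"] + list(C0.columns))
    return AgingModelFit(measure=measure, params=params,
                         sigma2_b=reml.sigma2_b, sigma2_e=reml.sigma2_e,
                         llf_reml=reml.llf, n_dogs=reml.n_groups,
                         n_obs=reml.n_obs, basis=basis,
                         ml_full=ml_full, ml_no_age=ml_no_age)


def _marginal_r2(fit: RandomInterceptFit) -> float:
    """Variance explained by fixed effects alone (marginal R2)."""
    var_f = np.var(fit.fitted_fixed())
    return var_f / (var_f + fit.sigma2_b + fit.sigma2_e)


def age_effect_size(scores: pd.DataFrame, measure: str,
                    fit: AgingModelFit = None) -> AgeEffectSize:
    """Likelihood-ratio test and variance-explained effect sizes for age.

    The LRT compares full-ML fits with and without the two age-polynomial
    terms (df = 2).  Partial R2 and Cohen's f2 are computed on the marginal
    (fixed-effects) R2 of the two nested mixed models:

        partial R2 = (R2_full - R2_red) / (1 - R2_red)
        f2         = (R2_full - R2_red) / (1 - R2_full)
    """
    if fit is None:
        fit = fit_aging_model(scores, measure)
    chi2 = 2.0 * (fit.ml_full.llf - fit.ml_no_age.llf)
    chi2 = max(chi2, 0.0)
    p = stats.chi2.sf(chi2, AGE_DF)
    r2_full = _marginal_r2(fit.ml_full)
    r2_red = _marginal_r2(fit.ml_no_age)
    partial = (r2_full - r2_red) / (1 - r2_red)
    f2 = (r2_full - r2_red) / (1 - r2_full)
    return AgeEffectSize(partial_r2=float(partial), cohens_f2=float(f2),
                         lrt_chi2=float(chi2), lrt_df=AGE_DF, lrt_p=float(p))


def aging_table(scores: pd.DataFrame,
                measures=("overall_score", "sr_score", "ds_score",
                          "cyl_score")) -> pd.DataFrame:
    """Coefficient table (estimate, 95% CI, p) for each score column."""
    rows = []
    for measure in measures:
        fit = fit_aging_model(scores, measure)
        eff = age_effect_size(scores, measure, fit=fit)
        for name, r in fit.params.iterrows():
            rows.append({"measure": measure, "term": name,
                         "estimate": r["estimate"], "ci_low": r["ci_low"],
                         "ci_high": r["ci_high"], "p": r["p"]})
        rows.append({"measure": measure, "term": "age_lrt_chi2",
                     "estimate": eff.lrt_chi2, "ci_low": np.nan,
                     "ci_high": np.nan, "p": eff.lrt_p})
        rows.append({"measure": measure, "term": "age_partial_r2",
                     "estimate": eff.partial_r2, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan})
        rows.append({"measure": measure, "term": "age_cohens_f2",
                     "estimate": eff.cohens_f2, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan})
    return pd.DataFrame(rows)
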