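"""Linear mixed model with a single random intercept per group.

The model is ``y = X b + u_g + e`` with ``u_g ~ N(0, sigma2_b)`` and
``e ~ N(0, sigma2_e)``.  The likelihood (ML or REML) is profiled down to a
one-dimensional optimization over the variance ratio ``theta =
sigma2_b / sigma2_e``: for fixed theta the GLS coefficients and the scale
have closed forms, because the marginal covariance is block diagonal with
blocks ``sigma2_e (I + theta J)`` whose inverse and determinant are
available analytically.  This makes a single fit a few hundred
floating-point operations per group, which is what allows the parametric
bootstrap (1,000 refits per confidence interval) and the simulation-based
test batteries to run quickly.

The boundary ``theta = 0`` (no between-group variance) is always evaluated
and kept when it beats the interior optimum; variance components are never
negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_THETA_LO, _LOG_THETA_HI = -12.0, 10.0


@dataclass
class RandomInterceptFit:
    """Result of :func:`fit_random_intercept`."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_b: float
    sigma2_e: float
    llf: float
    reml: bool
    n_obs: int
    n_groups: int
    df_resid: int
    exog_names: list
    _X: np.ndarray = None
    _group_codes: np.ndarray = None

    @property
    def icc(self) -> float:
        return self.sigma2_b / (self.sigma2_b + self.sigma2_e)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald confidence intervals for the fixed effects."""
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        se = self.se_beta
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm
        z = self.beta / self.se_beta
        return 2 * norm.sf(np.abs(z))

    def fitted_fixed(self) -> np.ndarray:
        return self._X @ self.beta

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (parametric bootstrap)."""
        u = rng.normal(0.0, np.sqrt(self.sigma2_b), size=self.n_groups)
        e = rng.normal(0.0, np.sqrt(self.sigma2_e), size=self.n_obs)
        return self.fitted_fixed() + u[self._group_codes] + e


def _profile(theta, n_i, XtX, Xty, yty, Sx, Sy, n, p, reml):
    """Profiled negative log-likelihood and GLS pieces at a given theta."""
    c = theta / (1.0 + theta * n_i)                      # per-group shrink
    A = XtX - (Sx.T * c) @ Sx                            # X' V~^-1 X
    b = Xty - Sx.T @ (c * Sy)                            # X' V~^-1 y
    yVy = yty - np.sum(c * Sy ** 2)
    beta = np.linalg.solve(A, b)
    Q = yVy - beta @ b
    logdet_blocks = np.sum(np.log1p(theta * n_i))
    if reml:
        sigma2 = Q / (n - p)
        sign, logdet_A = np.linalg.slogdet(A)
        nll = 0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                     + logdet_blocks + logdet_A)
    else:
        sigma2 = Q / n
        nll = 0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_blocks)
    return nll, beta, sigma2, A


def fit_random_intercept(y, X, groups, reml=True, exog_names=None):
    """Fit the random-intercept model by profiled ML or REML.

    Parameters
    ----------
    y : (n,) array
    X : (n, p) array — fixed-effects design, including the intercept column.
    groups : (n,) array of group labels (any hashable dtype).
    reml : bool
        REML (default) for reported coefficients and variance components;
        use ``reml=False`` for likelihood-ratio tests of fixed effects.

    Returns
    -------
    RandomInterceptFit
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible lengths")
    codes, _ = pd_factorize(groups)
    n_groups = codes.max() + 1
    n_i = np.bincount(codes, minlength=n_groups).astype(float)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y
    Sx = np.zeros((n_groups, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)

    def objective(log_theta):
        return _profile(np.exp(log_theta), n_i, XtX, Xty, yty, Sx, Sy,
                        n, p, reml)[0]

    res = minimize_scalar(objective, bounds=(_LOG_THETA_LO, _LOG_THETA_HI),
                          method="bounded", options={"xatol": 1e-8})
    theta = float(np.exp(res.x))
    nll = res.fun
    nll0 = _profile(0.0, n_i, XtX, Xty, yty, Sx, Sy, n, p, reml)[0]
    if nll0 <= nll:
        theta, nll = 0.0, nll0
    _, beta, sigma2, A = _profile(theta, n_i, XtX, Xty, yty, Sx, Sy, n, p, reml)
    cov_beta = sigma2 * np.linalg.inv(A)
    return RandomInterceptFit(
        beta=beta, cov_beta=cov_beta,
        sigma2_b=theta * sigma2, sigma2_e=sigma2,
        llf=-nll, reml=reml, n_obs=n, n_groups=int(n_groups),
        df_resid=n - p,
        exog_names=list(exog_names) if exog_names is not None
        else [f"x{j}" for j in range(p)],
        _X=X, _group_codes=codes)


def pd_factorize(values):
    """Stable integer codes for group labels (first-appearance order)."""
    import pandas as pd
    codes, uniques = pd.factorize(np.asarray(values))
    if (codes < 0).any():
        raise ValueError("group labels must not be missing")
    return codes, uniques
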