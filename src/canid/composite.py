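"""Composite (task-level and overall) cognitive scores.

The scoring model is fitted once on baseline data and then applied,
frozen, to data from any timepoint:

1. task-level PCA — first principal component of the Spatial Reversal
   triple (blocks completed, longest block, trials remaining) and of the
   five Delayed Search proportions, on the correlation scale (inputs
   standardized before rotation).  The Cylinder score is its single
   proportion.
2. Yeo-Johnson transformation of the Spatial Reversal and Delayed Search
   component scores (maximum-likelihood lambda on baseline) to normalize
   their skewed distributions.
3. z-standardization of all three task scores by baseline mean/SD.
4. overall PCA — first component of the three standardized task scores,
   z-standardized again; this is the overall battery score.

Missing data: Delayed Search trial-type proportions missing because the
dog made no choice are filled by predictive mean matching against the
baseline complete-case pool; a dog missing exactly one task score has it
imputed by a deterministic linear regression on the two observed task
scores and test location; dogs missing more than one task get no overall
score.

Component signs are fixed so that higher scores mean better performance
(blocks-completed / no-delay loadings positive; all tasks load positively
on the overall component).  Retest data are projected through the stored
baseline centers, scales, rotations, lambdas and standardization
constants — nothing is ever refitted on follow-up data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import data_model as dm
from .errors import FittingError, NotFittedError, ValidationError

logger = logging.getLogger(__name__)

TASKS = ("sr", "ds", "cyl")
_TASK_INPUTS = {"sr": list(dm.SR_MEASURE_COLUMNS), "ds": list(dm.DS_PROP_COLUMNS)}
#: variable whose loading is forced positive, per task
_ORIENT_VAR = {"sr": "sr_blocks", "ds": "ds_p_nodelay"}

MIN_PCA_CASES = 10


# ---------------------------------------------------------------------------
# First principal component on the correlation scale
# ---------------------------------------------------------------------------

@dataclass
class PC1Model:
    """Frozen first principal component of standardized inputs."""

    input_names: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # unit-norm eigenvector, orientation applied
    explained_var_ratio: float

    def scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.center) / self.scale
        return Z @ self.loadings

    def to_dict(self):
        d = asdict(self)
        for k in ("center", "scale", "loadings"):
            d[k] = list(map(float, d[k]))
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(input_names=list(d["input_names"]),
                   center=np.asarray(d["center"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   loadings=np.asarray(d["loadings"], dtype=float),
                   explained_var_ratio=float(d["explained_var_ratio"]))


def fit_pc1(X, input_names, orient_index=None) -> PC1Model:
    """Fit PC1 of the correlation matrix of ``X``.

    The eigenvector sign is arbitrary; it is resolved so that the loading at
    ``orient_index`` is positive, or — when ``orient_index`` is None — so
    that the loadings sum is positive (used for the overall component where
    every task is expected to load positively).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise FittingError("need at least 3 complete cases for a PCA")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        j = int(np.argmin(scale))
        raise FittingError(f"input {input_names[j]!r} is constant; "
                           "correlation-scale PCA undefined")
    Z = (X - center) / scale
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if orient_index is None:
        if v.sum() < 0:
            v = -v
        if np.any(v < 0):
            logger.warning("overall component has mixed-sign loadings: %s",
                           np.round(v, 3))
    elif v[orient_index] < 0:
        v = -v
    return PC1Model(input_names=list(input_names), center=center, scale=scale,
                    loadings=v,
                    explained_var_ratio=float(eigvals[-1] / eigvals.sum()))


def fit_task_pca(measures: pd.DataFrame, task: str) -> PC1Model:
    """Fit the PCA behind one task's summary score on baseline measures."""
    if task not in _TASK_INPUTS:
        raise ValueError(f"task must be one of {tuple(_TASK_INPUTS)}, got {task!r}")
    cols = _TASK_INPUTS[task]
    complete = measures.dropna(subset=cols)
    if len(complete) < MIN_PCA_CASES:
        raise FittingError(
            f"need >= {MIN_PCA_CASES} complete cases to fit the {task} PCA, "
            f"got {len(complete)}")
    return fit_pc1(complete[cols].to_numpy(), cols,
                   orient_index=cols.index(_ORIENT_VAR[task]))


def fit_overall_pca(task_scores: pd.DataFrame) -> PC1Model:
    """Fit the overall component on complete standardized task-score triples."""
    cols = list(TASKS)
    complete = task_scores.dropna(subset=cols)
    if len(complete) < 3:
        raise FittingError("need >= 3 complete task-score triples")
    return fit_pc1(complete[cols].to_numpy(), cols, orient_index=None)


# ---------------------------------------------------------------------------
# Yeo-Johnson + standardization
# ---------------------------------------------------------------------------

_GOLDEN = (np.sqrt(5) - 1) / 2


def fit_yeo_johnson_lambda(x, bounds=(-3.0, 3.0), grid=61, tol=1e-6) -> float:
    """Maximum-likelihood Yeo-Johnson lambda.

    A coarse grid over ``bounds`` locates the basin; golden-section search
    refines it to ``tol``.  Keeping the optimizer this explicit makes the
    fitted lambdas reproducible across platforms.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input to Yeo-Johnson fit")
    lams = np.linspace(bounds[0], bounds[1], grid)
    llf = np.array([stats.yeojohnson_llf(l, x) for l in lams])
    j = int(np.argmax(llf))
    lo = lams[max(j - 1, 0)]
    hi = lams[min(j + 1, grid - 1)]
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = -stats.yeojohnson_llf(c, x)
    fd = -stats.yeojohnson_llf(d, x)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = -stats.yeojohnson_llf(c, x)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = -stats.yeojohnson_llf(d, x)
    return float((a + b) / 2)


def yeo_johnson(x, lam: float) -> np.ndarray:
    """Apply the Yeo-Johnson transform with a fixed lambda."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    m = np.isfinite(x)
    if m.any():
        out[m] = stats.yeojohnson(x[m], lmbda=lam)
    return out


@dataclass
class TransformParams:
    """Frozen Yeo-Johnson lambdas and baseline standardization constants."""

    yj_lambda_sr: float = None
    yj_lambda_ds: float = None
    mean: dict = None      # per task + "overall"
    sd: dict = None

    def to_dict(self):
        return {"yj_lambda_sr": self.yj_lambda_sr,
                "yj_lambda_ds": self.yj_lambda_ds,
                "mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d):
        return cls(yj_lambda_sr=d["yj_lambda_sr"], yj_lambda_ds=d["yj_lambda_ds"],
                   mean=dict(d["mean"]), sd=dict(d["sd"]))


def transform_and_standardize(task_scores: pd.DataFrame,
                              params: TransformParams = None,
                              fit: bool = False):
    """Yeo-Johnson (SR, DS) then z-standardize all three task scores.

    In fitting mode, lambdas and mean/SD constants are estimated from the
    given (baseline) data and returned with the transformed scores; in
    application mode the stored constants are applied unchanged.
    """
    out = task_scores.copy()
    for col in TASKS:
        vals = out[col].to_numpy(dtype=float)
        bad = np.isinf(vals)
        if bad.any():
            raise ValueError(f"non-finite {col} score at row "
                             f"{int(np.flatnonzero(bad)[0])}")
    if fit:
        params = TransformParams(mean={}, sd={})
        params.yj_lambda_sr = fit_yeo_johnson_lambda(out["sr"].dropna())
        params.yj_lambda_ds = fit_yeo_johnson_lambda(out["ds"].dropna())
    elif params is None:
        raise ValueError("application mode requires fitted params")
    out["sr"] = yeo_johnson(out["sr"], params.yj_lambda_sr)
    out["ds"] = yeo_johnson(out["ds"], params.yj_lambda_ds)
    for col in TASKS:
        if fit:
            obs = out[col].dropna()
            params.mean[col] = float(obs.mean())
            params.sd[col] = float(obs.std(ddof=1))
        out[col] = (out[col] - params.mean[col]) / params.sd[col]
    return (out, params) if fit else out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationModel:
    """Deterministic 'norm.predict' regressions for single-task gaps.

    One linear model per task: the task's standardized score regressed on
    the two observed task scores plus test-location indicators (reference
    ACCC), fitted on baseline complete cases.  Prediction has no noise term.
    """

    coefs: dict  # task -> {name: value}; names: intercept, other tasks, loc_*

    _LOC_DUMMIES = ("loc_CC", "loc_SSP")

    @staticmethod
    def _design_row(row, others):
        x = [1.0] + [row[o] for o in others]
        x += [1.0 if row["location"] == "CC" else 0.0,
              1.0 if row["location"] == "SSP" else 0.0]
        return np.array(x)

    @classmethod
    def fit(cls, task_scores: pd.DataFrame) -> "ImputationModel":
        complete = task_scores.dropna(subset=list(TASKS))
        if len(complete) < 6:
            raise FittingError("need >= 6 complete triples to fit imputation")
        coefs = {}
        for task in TASKS:
            others = [t for t in TASKS if t != task]
            X = np.stack([cls._design_row(r, others)
                          for _, r in complete.iterrows()])
            y = complete[task].to_numpy(dtype=float)
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            names = ["intercept"] + others + list(cls._LOC_DUMMIES)
            coefs[task] = dict(zip(names, map(float, b)))
        return cls(coefs=coefs)

    def predict(self, task: str, row) -> float:
        others = [t for t in TASKS if t != task]
        x = self._design_row(row, others)
        b = self.coefs[task]
        names = ["intercept"] + others + list(self._LOC_DUMMIES)
        return float(x @ np.array([b[n] for n in names]))

    def to_dict(self):
        return {"coefs": {t: dict(c) for t, c in self.coefs.items()}}

    @classmethod
    def from_dict(cls, d):
        return cls(coefs={t: dict(c) for t, c in d["coefs"].items()})


def impute_task_score(model: ImputationModel, row: dict) -> tuple:
    """Complete a task-score triple with exactly one missing entry.

    Returns ``(completed_row, imputed_task)``; ``imputed_task`` is None when
    nothing was missing.  Rows missing two or more scores raise
    :class:`ValidationError` — the caller leaves those without an overall
    score.
    """
    missing = [t for t in TASKS if pd.isna(row[t])]
    if not missing:
        return dict(row), None
    if len(missing) >= 2:
        raise ValidationError("cannot impute a row missing 2+ task scores",
                              dog_id=row.get("dog_id"),
                              timepoint=row.get("timepoint"))
    task = missing[0]
    out = dict(row)
    out[task] = model.predict(task, row)
    return out, task


def impute_ds_trial_proportions(props, pool: pd.DataFrame, k: int = 5,
                                rng: np.random.Generator = None):
    """Predictive mean matching for missing Delayed Search proportions.

    For each missing trial-type proportion, a linear regression of that type
    on the row's observed types is fitted over the complete-case baseline
    ``pool``; the ``k`` donors whose predicted values are nearest the row's
    prediction are found, one is drawn with ``rng``, and that donor's
    *observed* value is copied in.  Imputed values therefore always lie in
    the support of the observed data.
    """
    if rng is None:
        rng = np.random.default_rng()
    cols = list(dm.DS_PROP_COLUMNS)
    vec = np.array([props[c] for c in cols], dtype=float)
    missing = [i for i in range(5) if np.isnan(vec[i])]
    if not missing:
        return {c: vec[i] for i, c in enumerate(cols)}
    observed = [i for i in range(5) if not np.isnan(vec[i])]
    if not observed:
        raise ValidationError("cannot impute a row with no observed proportions")
    donors = pool.dropna(subset=cols)
    if len(donors) == 0:
        raise FittingError("empty donor pool for predictive mean matching")
    D = donors[cols].to_numpy(dtype=float)
    for j in missing:
        Xd = np.column_stack([np.ones(len(D))] + [D[:, i] for i in observed])
        yd = D[:, j]
        b, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        pred_d = Xd @ b
        pred_r = b[0] + sum(b[m + 1] * vec[i] for m, i in enumerate(observed))
        order = np.argsort(np.abs(pred_d - pred_r), kind="stable")
        nearest = order[:min(k, len(order))]
        vec[j] = yd[rng.choice(nearest)]
    return {c: vec[i] for i, c in enumerate(cols)}


# ---------------------------------------------------------------------------
# The frozen scoring model
# ---------------------------------------------------------------------------

class CanidScorer(BaseEstimator, TransformerMixin):
    """Baseline-fitted battery scoring model.

    ``fit`` takes the baseline measures table (merged with session
    covariates: ``test_age_years``, ``sex``, ``location``); ``transform``
    maps a measures table from any timepoint to the long score table.
    Projection applies only stored constants, so
    ``transform(baseline) == fitted baseline scores`` exactly.

    Parameters
    ----------
    n_donors : int
        Donor-pool size for predictive mean matching (default 5).
    random_state : int or None
        Seed for the PMM donor draw.  Draws are keyed per (dog, timepoint,
        trial type), so scoring is deterministic and independent of row
        order.
    """

    _REQUIRED = ["dog_id", "timepoint", "test_age_years", "sex", "location"] \
        + list(dm.SR_MEASURE_COLUMNS) + list(dm.DS_PROP_COLUMNS) + ["cyl_prop"]

    def __init__(self, n_donors: int = 5, random_state=None):
        self.n_donors = n_donors
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        df = self._check_input(X)
        self.ds_pool_ = df.dropna(subset=list(dm.DS_PROP_COLUMNS))[
            list(dm.DS_PROP_COLUMNS)].reset_index(drop=True)
        completed = self._complete_ds(df)
        self.sr_pca_ = fit_task_pca(completed, "sr")
        self.ds_pca_ = fit_task_pca(completed, "ds")
        raw = self._raw_task_scores(completed)
        std, self.transforms_ = transform_and_standardize(raw, fit=True)
        self.imputation_ = ImputationModel.fit(std)
        triples = self._fill_single_gaps(std)[0]
        self.overall_pca_ = fit_overall_pca(triples)
        complete = triples.dropna(subset=list(TASKS))
        overall_raw = self.overall_pca_.scores(complete[list(TASKS)].to_numpy())
        self.transforms_.mean["overall"] = float(np.mean(overall_raw))
        self.transforms_.sd["overall"] = float(np.std(overall_raw, ddof=1))
        self.fingerprint_ = self._fingerprint(df)
        return self

    # -- application ------------------------------------------------------

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        df = self._check_input(X)
        completed = self._complete_ds(df)
        ds_pmm_flag = completed.pop("_ds_pmm")
        raw = self._raw_task_scores(completed)
        std = transform_and_standardize(raw, self.transforms_)
        triples, imputed_tasks = self._fill_single_gaps(std)
        obs = triples[list(TASKS)].to_numpy(dtype=float)
        overall = np.full(len(triples), np.nan)
        complete_mask = ~np.isnan(obs).any(axis=1)
        if complete_mask.any():
            raw_overall = self.overall_pca_.scores(obs[complete_mask])
            overall[complete_mask] = (
                (raw_overall - self.transforms_.mean["overall"])
                / self.transforms_.sd["overall"])
        out = pd.DataFrame({
            "dog_id": df["dog_id"].to_numpy(),
            "timepoint": df["timepoint"].to_numpy(),
            "test_age_years": df["test_age_years"].to_numpy(dtype=float),
            "sex": df["sex"].to_numpy(),
            "location": df["location"].to_numpy(),
            "sr_score": triples["sr"].to_numpy(dtype=float),
            "ds_score": triples["ds"].to_numpy(dtype=float),
            "cyl_score": triples["cyl"].to_numpy(dtype=float),
            "overall_score": overall,
            "sr_imputed": [t == "sr" for t in imputed_tasks],
            "ds_imputed": [t == "ds" or f
                           for t, f in zip(imputed_tasks, ds_pmm_flag)],
            "cyl_imputed": [t == "cyl" for t in imputed_tasks],
        }, columns=list(dm.SCORES_COLUMNS))
        return out

    # -- internals --------------------------------------------------------

    def _check_input(self, X):
        missing = [c for c in self._REQUIRED if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks column(s) {', '.join(missing)}")
        return X.reset_index(drop=True)

    def _check_fitted(self):
        if not hasattr(self, "overall_pca_"):
            raise NotFittedError("CanidScorer must be fitted before projection")

    def _pmm_rng(self, dog_id, timepoint):
        base = 0 if self.random_state is None else int(self.random_state)
        key = f"{base}|{dog_id}|{timepoint}".encode()
        return np.random.default_rng(zlib.crc32(key))

    def _complete_ds(self, df):
        """Fill missing DS proportions by PMM where at least one is observed."""
        cols = list(dm.DS_PROP_COLUMNS)
        out = df.copy()
        flags = []
        for i, row in out.iterrows():
            vals = row[cols].to_numpy(dtype=float)
            n_miss = int(np.isnan(vals).sum())
            if n_miss == 0 or n_miss == 5:
                flags.append(False)
                continue
            filled = impute_ds_trial_proportions(
                {c: row[c] for c in cols}, self.ds_pool_, k=self.n_donors,
                rng=self._pmm_rng(row["dog_id"], row["timepoint"]))
            for c in cols:
                out.at[i, c] = filled[c]
            flags.append(True)
        out["_ds_pmm"] = flags
        return out

    def _raw_task_scores(self, df):
        sr = np.full(len(df), np.nan)
        ds = np.full(len(df), np.nan)
        sr_in = df[list(dm.SR_MEASURE_COLUMNS)].to_numpy(dtype=float)
        ds_in = df[list(dm.DS_PROP_COLUMNS)].to_numpy(dtype=float)
        m = ~np.isnan(sr_in).any(axis=1)
        if m.any():
            sr[m] = self.sr_pca_.scores(sr_in[m])
        m = ~np.isnan(ds_in).any(axis=1)
        if m.any():
            ds[m] = self.ds_pca_.scores(ds_in[m])
        return pd.DataFrame({"sr": sr, "ds": ds,
                             "cyl": df["cyl_prop"].to_numpy(dtype=float),
                             "location": df["location"].to_numpy()})

    def _fill_single_gaps(self, std):
        out = std.copy()
        imputed = []
        for i, row in out.iterrows():
            n_miss = int(row[list(TASKS)].isna().sum())
            if n_miss == 1:
                filled, task = impute_task_score(self.imputation_, row.to_dict())
                for t in TASKS:
                    out.at[i, t] = filled[t]
                imputed.append(task)
            else:
                imputed.append(None)
        return out, imputed

    @staticmethod
    def _fingerprint(df):
        cols = (["dog_id", "timepoint"] + list(dm.SR_MEASURE_COLUMNS)
                + list(dm.DS_PROP_COLUMNS) + ["cyl_prop"])
        payload = df[cols].sort_values(["dog_id", "timepoint"]) \
            .to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- persistence ------------------------------------------------------

    def to_json(self, path=None):
        self._check_fitted()
        doc = {
            "format": "canid-scoring-model-v1",
            "n_donors": self.n_donors,
            "random_state": self.random_state,
            "sr_pca": self.sr_pca_.to_dict(),
            "ds_pca": self.ds_pca_.to_dict(),
            "overall_pca": self.overall_pca_.to_dict(),
            "transforms": self.transforms_.to_dict(),
            "imputation": self.imputation_.to_dict(),
            "ds_pool": self.ds_pool_.to_dict(orient="list"),
            "fingerprint": self.fingerprint_,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        if doc.get("format") != "canid-scoring-model-v1":
            raise ValueError("not a scoring-model document")
        obj = cls(n_donors=doc["n_donors"], random_state=doc["random_state"])
        obj.sr_pca_ = PC1Model.from_dict(doc["sr_pca"])
        obj.ds_pca_ = PC1Model.from_dict(doc["ds_pca"])
        obj.overall_pca_ = PC1Model.from_dict(doc["overall_pca"])
        obj.transforms_ = TransformParams.from_dict(doc["transforms"])
        obj.imputation_ = ImputationModel.from_dict(doc["imputation"])
        obj.ds_pool_ = pd.DataFrame(doc["ds_pool"],
                                    columns=list(dm.DS_PROP_COLUMNS))
        obj.fingerprint_ = doc["fingerprint"]
        return obj


def project(model: CanidScorer, sessions: pd.DataFrame) -> pd.DataFrame:
    """Project scored measures from any timepoint through a fitted model."""
    return model.transform(sessions)
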