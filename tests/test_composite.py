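import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import PowerTransformer, StandardScaler

from canid import composite as cp
from canid import data_model as dm
from canid.errors import FittingError, NotFittedError, ValidationError


# ---------------------------------------------------------------------------
# PC1 on the correlation scale
# ---------------------------------------------------------------------------

class TestPC1:
    def _random_X(self, rng, n=200, p=4):
        A = rng.normal(size=(p, p))
        return rng.normal(size=(n, p)) @ A

    def test_matches_sklearn_pca_on_standardized_data(self, rng):
        X = self._random_X(rng)
        model = cp.fit_pc1(X, [f"v{i}" for i in range(4)], orient_index=0)
        Z = StandardScaler().fit_transform(X) \
            * np.sqrt(len(X) / (len(X) - 1.0))
        ref = PCA(n_components=1).fit(Z)
        v = ref.components_[0]
        if v[0] < 0:
            v = -v
        np.testing.assert_allclose(np.abs(model.loadings), np.abs(v),
                                   atol=1e-8)
        np.testing.assert_allclose(model.explained_var_ratio,
                                   ref.explained_variance_ratio_[0],
                                   atol=1e-8)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = self._random_X(rng)
        model = cp.fit_pc1(X, list("abcd"), orient_index=2)
        # oracle: direct eigendecomposition of np.corrcoef
        w, V = np.linalg.eigh(np.corrcoef(X, rowvar=False))
        v = V[:, np.argmax(w)]
        if v[2] < 0:
            v = -v
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(model.scores(X), Z @ v, atol=1e-8)

    def test_perfectly_collinear_inputs(self):
        x = np.linspace(-2, 2, 50)
        X = np.column_stack([x, 2 * x + 1, -3 * x])
        model = cp.fit_pc1(X, list("abc"), orient_index=0)
        assert model.explained_var_ratio == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(model.loadings),
                                   np.full(3, 1 / np.sqrt(3)), atol=1e-8)
        assert model.loadings[0] > 0 and model.loadings[1] > 0
        assert model.loadings[2] < 0  # negated input loads negatively

    def test_orientation_flag_forces_positive_loading(self, rng):
        X = self._random_X(rng)
        for j in range(4):
            model = cp.fit_pc1(X, list("abcd"), orient_index=j)
            assert model.loadings[j] > 0

    def test_constant_input_rejected_with_name(self, rng):
        X = self._random_X(rng)
        X[:, 1] = 5.0
        with pytest.raises(FittingError, match="v1"):
            cp.fit_pc1(X, [f"v{i}" for i in range(4)], orient_index=0)

    def test_isotropic_noise_explains_about_one_quarter(self, rng):
        X = rng.normal(size=(4000, 4))
        model = cp.fit_pc1(X, list("abcd"), orient_index=None)
        assert model.explained_var_ratio == pytest.approx(0.25, abs=0.05)

    def test_rank_one_structure_explains_everything(self, rng):
        f = rng.normal(size=500)
        X = np.outer(f, [1.0, 0.8, 1.2]) + rng.normal(scale=1e-8,
                                                      size=(500, 3))
        model = cp.fit_pc1(X, list("abc"), orient_index=None)
        assert model.explained_var_ratio > 0.999
        assert np.all(model.loadings > 0)


# ---------------------------------------------------------------------------
# Yeo-Johnson
# ---------------------------------------------------------------------------

class TestYeoJohnson:
    def test_lambda_one_is_identity(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_allclose(cp.yeo_johnson(x, 1.0), x, atol=1e-12)

    def test_symmetric_data_fits_lambda_near_one(self, rng):
        x = rng.normal(0, 1, 4000)
        lam = cp.fit_yeo_johnson_lambda(x)
        assert lam == pytest.approx(1.0, abs=0.1)

    def test_matches_scipy_mle(self, rng):
        x = rng.gamma(2.0, 1.0, 500) - 1.0
        lam = cp.fit_yeo_johnson_lambda(x)
        _, lam_ref = stats.yeojohnson(x)
        assert lam == pytest.approx(lam_ref, abs=1e-4)

    def test_matches_sklearn_power_transformer(self, rng):
        x = rng.exponential(1.0, 400)
        lam = cp.fit_yeo_johnson_lambda(x)
        pt = PowerTransformer(method="yeo-johnson",
                              standardize=False).fit(x[:, None])
        assert lam == pytest.approx(float(pt.lambdas_[0]), abs=1e-3)

    def test_reduces_skew_of_skewed_data(self, rng):
        x = rng.exponential(1.0, 1000)
        lam = cp.fit_yeo_johnson_lambda(x)
        y = cp.yeo_johnson(x, lam)
        assert abs(stats.skew(y)) < abs(stats.skew(x)) / 3

    def test_monotone_and_nan_passthrough(self, rng):
        x = np.sort(rng.normal(size=50))
        for lam in (-2.0, -0.5, 0.0, 0.7, 2.5):
            y = cp.yeo_johnson(x, lam)
            assert np.all(np.diff(y) > 0)
        y = cp.yeo_johnson(np.array([1.0, np.nan, -1.0]), 0.5)
        assert np.isnan(y[1]) and np.isfinite(y[[0, 2]]).all()


# ---------------------------------------------------------------------------
# Imputation primitives
# ---------------------------------------------------------------------------

class TestImputation:
    def _std_scores(self, rng, n=60):
        f = rng.normal(size=n)
        df = pd.DataFrame({
            "sr": f + rng.normal(0, 0.5, n),
            "ds": f + rng.normal(0, 0.5, n),
            "cyl": f + rng.normal(0, 0.5, n),
            "location": rng.choice(["ACCC", "CC", "SSP"], n),
        })
        return df

    def test_complete_row_is_a_no_op(self, rng):
        df = self._std_scores(rng)
        model = cp.ImputationModel.fit(df)
        row = df.iloc[0].to_dict()
        out, task = cp.impute_task_score(model, row)
        assert task is None and out == row

    def test_exact_linear_relation_recovered(self, rng):
        df = self._std_scores(rng)
        df["cyl"] = 0.5 * df["sr"] - 0.25 * df["ds"] + 0.1
        model = cp.ImputationModel.fit(df)
        row = {"sr": 1.0, "ds": -2.0, "cyl": np.nan, "location": "ACCC"}
        out, task = cp.impute_task_score(model, row)
        assert task == "cyl"
        assert out["cyl"] == pytest.approx(0.5 * 1.0 - 0.25 * -2.0 + 0.1,
                                           abs=1e-8)

    def test_two_missing_tasks_rejected(self, rng):
        model = cp.ImputationModel.fit(self._std_scores(rng))
        with pytest.raises(ValidationError, match="2"):
            cp.impute_task_score(model, {"sr": np.nan, "ds": np.nan,
                                         "cyl": 0.0, "location": "ACCC"})

    def test_pmm_values_come_from_donor_support(self, rng):
        pool = pd.DataFrame(
            rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(40, 5)),
            columns=list(dm.DS_PROP_COLUMNS))
        props = {c: v for c, v in zip(dm.DS_PROP_COLUMNS,
                                      [1.0, np.nan, 0.5, np.nan, 0.0])}
        out = cp.impute_ds_trial_proportions(props, pool, k=5, rng=rng)
        support = set(np.unique(pool.to_numpy()))
        for c in dm.DS_PROP_COLUMNS:
            assert out[c] in support or out[c] == props[c]
        # observed entries are untouched
        assert out["ds_p_nodelay"] == 1.0 and out["ds_p_d40x"] == 0.0

    def test_pmm_k1_equals_brute_force_nearest_donor(self, rng):
        pool = pd.DataFrame(rng.uniform(0, 1, size=(30, 5)),
                            columns=list(dm.DS_PROP_COLUMNS))
        props = {c: v for c, v in zip(
            dm.DS_PROP_COLUMNS, [0.8, 0.6, np.nan, 0.4, 0.2])}
        out = cp.impute_ds_trial_proportions(dict(props), pool, k=1, rng=rng)
        # brute-force oracle: refit the same regression and take the donor
        # with the closest predicted value
        obs = [0, 1, 3, 4]
        D = pool.to_numpy()
        Xd = np.column_stack([np.ones(30)] + [D[:, i] for i in obs])
        b, *_ = np.linalg.lstsq(Xd, D[:, 2], rcond=None)
        pred_d = Xd @ b
        pred_r = b[0] + b[1] * 0.8 + b[2] * 0.6 + b[3] * 0.4 + b[4] * 0.2
        donor = int(np.argmin(np.abs(pred_d - pred_r)))
        assert out["ds_p_d10x"] == D[donor, 2]

    def test_all_missing_rejected(self, rng):
        pool = pd.DataFrame(rng.uniform(0, 1, size=(30, 5)),
                            columns=list(dm.DS_PROP_COLUMNS))
        with pytest.raises(ValidationError):
            cp.impute_ds_trial_proportions(
                {c: np.nan for c in dm.DS_PROP_COLUMNS}, pool, rng=rng)


# ---------------------------------------------------------------------------
# The frozen scorer
# ---------------------------------------------------------------------------

class TestCanidScorer:
    def test_unfitted_transform_raises(self, merged):
        with pytest.raises(NotFittedError):
            cp.CanidScorer().transform(merged)

    def test_baseline_scores_are_standardized(self, scores):
        base = scores[scores["timepoint"] == "baseline"]
        for col in ("sr_score", "ds_score", "cyl_score", "overall_score"):
            obs = base[col].dropna()
            assert abs(obs.mean()) < 0.25
            assert obs.std(ddof=1) == pytest.approx(1.0, abs=0.25)

    def test_overall_pca_loads_all_tasks_positively(self, fitted_scorer):
        assert np.all(fitted_scorer.overall_pca_.loadings > 0)

    def test_projection_is_frozen_idempotent(self, fitted_scorer, merged):
        base = merged[merged["timepoint"] == "baseline"]
        s1 = fitted_scorer.transform(base)
        s2 = fitted_scorer.transform(base)
        pd.testing.assert_frame_equal(s1, s2)
        # row order must not matter for the deterministic PMM draws
        shuffled = base.sample(frac=1.0, random_state=5)
        s3 = fitted_scorer.transform(shuffled)
        s3 = s3.sort_values(["dog_id", "timepoint"]).reset_index(drop=True)
        s1s = s1.sort_values(["dog_id", "timepoint"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1s, s3)

    def test_projection_never_refits(self, fitted_scorer, merged):
        before = fitted_scorer.to_json()
        fitted_scorer.transform(merged)
        assert fitted_scorer.to_json() == before

    def test_overall_missing_when_two_tasks_missing(self, fitted_scorer,
                                                    merged):
        row = merged[merged["timepoint"] == "baseline"].iloc[[0]].copy()
        row[list(dm.SR_MEASURE_COLUMNS)] = np.nan
        row[list(dm.DS_PROP_COLUMNS)] = np.nan
        out = fitted_scorer.transform(row)
        assert np.isnan(out["overall_score"].iloc[0])
        assert np.isnan(out["sr_score"].iloc[0])

    def test_single_missing_task_is_imputed_and_flagged(self, fitted_scorer,
                                                        merged):
        row = merged[merged["timepoint"] == "baseline"].dropna(
            subset=list(dm.SR_MEASURE_COLUMNS)).iloc[[0]].copy()
        row[list(dm.SR_MEASURE_COLUMNS)] = np.nan
        out = fitted_scorer.transform(row)
        assert out["sr_imputed"].iloc[0]
        assert np.isfinite(out["sr_score"].iloc[0])
        assert np.isfinite(out["overall_score"].iloc[0])

    def test_score_table_satisfies_invariants(self, scores):
        dm.validate_scores(scores)
        n_tasks = scores[["sr_score", "ds_score", "cyl_score"]] \
            .notna().sum(axis=1)
        assert (scores.loc[scores["overall_score"].notna(), :].pipe(len)
                == (n_tasks >= 2)[scores["overall_score"].notna()].sum())

    def test_overall_correlates_negatively_with_age(self, scores):
        base = scores[scores["timepoint"] == "baseline"].dropna(
            subset=["overall_score"])
        r = np.corrcoef(base["test_age_years"], base["overall_score"])[0, 1]
        assert r < -0.1

    def test_json_round_trip_preserves_projection(self, fitted_scorer,
                                                  merged, tmp_path):
        path = tmp_path / "model.json"
        fitted_scorer.to_json(path)
        loaded = cp.CanidScorer.from_json(path)
        pd.testing.assert_frame_equal(loaded.transform(merged),
                                      fitted_scorer.transform(merged))
        assert loaded.fingerprint_ == fitted_scorer.fingerprint_

    def test_rejects_non_model_document(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="scoring-model"):
            cp.CanidScorer.from_json(path)

    def test_missing_column_named_in_error(self, merged):
        with pytest.raises(ValueError, match="cyl_prop"):
            cp.CanidScorer().fit(merged.drop(columns=["cyl_prop"]))

    def test_sklearn_estimator_protocol(self):
        from sklearn.base import clone
        est = cp.CanidScorer(n_donors=3, random_state=4)
        params = est.get_params()
        assert params == {"n_donors": 3, "random_state": 4}
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_project_function_equals_transform(self, fitted_scorer, merged):
        pd.testing.assert_frame_equal(
            cp.project(fitted_scorer, merged), fitted_scorer.transform(merged))
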