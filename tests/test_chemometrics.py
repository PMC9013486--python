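"""PCA-guided index subsetting, stepwise AIC, PLSR with LOOCV."""

import numpy as np
import pandas as pd
import pytest

from c4spectra.chemometrics import (
    PLSRModel,
    fit_plsr,
    loocv,
    pca_index_subset,
    predict_traits,
    r_squared,
    stepwise_aic,
)


class TestPcaIndexSubset:
    def test_perfect_duplicates_collapse_to_one(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "a_copy": a * 2.0 + 1.0, "b": rng.normal(size=50)})
        sel = pca_index_subset(df, corr_threshold=0.9).selected
        assert "b" in sel
        assert len({"a", "a_copy"} & set(sel)) == 1

    def test_orthogonal_indices_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert sorted(pca_index_subset(df).selected) == list("abcd")

    def test_three_factor_clusters_keep_one_each(self, rng):
        f = rng.normal(size=(120, 3))
        cols = {}
        for k in range(3):
            for j in range(5):
                cols[f"f{k}_{j}"] = f[:, k] * (1 + 0.1 * j) + rng.normal(size=120) * 1e-3
        res = pca_index_subset(pd.DataFrame(cols), corr_threshold=0.9)
        assert len(res.selected) == 3
        assert {name[:2] for name in res.selected} == {"f0", "f1", "f2"}

    def test_constant_index_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "k": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            res = pca_index_subset(df)
        assert res.dropped_constant == ["k"]


class TestStepwiseAic:
    def test_planted_single_predictor_recovered(self, rng):
        # AIC (k=2) admits a spurious regressor with ~16% probability per
        # candidate even as noise vanishes, so assert the recovered
        # substance: the planted term, its coefficient, and that any extra
        # terms are numerically negligible.
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = 3.0 + 2.0 * X["b"] + rng.normal(size=100) * 1e-6
        model = stepwise_aic(X, y)
        assert "b" in model.selected
        assert model.coefficients["b"] == pytest.approx(2.0, abs=1e-3)
        assert model.intercept == pytest.approx(3.0, abs=1e-3)
        for name, coef in model.coefficients.items():
            if name != "b":
                assert abs(coef) < 1e-3

    def test_null_data_selects_intercept_only(self, rng):
        # single candidate: with more, AIC's ~16%-per-candidate spurious
        # acceptance rate makes intercept-only selection a minority event
        X = pd.DataFrame({"a": rng.normal(size=200)})
        y = rng.normal(size=200)
        model = stepwise_aic(X, y)
        assert model.selected == []
        assert model.r2 == 0.0

    def test_final_aic_never_above_intercept_only(self, rng):
        import statsmodels.api as sm

        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(60, 4)), columns=list("abcd"))
            y = X["a"] * r.normal() + r.normal(size=60)
            model = stepwise_aic(X, y)
            aic0 = sm.OLS(y, np.ones((60, 1))).fit().aic
            assert model.aic <= aic0 + 1e-10

    def test_prediction_matches_fitted_equation(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = 1.0 + 0.5 * X["a"] - 2.0 * X["c"] + rng.normal(size=80) * 0.01
        model = stepwise_aic(X, y)
        pred = model.predict(X)
        assert r_squared(y, pred) > 0.99


class TestPlsr:
    def test_full_rank_equals_ols_normal_equations(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + 1.0 + rng.normal(size=30) * 0.1
        model = fit_plsr(X, y, max_latent=5, n_latent=5)
        design = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(model.predict(X), design @ beta, atol=1e-8)

    def test_rank3_response_needs_three_components(self, rng):
        S = rng.normal(size=(40, 3))
        X = S @ rng.normal(size=(3, 60))
        y = S @ np.array([2.0, -1.0, 0.5])
        model = fit_plsr(X, y, max_latent=10)
        assert model.n_latent <= 3
        assert model.cv_r2 >= 0.999

    def test_centring_invariance_to_bandwise_constant(self, rng):
        X = rng.normal(size=(25, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=25) * 0.05
        m1 = fit_plsr(X, y, max_latent=6)
        shift = rng.normal(size=12)
        m2 = fit_plsr(X + shift, y, max_latent=6)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X + shift), atol=1e-8)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20) + 5.0
        model = fit_plsr(X, y, max_latent=4)
        assert predict_traits(model, X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean()
        )

    def test_insample_predictions_from_training_matrix(self, rng):
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8)
        model = fit_plsr(X, y, max_latent=4)
        assert r_squared(y, model.predict(X)) == pytest.approx(
            model.insample_r2, abs=1e-12
        )

    def test_band_count_mismatch_rejected(self, rng):
        model = fit_plsr(rng.normal(size=(15, 6)), rng.normal(size=15), max_latent=3)
        with pytest.raises(ValueError):
            model.predict(rng.normal(size=(2, 5)))

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsr(rng.normal(size=(15, 6)), np.ones(15))

    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=20) * 0.1
        model = fit_plsr(X, y, max_latent=4)
        back = PLSRModel.from_json(model.to_json())
        np.testing.assert_allclose(model.predict(X), back.predict(X), atol=1e-12)


class TestLoocv:
    class _Linear:
        def fit(self, X, y):
            d = np.column_stack([np.ones(len(y)), X])
            self.b = np.linalg.lstsq(d, y, rcond=None)[0]
            return self

        def predict(self, X):
            return np.column_stack([np.ones(X.shape[0]), X]) @ self.b

    def test_three_point_hand_oracle(self):
        """Each fold fits a line through the other two points exactly."""
        X = np.array([[0.0], [1.0], [3.0]])
        y = np.array([1.0, 2.0, 10.0])
        pred, r2, rmse, _ = loocv(self._Linear, X, y)
        # leave out i: line through the remaining two points
        expected = []
        for i in range(3):
            (x1, y1), (x2, y2) = [(X[j, 0], y[j]) for j in range(3) if j != i]
            slope = (y2 - y1) / (x2 - x1)
            expected.append(y1 + slope * (X[i, 0] - x1))
        np.testing.assert_allclose(pred, expected, atol=1e-10)

    def test_perfect_linear_data(self):
        X = np.arange(10.0)[:, None]
        y = 2.0 * X.ravel() + 1.0
        pred, r2, rmse, rmse_pct = loocv(self._Linear, X, y)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_prediction_vector_in_input_order(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        pred, *_ = loocv(self._Linear, X, y)
        assert pred.shape == (8,)
        assert np.isfinite(pred).all()
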