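import numpy as np
import pandas as pd
import pytest

from lipochemo.pls import (PLSRegression, pls_fit, pls_predict, q2_loo,
                           validation_stats)


def _simple_regression_predictions(x, y):
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return y.mean() + slope * (x - x.mean())


class TestPLSFit:
    def test_noiseless_single_descriptor_one_lv(self, rng):
        x = rng.normal(size=15)
        y = 2.0 * x + 1.0
        model = pls_fit(x[:, None], y, 1)
        resid = y - pls_predict(model, x[:, None])
        assert np.abs(resid).max() < 1e-10

    def test_one_lv_single_descriptor_equals_simple_regression(self, rng):
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        model = pls_fit(x[:, None], y, 1)
        np.testing.assert_allclose(pls_predict(model, x[:, None]),
                                   _simple_regression_predictions(x, y),
                                   atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = pls_fit(X, y, 4)
        Z = np.column_stack([np.ones(20), X])
        ols = Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(pls_predict(model, X), ols, atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = pls_fit(X, y, 3)
        b = pls_fit(X[perm], y[perm], 3)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-10)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-10)

    def test_matches_sklearn_predictions(self, rng):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(25, 8))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(size=25) * 0.2
        ours = pls_fit(X, y, 3)
        ref = skpls.PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(pls_predict(ours, X),
                                   ref.predict(X).ravel(), atol=1e-8)

    def test_zero_variance_descriptor_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            pls_fit(X, rng.normal(size=10), 1)

    def test_components_beyond_rank_rejected(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x])  # rank 1 after centering
        with pytest.raises(ValueError):
            pls_fit(X, rng.normal(size=10), 2)


class TestPLSPredict:
    def test_training_mean_row_predicts_training_mean(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        model = pls_fit(X, y, 2)
        pred = pls_predict(model, X.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_shifted_inputs_shift_predictions_linearly(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        model = pls_fit(X, y, 2)
        shift = np.array([1.0, -0.5, 2.0])
        delta = pls_predict(model, X + shift) - pls_predict(model, X)
        np.testing.assert_allclose(delta, np.full(15, model.coef_ @ shift),
                                   atol=1e-10)

    def test_missing_descriptor_column_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        model = pls_fit(X, rng.normal(size=12), 2)
        with pytest.raises(ValueError, match="'b'"):
            pls_predict(model, X[["a", "c"]])


class TestQ2Loo:
    def test_perfect_linear_data(self, rng):
        X = rng.normal(size=(10, 2))
        y = X @ np.array([1.5, -2.0]) + 0.3
        q2, rmse = q2_loo(X, y, 2)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert rmse == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_n4_single_descriptor(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([0.1, 0.9, 2.2, 3.9])
        press = 0.0
        for i in range(4):
            mask = np.arange(4) != i
            xm, ym = x[mask], y[mask]
            slope = np.cov(xm, ym, ddof=1)[0, 1] / np.var(xm, ddof=1)
            pred = ym.mean() + slope * (x[i] - xm.mean())
            press += (pred - y[i]) ** 2
        q2, rmse = q2_loo(x[:, None], y, 1)
        tss = ((y - y.mean()) ** 2).sum()
        assert q2 == pytest.approx(1 - press / tss, abs=1e-10)
        assert rmse == pytest.approx(np.sqrt(press / 4), abs=1e-10)

    def test_pure_noise_rarely_predictive(self):
        low = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            q2, _ = q2_loo(X, y, 2)
            low += q2 < 0.3
        assert low >= 95


def _stats_oracle(yt, pt, ye, pe):
    """Independent transcription of the validation formulas."""
    n_tr, n_ext = len(yt), len(ye)
    r2 = 1 - np.sum((yt - pt) ** 2) / np.sum((yt - np.mean(yt)) ** 2)
    q2f1 = 1 - np.sum((ye - pe) ** 2) / np.sum((ye - np.mean(yt)) ** 2)
    q2f2 = 1 - np.sum((ye - pe) ** 2) / np.sum((ye - np.mean(ye)) ** 2)
    q2f3 = 1 - (np.sum((ye - pe) ** 2) / n_ext) / (
        np.sum((yt - np.mean(yt)) ** 2) / n_tr)
    rmsep = np.sqrt(np.sum((ye - pe) ** 2) / n_ext)
    ccc = 2 * np.sum((ye - ye.mean()) * (pe - pe.mean())) / (
        np.sum((ye - ye.mean()) ** 2) + np.sum((pe - pe.mean()) ** 2)
        + n_ext * (ye.mean() - pe.mean()) ** 2)
    return r2, q2f1, q2f2, q2f3, rmsep, ccc


class TestValidationStats:
    def test_random_vectors_match_formula_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            yt, pt = rng.normal(size=10), rng.normal(size=10)
            ye, pe = rng.normal(size=10), rng.normal(size=10)
            s = validation_stats(yt, pt, ye, pe)
            r2, q2f1, q2f2, q2f3, rmsep, ccc = _stats_oracle(yt, pt, ye, pe)
            assert s.r2 == pytest.approx(r2, abs=1e-10)
            assert s.q2_f1 == pytest.approx(q2f1, abs=1e-10)
            assert s.q2_f2 == pytest.approx(q2f2, abs=1e-10)
            assert s.q2_f3 == pytest.approx(q2f3, abs=1e-10)
            assert s.rmse_p == pytest.approx(rmsep, abs=1e-10)
            assert s.ccc == pytest.approx(ccc, abs=1e-10)

    def test_perfect_external_predictions(self, rng):
        yt = rng.normal(size=8)
        ye = rng.normal(size=5)
        s = validation_stats(yt, yt, ye, ye)
        for v in (s.q2_f1, s.q2_f2, s.q2_f3, s.ccc, s.r2):
            assert v == pytest.approx(1.0)
        assert s.rmse_p == pytest.approx(0.0)

    def test_mean_prediction_zeroes_q2f2(self, rng):
        yt = rng.normal(size=8)
        ye = rng.normal(size=6)
        s = validation_stats(yt, yt, ye, np.full(6, ye.mean()))
        assert s.q2_f2 == pytest.approx(0.0, abs=1e-12)

    def test_q2f1_dominates_q2f2(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            yt, pt = rng.normal(size=9), rng.normal(size=9)
            ye, pe = rng.normal(loc=0.5, size=7), rng.normal(size=7)
            s = validation_stats(yt, pt, ye, pe)
            assert s.q2_f1 >= s.q2_f2 - 1e-12

    def test_ccc_is_one_only_for_exact_agreement(self, rng):
        ye = rng.normal(size=9)
        yt = rng.normal(size=9)
        exact = validation_stats(yt, yt, ye, ye)
        assert exact.ccc == pytest.approx(1.0)
        off = validation_stats(yt, yt, ye, ye + 0.1)
        assert off.ccc < 1.0

    def test_degenerate_denominator_flagged_not_infinite(self):
        yt = np.array([1.0, 1.0, 1.0])
        s = validation_stats(yt, yt, np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert "r2" in s.undefined
        assert np.isnan(s.r2)


class TestModelInterface:
    def test_results_object_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() * 2 + rng.normal(size=20) * 0.1
        res = PLSRegression(X, y, n_components=2).fit()
        assert res.rsquared > 0.9
        q2, rmse_cv = res.loo()
        assert q2 <= 1.0 and rmse_cv >= 0.0
        assert "(intercept)" in res.params.index
        assert "R2" in res.summary()
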