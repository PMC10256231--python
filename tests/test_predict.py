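"""Feature selectors, learners and the repeated cross-validation protocol."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.model_selection import KFold

from fieldomics import predict

warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    n, p = 62, 60
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"g{i}" for i in range(p)])
    y = 2 * X["g3"].to_numpy() + 1.5 * X["g7"].to_numpy() - X["g11"].to_numpy()
    y = y + 0.3 * rng.standard_normal(n)
    return X, y


class TestMedianSelector:
    def test_all_positive_kept(self):
        X = pd.DataFrame(np.full((10, 4), 2.0))
        assert len(predict.select_median_expressed(X)) == 4

    def test_median_midpoint_convention(self):
        # even n: feature positive in exactly half the samples, midpoint > 0
        col = np.array([-1.0, -2.0, 3.0, 4.0])  # median = 0.5 > 0
        X = pd.DataFrame({"keep": col, "drop": -col})
        kept = predict.select_median_expressed(X)
        assert list(kept) == ["keep"]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no features"):
            predict.select_median_expressed(pd.DataFrame(np.full((5, 3), -1.0)))


class TestSpearmanSelector:
    def test_monotone_feature_selected_first(self, rng):
        n = 40
        x = rng.standard_normal(n)
        X = pd.DataFrame({"signal": x, "noise1": rng.standard_normal(n),
                          "noise2": rng.standard_normal(n)})
        y = np.exp(x)  # monotone but nonlinear
        kept = predict.select_spearman(X, y)
        assert "signal" in kept

    def test_pure_noise_usually_falls_back_or_errors(self, rng):
        n = 56
        X = pd.DataFrame(rng.standard_normal((n, 40)))
        y = rng.standard_normal(n)
        try:
            kept = predict.select_spearman(X, y)
            assert len(kept) <= 5
        except ValueError:
            pass  # nothing survived the fallback either

    def test_tied_values_use_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        y = np.arange(8.0)
        X = pd.DataFrame({"g": x})
        _, p = predict._spearman_pvalues(X.to_numpy(), y)
        rho_ref = stats.spearmanr(x, y).statistic
        rho, _ = predict._spearman_pvalues(X.to_numpy(), y)
        assert rho[0] == pytest.approx(rho_ref)

    def test_deterministic(self, linear_data):
        X, y = linear_data
        a = predict.select_spearman(X, y)
        b = predict.select_spearman(X, y)
        assert list(a) == list(b)


class TestHsicLasso:
    def test_score_equals_brute_force_trace(self, rng):
        """HSIC estimate matches an explicit double-loop computation."""
        n = 6
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = rng.standard_normal(n)
        scores = predict.hsic_scores(X, y)

        def gram(v):
            v = (v - v.mean()) / v.std()
            K = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    K[i, j] = np.exp(-0.5 * (v[i] - v[j]) ** 2)
            H = np.eye(n) - np.ones((n, n)) / n
            return H @ K @ H

        Ky = gram(y)
        for col in "abc":
            Kf = gram(X[col].to_numpy())
            expected = np.trace(Kf @ Ky) / (n - 1) ** 2
            assert scores[col] == pytest.approx(expected, rel=1e-10)

    def test_nonlinear_signal_found_where_spearman_fails(self, rng):
        n = 80
        x = rng.standard_normal(n)
        X = pd.DataFrame(
            {"quad": x, **{f"n{i}": rng.standard_normal(n) for i in range(10)}}
        )
        y = x**2 + 0.1 * rng.standard_normal(n)
        kept = predict.hsic_lasso_select(X, y, max_features=3, prefilter=None)
        assert kept[0] == "quad"
        # the rank filter has no power on the symmetric quadratic
        rho = stats.spearmanr(x, y).statistic
        assert abs(rho) < 0.25

    def test_max_features_cap(self, linear_data):
        X, y = linear_data
        kept = predict.hsic_lasso_select(X, y, max_features=5, prefilter=None)
        assert 1 <= len(kept) <= 5

    def test_constant_features_excluded(self, rng):
        X = pd.DataFrame({"c": np.ones(20), "x": rng.standard_normal(20)})
        kept = predict.hsic_lasso_select(X, rng.standard_normal(20), prefilter=None)
        assert "c" not in kept

    def test_variance_prefilter_reduces_candidates(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 20)) * np.arange(1, 21))
        y = X.iloc[:, 19].to_numpy() + 0.1 * rng.standard_normal(30)
        kept = predict.hsic_lasso_select(X, y, max_features=3, prefilter=5)
        assert set(kept) <= set(X.columns[-5:])


class TestEnet:
    def test_sparse_recovery(self, rng):
        n, p = 56, 50
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[[2, 9, 17]] = [3.0, -2.0, 2.5]
        y = X @ beta + 0.2 * rng.standard_normal(n)
        Xte = rng.standard_normal((30, p))
        yte = Xte @ beta
        pred, coef = predict.fit_predict_enet(X, y, Xte, seed=0)
        from fieldomics.lme import oos_r2

        assert oos_r2(yte, pred) >= 0.95
        top3 = np.argsort(-np.abs(coef))[:3]
        assert set(top3) == {2, 9, 17}

    def test_null_response_no_out_of_sample_skill(self, rng):
        from fieldomics.lme import oos_r2

        n, p = 50, 30
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        Xte = rng.standard_normal((40, p))
        yte = rng.standard_normal(40)
        pred, coef = predict.fit_predict_enet(X, y, Xte, seed=0)
        assert oos_r2(yte, pred) <= 0.1
        # most mass stays out of the model
        assert np.mean(coef == 0) >= 0.3 or np.abs(coef).sum() < 2.0

    def test_duplicated_columns_share_weight(self, rng):
        n = 60
        x = rng.standard_normal(n)
        noise = rng.standard_normal((n, 10))
        X = np.column_stack([x, x, noise])
        y = 3.0 * x + 0.1 * rng.standard_normal(n)
        _, coef = predict.fit_predict_enet(
            X, y, X, l1_ratios=(0.5,), seed=0
        )
        # grouped shrinkage: both duplicates retained with similar weight
        assert coef[0] != 0 and coef[1] != 0
        assert coef[0] == pytest.approx(coef[1], rel=0.3)


class TestRandomForest:
    def test_step_function_importance_dominates(self, rng):
        n = 80
        x = rng.standard_normal(n)
        X = np.column_stack([x, rng.standard_normal((n, 4))])
        y = (x > 0).astype(float)
        _, imp = predict.fit_predict_rf(
            X, y, X, n_estimators=100, depth_grid=(2, 5), leaf_grid=(1,), seed=0
        )
        assert imp[0] > 0.5

    def test_oob_argmax_contract(self, rng):
        from sklearn.ensemble import RandomForestRegressor

        n = 60
        X = rng.standard_normal((n, 5))
        y = X[:, 0] + 0.5 * rng.standard_normal(n)
        depth_grid, leaf_grid = (1, 5), (1, 5)
        _, _ = predict.fit_predict_rf(
            X, y, X, n_estimators=50, depth_grid=depth_grid, leaf_grid=leaf_grid, seed=3
        )
        scores = {}
        for d in depth_grid:
            for le in leaf_grid:
                rf = RandomForestRegressor(
                    n_estimators=50, max_depth=d, min_samples_leaf=le,
                    max_features=1.0, bootstrap=True, oob_score=True,
                    random_state=3, n_jobs=1,
                ).fit(X, y)
                scores[(d, le)] = rf.oob_score_
        best = max(scores, key=scores.get)
        rf_best = RandomForestRegressor(
            n_estimators=50, max_depth=best[0], min_samples_leaf=best[1],
            max_features=1.0, bootstrap=True, oob_score=True, random_state=3, n_jobs=1,
        ).fit(X, y)
        pred_direct = rf_best.predict(X)
        pred_ours, _ = predict.fit_predict_rf(
            X, y, X, n_estimators=50, depth_grid=depth_grid, leaf_grid=leaf_grid, seed=3
        )
        np.testing.assert_allclose(pred_ours, pred_direct)

    def test_seeded_run_reproducible(self, rng):
        n = 40
        X = rng.standard_normal((n, 4))
        y = rng.standard_normal(n)
        p1, i1 = predict.fit_predict_rf(X, y, X, n_estimators=30,
                                        depth_grid=(2,), leaf_grid=(1,), seed=7)
        p2, i2 = predict.fit_predict_rf(X, y, X, n_estimators=30,
                                        depth_grid=(2,), leaf_grid=(1,), seed=7)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(i1, i2)


FAST_ENET = {"l1_ratios": (0.5, 1.0), "n_alphas": 20}


class TestRepeatedCv:
    def test_reproducible_given_seeds(self, linear_data):
        X, y = linear_data
        scheme = predict.CvScheme(2, 5, 3)
        r1 = predict.run_repeated_cv(X, y, "spearman", "enet", scheme,
                                     model_kwargs=FAST_ENET)
        r2 = predict.run_repeated_cv(X, y, "spearman", "enet", scheme,
                                     model_kwargs=FAST_ENET)
        assert r1.split_r2 == r2.split_r2
        assert r1.pooled_pcc == r2.pooled_pcc

    def test_median_is_midpoint_average(self):
        res = predict.PredictionResult(
            selector="median", model="enet",
            split_r2=list(np.arange(90.0)), pooled_r2=[0.0], pooled_pcc=[0.0],
        )
        vals = np.sort(np.arange(90.0))
        assert res.median_test_r2 == (vals[44] + vals[45]) / 2

    def test_pooled_pcc_is_concatenated_not_averaged(self, linear_data):
        """Pooled PCC equals the correlation of the concatenated test
        predictions, reproduced independently with the same fold seeds."""
        X, y = linear_data
        scheme = predict.CvScheme(1, 5, 9)
        res = predict.run_repeated_cv(X, y, "median", "enet", scheme,
                                      model_kwargs=FAST_ENET)
        X5 = X + 5.0  # make the median filter keep everything
        res = predict.run_repeated_cv(X5, y, "median", "enet", scheme,
                                      model_kwargs=FAST_ENET)
        preds = np.empty_like(y)
        kf = KFold(5, shuffle=True, random_state=9)
        fold_pccs = []
        for train, test in kf.split(y):
            p, _ = predict.fit_predict_enet(
                X5.iloc[train].to_numpy(), y[train], X5.iloc[test].to_numpy(),
                seed=9, **FAST_ENET,
            )
            preds[test] = p
            fold_pccs.append(stats.pearsonr(y[test], p).statistic)
        pooled = stats.pearsonr(y, preds).statistic
        assert res.pooled_pcc[0] == pytest.approx(pooled, abs=1e-9)
        assert pooled != pytest.approx(np.mean(fold_pccs), abs=1e-6)

    def test_every_plant_tested_once_per_repeat(self, linear_data):
        X, y = linear_data
        scheme = predict.CvScheme(1, 10, 0)
        res = predict.run_repeated_cv(X + 5.0, y, "median", "enet", scheme,
                                      model_kwargs=FAST_ENET)
        assert len(res.split_r2) == 10
        assert np.isfinite(res.pooled_r2[0])

    def test_signal_beats_null(self, linear_data):
        X, y = linear_data
        scheme = predict.CvScheme(2, 5, 0)
        sig = predict.run_repeated_cv(X, y, "spearman", "enet", scheme,
                                      model_kwargs=FAST_ENET)
        rng = np.random.default_rng(1)
        null = predict.run_repeated_cv(X, rng.permutation(y), "median", "enet", scheme,
                                       model_kwargs=FAST_ENET)
        assert sig.median_test_r2 > 0.5
        assert null.median_test_r2 < sig.median_test_r2


class TestPermutationBaseline:
    def test_percentile_linear_interpolation(self, linear_data):
        X, y = linear_data
        scores, pct = predict.permutation_baseline(
            X, y, "median", "enet", n_perm=12, seed=0, model_kwargs=FAST_ENET
        )
        valid = scores[np.isfinite(scores)]
        assert pct == pytest.approx(np.percentile(valid, 95, method="linear"))

    def test_signal_earns_star(self, linear_data):
        X, y = linear_data
        res = predict.run_repeated_cv(X, y, "spearman", "enet",
                                      predict.CvScheme(2, 5, 0),
                                      model_kwargs=FAST_ENET)
        _, pct = predict.permutation_baseline(
            X, y, "spearman", "enet", n_perm=30, seed=0, model_kwargs=FAST_ENET
        )
        assert res.median_test_r2 > pct


class TestImportanceRanking:
    def test_constant_importance_and_frequency(self):
        res = predict.PredictionResult(
            selector="median", model="rf",
            split_r2=[0.5] * 4, pooled_r2=[0.5], pooled_pcc=[0.7],
            selected=[np.array(["a", "b"])] * 4,
            importances=[{"a": 0.9, "b": 0.1}] * 4,
        )
        table = predict.rank_feature_importance({"median": res})
        assert table.loc["a", "median_importance"] == 0.9
        assert table.loc["a", "selection_frequency"] == 1.0
        assert table.index[0] == "a"

    def test_never_selected_feature_excluded(self):
        res = predict.PredictionResult(
            selector="median", model="rf",
            split_r2=[0.5], pooled_r2=[0.5], pooled_pcc=[0.7],
            selected=[np.array(["a"])],
            importances=[{"a": 1.0}],
        )
        table = predict.rank_feature_importance({"median": res})
        assert "b" not in table.index

    def test_best_selector_wins(self):
        good = predict.PredictionResult("spearman", "enet", [0.8], [0.8], [0.9],
                                        [np.array(["a"])], [{"a": 1.0}])
        bad = predict.PredictionResult("median", "enet", [0.1], [0.1], [0.2],
                                       [np.array(["z"])], [{"z": 9.0}])
        table = predict.rank_feature_importance({"spearman": good, "median": bad})
        assert table.attrs["best_selector"] == "spearman"
        assert "z" not in table.index

    def test_unselected_splits_missing_not_zero(self):
        res = predict.PredictionResult(
            "median", "enet", [0.5, 0.5], [0.5], [0.7],
            selected=[np.array(["a", "b"]), np.array(["a"])],
            importances=[{"a": 0.5, "b": 0.8}, {"a": 0.7}],
        )
        table = predict.rank_feature_importance({"median": res})
        # b's median over the single split where it was selected
        assert table.loc["b", "median_importance"] == 0.8
        assert table.loc["b", "selection_frequency"] == 0.5
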