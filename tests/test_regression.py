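"""OLS, forward selection, VIF, NIPALS PLS1 and the component scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cbqsar import (ForwardSelectionMLR, PLS1Regression, adjusted_r_squared,
                    ols_fit, r_squared, scan_components, vif)


def standardized(rng, n, m, names=None):
    X = pd.DataFrame(rng.standard_normal((n, m)),
                     columns=names or [f"d{j}" for j in range(m)])
    return (X - X.mean()) / X.std(ddof=1)


class TestOLS:
    def test_noiseless_recovery(self, rng):
        Z = standardized(rng, 20, 1)
        y = 3.0 + 1.7 * Z["d0"].to_numpy()
        model = ols_fit(Z, y)
        assert model.coefficients[0] == pytest.approx(1.7, abs=1e-10)
        assert r_squared(y, model.predict(Z)) == pytest.approx(1.0, abs=1e-12)

    def test_intercept_is_mean_response(self, rng):
        Z = standardized(rng, 15, 3)
        y = rng.standard_normal(15) + 5.0
        model = ols_fit(Z, y)
        assert model.intercept == pytest.approx(float(np.mean(y)), abs=1e-10)

    def test_hand_solved_bivariate_normal_equations(self):
        # 5-point toy; expected coefficients from the 2x2 normal equations
        # solved independently below
        Z = pd.DataFrame({"a": [-2.0, -1.0, 0.0, 1.0, 2.0],
                          "b": [1.0, -1.0, 0.0, -1.0, 1.0]})
        y = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        A = Z.to_numpy()
        expected = np.linalg.solve(A.T @ A, A.T @ (y - y.mean()))
        model = ols_fit(Z, y)
        np.testing.assert_allclose(model.coefficients, expected, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        Z = standardized(rng, 25, 4)
        y = Z.to_numpy() @ np.array([0.5, -0.3, 0.2, 0.9]) \
            + 0.3 * rng.standard_normal(25) + 6.0
        ref = sm.OLS(y, sm.add_constant(Z.to_numpy())).fit()
        model = ols_fit(Z, y)
        np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-8)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-8)

    def test_residuals_orthogonal_to_predictors(self, rng):
        Z = standardized(rng, 30, 3)
        y = rng.standard_normal(30)
        model = ols_fit(Z, y)
        resid = y - model.predict(Z)
        assert np.abs(Z.to_numpy().T @ resid).max() < 1e-8

    def test_singular_design_rejected(self, rng):
        Z = standardized(rng, 10, 2)
        Z["c"] = Z["d0"] + Z["d1"]
        with pytest.raises(ValueError, match="cond"):
            ols_fit(Z, rng.standard_normal(10))

    def test_underdetermined_rejected(self, rng):
        Z = standardized(rng, 4, 5)
        with pytest.raises(ValueError, match="n > p"):
            ols_fit(Z, rng.standard_normal(4))


class TestForwardSelection:
    def test_single_relevant_feature_found(self, rng):
        Z = standardized(rng, 40, 6)
        y = 6.0 + 0.9 * Z["d2"].to_numpy() + 0.05 * rng.standard_normal(40)
        f = ForwardSelectionMLR().fit(Z, y)
        assert f.selected_features_[0] == "d2"

    def test_two_orthogonal_signals_equal_best_subset(self):
        rng = np.random.default_rng(21)
        Z = standardized(rng, 30, 5)
        y = 6.0 + 0.8 * Z["d1"].to_numpy() - 0.6 * Z["d3"].to_numpy() \
            + 0.1 * rng.standard_normal(30)
        f = ForwardSelectionMLR(max_features=2).fit(Z, y)
        # brute-force best-subset-of-2 oracle by adjusted R²
        best, best_adj = None, -np.inf
        for pair in itertools.combinations(Z.columns, 2):
            m = ols_fit(Z[list(pair)], y)
            adj = adjusted_r_squared(r_squared(y, m.predict(Z[list(pair)])),
                                     30, 2)
            if adj > best_adj:
                best, best_adj = set(pair), adj
        assert set(f.selected_features_) == best == {"d1", "d3"}

    def test_all_junk_selects_almost_nothing(self):
        rng = np.random.default_rng(1)
        Z = standardized(rng, 50, 6, names=[f"j{i}" for i in range(6)])
        y = rng.standard_normal(50)
        f = ForwardSelectionMLR().fit(Z, y)
        assert len(f.selected_features_) <= 1
        if f.selected_features_:
            assert f.adjusted_r2_ < 0.3

    def test_accepted_steps_strictly_increase(self, rng):
        Z = standardized(rng, 30, 6)
        y = Z.to_numpy() @ rng.standard_normal(6) + 0.2 * rng.standard_normal(30)
        f = ForwardSelectionMLR().fit(Z, y)
        accepted = [s.adjusted_r2 for s in f.trace_.steps if s.accepted]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))

    @pytest.mark.parametrize("seed", range(20))
    def test_each_accepted_step_is_stagewise_argmax(self, seed):
        # independent oracle: at every accepted stage, exhaustively score
        # all candidate extensions with a plain lstsq fit
        rng = np.random.default_rng(seed)
        n, m = 25, 6
        Z = standardized(rng, n, m)
        y = Z.to_numpy() @ rng.normal(0, 0.6, m) + 0.4 * rng.standard_normal(n)
        f = ForwardSelectionMLR().fit(Z, y)
        chosen = []
        for step in f.trace_.steps:
            if not step.accepted:
                continue
            best_adj = -np.inf
            for cand in [c for c in Z.columns if c not in chosen]:
                cols = chosen + [cand]
                A = np.column_stack([np.ones(n), Z[cols].to_numpy()])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                r2 = 1 - ((y - A @ coef) ** 2).sum() / ((y - y.mean()) ** 2).sum()
                best_adj = max(best_adj,
                               adjusted_r_squared(r2, n, len(cols)))
            assert step.adjusted_r2 == pytest.approx(best_adj, abs=1e-9)
            chosen.append(step.feature)

    def test_max_features_respected(self, rng):
        Z = standardized(rng, 30, 6)
        y = Z.to_numpy() @ np.ones(6) + 0.1 * rng.standard_normal(30)
        f = ForwardSelectionMLR(max_features=2).fit(Z, y)
        assert len(f.selected_features_) <= 2


class TestVIF:
    def test_orthogonal_columns_give_unity(self):
        g = np.random.default_rng(3)
        raw = g.standard_normal((10, 2))
        raw -= raw.mean(axis=0)
        basis, _ = np.linalg.qr(raw)
        Z = pd.DataFrame(basis, columns=["a", "b"])
        out = vif(Z)
        assert out["a"] == pytest.approx(1.0, abs=1e-10)
        assert out["b"] == pytest.approx(1.0, abs=1e-10)

    def test_known_pairwise_correlation(self):
        # exact r = 0.6 via orthonormal construction: VIF = 1/(1-0.36)
        g = np.random.default_rng(4)
        raw = g.standard_normal((12, 2))
        raw -= raw.mean(axis=0)
        basis, _ = np.linalg.qr(raw)
        u, v = basis.T
        Z = pd.DataFrame({"a": u, "b": 0.6 * u + 0.8 * v})
        out = vif(Z)
        assert out["a"] == pytest.approx(1.5625, abs=1e-9)
        assert out["b"] == pytest.approx(1.5625, abs=1e-9)

    def test_exact_collinearity_flags_infinity(self, rng):
        Z = standardized(rng, 12, 2)
        Z["c"] = Z["d0"] + Z["d1"]
        out = vif(Z)
        assert all(np.isinf(v) for v in out.values())


class TestPLS1:
    def test_full_rank_equals_ols(self, rng):
        for _ in range(10):
            n, m = int(rng.integers(6, 13)), int(rng.integers(2, 6))
            if n <= m + 1:
                continue
            Z = standardized(rng, n, m)
            y = rng.standard_normal(n)
            pls = PLS1Regression(n_components=m).fit(Z, y)
            ref = ols_fit(Z, y)
            np.testing.assert_allclose(pls.predict(Z), ref.predict(Z), atol=1e-8)

    def test_single_collinear_column_one_component(self, rng):
        Z = standardized(rng, 15, 3)
        y = 2.0 + 1.3 * Z["d1"].to_numpy()
        pls = PLS1Regression(n_components=1).fit(Z[["d1"]], y)
        assert r_squared(y, pls.predict(Z[["d1"]])) == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_reference(self):
        # independent implementation cross-check on a seeded 6x4 instance
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(42)
        Z = standardized(rng, 6, 4)
        y = rng.standard_normal(6)
        ours = PLS1Regression(n_components=2).fit(Z, y)
        ref = PLSRegression(n_components=2, scale=False).fit(Z.to_numpy(), y)
        np.testing.assert_allclose(
            ours.predict(Z), ref.predict(Z.to_numpy()).ravel(), atol=1e-8)

    def test_score_orthogonality_and_deflation_identity(self, rng):
        Z = standardized(rng, 12, 6)
        y = rng.standard_normal(12)
        pls = PLS1Regression(n_components=4).fit(Z, y)
        T = pls.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        # X = T P' + X_res: reconstruct deflation residual explicitly
        Xc = Z.to_numpy() - Z.to_numpy().mean(axis=0)
        X_res = Xc - T @ pls.x_loadings_.T
        np.testing.assert_allclose(Xc, T @ pls.x_loadings_.T + X_res, atol=1e-12)
        # variance bookkeeping
        assert pls.x_variance_explained_.sum() <= 1 + 1e-12
        assert (pls.x_variance_explained_ >= 0).all()

    def test_collapsed_model_reproduces_fitted_values(self, rng):
        Z = standardized(rng, 10, 5)
        y = rng.standard_normal(10)
        pls = PLS1Regression(n_components=3).fit(Z, y)
        lm = pls.to_linear_model()
        np.testing.assert_allclose(lm.predict(Z), pls.predict(Z), atol=1e-10)
        assert lm.provenance == "plsr_collapsed"

    def test_components_beyond_rank_rejected(self, rng):
        Z = standardized(rng, 5, 8)  # rank at most 4 after centering
        with pytest.raises(ValueError, match="rank"):
            PLS1Regression(n_components=5).fit(Z, rng.standard_normal(5))

    def test_fully_deflated_response_rejected(self):
        # rank-2 X whose response is exactly the first component's score:
        # the second weight vector has zero norm
        g = np.random.default_rng(8)
        raw = g.standard_normal((10, 2))
        raw -= raw.mean(axis=0)
        basis, _ = np.linalg.qr(raw)
        Z = pd.DataFrame(basis, columns=["u", "v"])
        y = Z["u"].to_numpy()
        with pytest.raises(ValueError, match="deflated"):
            PLS1Regression(n_components=2).fit(Z, y)


class TestComponentScan:
    def test_noiseless_single_factor_is_perfect_at_one(self, rng):
        n = 12
        f = rng.standard_normal(n)
        X = pd.DataFrame({"a": 2 * f, "b": -f, "c": 0.5 * f})
        y = 3.0 + f
        scan = scan_components(X, y, max_components=1)
        assert scan.r2[0] == pytest.approx(1.0, abs=1e-8)

    def test_r2_non_decreasing(self, rng):
        X = pd.DataFrame(rng.standard_normal((14, 6)),
                         columns=[f"d{j}" for j in range(6)])
        y = rng.standard_normal(14)
        scan = scan_components(X, y, max_components=4)
        assert all(b >= a - 1e-10 for a, b in zip(scan.r2, scan.r2[1:]))

    def test_q2_peaks_at_planted_latent_dimension(self):
        # two latent factors drive both X and y; extra components overfit
        rng = np.random.default_rng(0)
        n, m = 14, 8
        F = rng.standard_normal((n, 2))
        load = rng.standard_normal((2, m))
        X = pd.DataFrame(F @ load + 0.3 * rng.standard_normal((n, m)),
                         columns=[f"d{j}" for j in range(m)])
        y = 2 * F[:, 0] - 1.5 * F[:, 1] + 0.8 * rng.standard_normal(n)
        scan = scan_components(X, y, max_components=4)
        assert scan.best_by_q2 == 2

    def test_q2_equals_explicit_fold_loop(self):
        # oracle: re-implement leave-one-out for the scanned procedure
        from cbqsar.preprocessing import DescriptorStandardizer
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((10, 4)),
                         columns=list("abcd"))
        y = X["a"].to_numpy() + 0.5 * rng.standard_normal(10)
        scan = scan_components(X, y, max_components=2)
        for k, ncomp in enumerate(scan.n_components):
            press = 0.0
            for i in range(10):
                rest = [j for j in range(10) if j != i]
                std = DescriptorStandardizer().fit(X.iloc[rest])
                pls = PLS1Regression(n_components=ncomp).fit(
                    std.transform(X.iloc[rest]), y[rest])
                pred = pls.predict(std.transform(X.iloc[[i]]))[0]
                press += (y[i] - pred) ** 2
            q2 = 1 - press / ((y - y.mean()) ** 2).sum()
            assert scan.q2[k] == pytest.approx(q2, abs=1e-12)


class TestParameterRecovery:
    def test_ols_and_full_rank_pls_recover_planted_coefficients(self):
        rng = np.random.default_rng(1)
        n = 100
        Z = standardized(rng, n, 2, names=["a", "b"])
        beta = np.array([0.8, -0.4])
        y = 6.0 + Z.to_numpy() @ beta + 0.1 * rng.standard_normal(n)
        for model in (ols_fit(Z, y),
                      PLS1Regression(n_components=2).fit(Z, y).to_linear_model()):
            np.testing.assert_allclose(model.coefficients, beta, atol=0.05)
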