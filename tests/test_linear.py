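import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ruecanopy.linear import (
    BestSubsetLinear,
    LinearModelSpec,
    apply_model,
    best_subset,
    fit_linear,
    published_models,
    vif,
)


def oracle_best_subset(design, y, max_k, vif_max=10.0, size_alpha=0.05):
    """Independent re-implementation of the documented selection rule using
    statsmodels OLS and scipy's F distribution."""
    import statsmodels.api as sm
    from scipy.stats import f as f_dist
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    cols = list(design.columns)
    n, p = len(y), len(cols)
    best_by_size = {}
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(cols, k):
            X = design[list(subset)].to_numpy()
            if k >= 2:
                Xc = sm.add_constant(X)
                vifs = [variance_inflation_factor(Xc, j + 1) for j in range(k)]
                if any(v > vif_max for v in vifs):
                    continue
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            key = (-fit.rsquared, fit.ssr)
            if k not in best_by_size or key < best_by_size[k][0]:
                best_by_size[k] = (key, subset, fit)
    alpha = size_alpha / p
    sizes = sorted(best_by_size)
    win_k = sizes[0]
    winner = best_by_size[win_k]
    for k in sizes[1:]:
        cand = best_by_size[k]
        sse_s, sse_b = winner[2].ssr, cand[2].ssr
        dfd = n - k - 1
        if sse_b <= 0:
            if sse_s > 1e-12 * np.sum((y - y.mean()) ** 2):
                winner, win_k = cand, k
            continue
        F = ((sse_s - sse_b) / (k - win_k)) / (sse_b / dfd)
        if F > 0 and f_dist.sf(F, k - win_k, dfd) < alpha:
            winner, win_k = cand, k
    _, subset, fit = winner
    return set(subset), dict(zip(subset, fit.params[1:])), fit.params[0]


class TestFitLinear:
    def test_exact_noise_free_line(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        spec, metrics = fit_linear(x, 2 * x["x"] + 1)
        assert spec.intercept == pytest.approx(1.0, abs=1e-10)
        assert spec.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert metrics.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"] - 0.5 * X["b"] + rng.normal(size=30)
        spec, _ = fit_linear(X, y)
        Xd = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert spec.intercept == pytest.approx(beta[0], abs=1e-9)
        assert spec.coefficients["a"] == pytest.approx(beta[1], abs=1e-9)
        assert spec.coefficients["b"] == pytest.approx(beta[2], abs=1e-9)

    def test_p_at_least_n_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 4)))
        with pytest.raises(ValueError, match="n > p"):
            fit_linear(X, np.arange(4.0))

    def test_rank_deficiency_names_collinear_predictors(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]
        X["c"] = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(X, rng.normal(size=20))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        assert all(v == pytest.approx(1.0) for v in vif(X).values())

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        out = vif(pd.DataFrame({"a": a, "b": a}))
        assert all(math.isinf(v) for v in out.values())

    def test_correlated_pair_closed_form(self):
        # Var inflation for a bivariate pair is 1/(1 - r^2)
        rng = np.random.default_rng(3)
        z = rng.normal(size=20000)
        x = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=20000)
        out = vif(pd.DataFrame({"a": z, "b": x}))
        r2 = np.corrcoef(z, x)[0, 1] ** 2
        assert out["a"] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestBestSubset:
    def test_candidate_count_binomial(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        res = best_subset(X, rng.normal(size=30), max_k=3)
        assert res.candidates_evaluated == 6 + 15 + 20

    def test_noise_free_planted_pair_recovered_exactly(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("ABCDEF"))
        y = 2 * X["B"] - 1.5 * X["E"]
        res = best_subset(X, y, max_k=3)
        assert set(res.best.coefficients) == {"B", "E"}
        assert res.best.coefficients["B"] == pytest.approx(2.0, abs=1e-9)

    def test_max_k_one_reduces_to_best_single_correlation(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = X["c"] + 0.5 * rng.normal(size=40)
        res = best_subset(X, y, max_k=1)
        best_r = max(X.columns, key=lambda c: abs(np.corrcoef(X[c], y)[0, 1]))
        assert list(res.best.coefficients) == [best_r]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(35, 8)), columns=[f"x{i}" for i in range(8)])
        y = (1.2 * X["x1"] - 0.8 * X["x4"] + 0.6 * X["x6"] + 0.4 * rng.normal(size=35)).to_numpy()
        ours = best_subset(X, y, max_k=3)
        subset, coeffs, intercept = oracle_best_subset(X, y, max_k=3)
        assert set(ours.best.coefficients) == subset
        for name, b in coeffs.items():
            assert ours.best.coefficients[name] == pytest.approx(b, abs=1e-8)
        assert ours.best.intercept == pytest.approx(intercept, abs=1e-8)

    def test_vif_filter_excludes_collinear_subsets(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "b": a + 0.01 * rng.normal(size=40), "c": rng.normal(size=40)})
        y = a + X["c"] + 0.1 * rng.normal(size=40)
        res = best_subset(X, y, max_k=2, vif_max=10)
        assert not {"a", "b"} <= set(res.best.coefficients)

    def test_no_survivor_raises_helpful_error(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": a * 2})
        # single-predictor subsets always survive, so force k >= 2 by passing
        # identical columns and vif_max below 1 is impossible; instead check
        # the message path via a direct duplicated design at max_k=2
        res = best_subset(X, a + rng.normal(size=30) * 0.1, max_k=2)
        assert len(res.best.coefficients) == 1  # the pair is VIF-blocked


class TestModelClassAndRegistry:
    def test_model_results_roundtrip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
        df["resp"] = 3 * df["x"] + rng.normal(size=40) * 0.2
        res = BestSubsetLinear.from_dataframe(df, "resp", max_k=2).fit()
        assert "x" in res.params.index
        assert "resp" in res.summary()
        spec2 = LinearModelSpec.from_json(res.spec.to_json())
        assert spec2.coefficients == res.spec.coefficients

    def test_registry_size_and_provenance(self):
        reg = published_models()
        assert len(reg) == 26
        assert all(s.provenance == "published_table" for s in reg.values())
        traits = {s.response for s in reg.values()}
        assert len(traits) == 13

    def test_ipar_e40_bcs_coefficients(self):
        spec = published_models()["IPAR_E40_bcs"]
        assert spec.intercept == pytest.approx(289.723)
        assert set(spec.coefficients) == {"CTvg", "NDVIGSvg"}
        assert spec.coefficients["CTvg"] == pytest.approx(-9.158)
        assert spec.coefficients["NDVIGSvg"] == pytest.approx(168.407)

    def test_ipar_pm_bcs_and_cvi_identical(self):
        reg = published_models()
        a, b = reg["IPAR_PM_bcs"], reg["IPAR_PM_cVI"]
        assert a.intercept == b.intercept
        assert a.coefficients == b.coefficients

    def test_apply_model_dot_product_oracle(self):
        rng = np.random.default_rng(9)
        names = ["u", "v", "w"]
        spec = LinearModelSpec("t", intercept=1.5,
                               coefficients=dict(zip(names, rng.normal(size=3))))
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=names)
        expect = 1.5 + table.to_numpy() @ np.array(list(spec.coefficients.values()))
        np.testing.assert_allclose(apply_model(spec, table), expect, atol=1e-12)

    def test_apply_model_missing_predictor_named(self):
        spec = published_models()["IPAR_E40_bcs"]
        with pytest.raises(KeyError, match="NDVIGSvg"):
            apply_model(spec, pd.DataFrame({"CTvg": [1.0]}))

    def test_apply_model_is_linear_without_intercept(self):
        spec = LinearModelSpec("t", intercept=0.0, coefficients={"a": 2.0, "b": -1.0})
        x = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        np.testing.assert_allclose(apply_model(spec, 3 * x), 3 * apply_model(spec, x))

    def test_best_values_slice_uses_highest_observed(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["resp"] = 2 * df["x"] + 0.1 * rng.normal(size=30)
        res = BestSubsetLinear.from_dataframe(df, "resp", max_k=1).fit()
        m = res.evaluate_best_values(df[["x"]], df["resp"], n_best=10)
        assert m.n == 10
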