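import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alphadec.stats import (gelman_scale, zscore, effective_tests,
                            adjust_alpha, fit_outcome_model, ModelSpec,
                            correlation_table, posterior_to_prior,
                            StatsError, CollinearityError)


class TestGelmanScale:
    def test_simple_triplet(self):
        assert gelman_scale([1, 2, 3]) == pytest.approx([-0.5, 0.0, 0.5])

    def test_pair(self):
        # sd([10,20]) = 7.071..., halved z-scores: +/- 0.7071/2
        assert gelman_scale([10, 20]) == pytest.approx([-0.35355339, 0.35355339])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40,
                    unique=True))
    def test_output_moments(self, xs):
        out = gelman_scale(xs)
        assert abs(out.mean()) < 1e-9
        assert out.std(ddof=1) == pytest.approx(0.5, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            gelman_scale([3.0, 3.0, 3.0])


class TestEffectiveTests:
    def test_identity_matrix(self):
        assert effective_tests(np.eye(5)) == pytest.approx(5.0, abs=1e-9)

    def test_perfectly_correlated_pair(self):
        assert effective_tests(np.ones((2, 2))) == pytest.approx(1.0, abs=1e-9)

    def test_equicorrelated_closed_form(self):
        c = np.full((3, 3), 0.5)
        np.fill_diagonal(c, 1.0)
        # eigenvalues {2, 0.5, 0.5}: Var = 0.75, Meff = 1 + 2*(1 - 0.25)
        assert effective_tests(c) == pytest.approx(2.5, abs=1e-9)

    def test_asymmetric_rejected(self):
        c = np.eye(3)
        c[0, 1] = 0.5
        with pytest.raises(StatsError):
            effective_tests(c)


class TestAdjustAlpha:
    def test_single_test_unchanged(self):
        adj, level = adjust_alpha(0.05, 1.0, "sidak")
        assert adj == pytest.approx(0.05)
        assert level == pytest.approx(0.95)

    def test_sidak_six_effective_tests(self):
        adj, _ = adjust_alpha(0.05, 6.0, "sidak")
        assert adj == pytest.approx(0.008512, abs=1e-6)

    def test_bonferroni_six_gives_9917_interval(self):
        adj, level = adjust_alpha(0.05, 6.0, "bonferroni")
        assert adj == pytest.approx(0.008333, abs=1e-6)
        assert level == pytest.approx(0.99167, abs=1e-5)

    def test_monotone_in_meff_and_method_order(self):
        prev = 1.0
        for meff in (1.0, 2.0, 4.0, 8.0):
            sid, _ = adjust_alpha(0.05, meff, "sidak")
            bon, _ = adjust_alpha(0.05, meff, "bonferroni")
            assert sid >= bon
            assert sid <= prev
            prev = sid

    def test_invalid_alpha(self):
        with pytest.raises(StatsError):
            adjust_alpha(1.5, 2.0)


class TestOlsBackend:
    def test_noiseless_coefficient_recovery(self):
        rng = np.random.default_rng(0)
        age = rng.standard_normal(100)
        df = pd.DataFrame({"age": age, "y": 0.4 * age})
        res = fit_outcome_model(ModelSpec("y", ["age"]), df)
        assert res.coefficient("age") == pytest.approx(0.4, abs=1e-10)
        assert res.table.loc["age", "significant"]

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.standard_normal((12, 2))
            y = rng.standard_normal(12)
            df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "y": y})
            res = fit_outcome_model(ModelSpec("y", ["x1", "x2"]), df)
            Xc = np.column_stack([np.ones(12), X])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            assert res.coefficient("x1") == pytest.approx(beta[1], abs=1e-10)
            assert res.coefficient("x2") == pytest.approx(beta[2], abs=1e-10)

    def test_scaled_single_predictor_equals_pearson_r(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.3 * x + rng.standard_normal(500)
        df = pd.DataFrame({"x": gelman_scale(x), "y": gelman_scale(y)})
        res = fit_outcome_model(ModelSpec("y", ["x"]), df)
        assert res.coefficient("x") == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_categorical_treatment_coding(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
            "site": ["a", "b", "c", "a", "b", "c"],
        })
        res = fit_outcome_model(ModelSpec("y", ["site"]), df)
        assert res.coefficient("site_b") == pytest.approx(1.0)
        assert res.coefficient("site_c") == pytest.approx(2.0)

    def test_collinearity_error_names_columns(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"y": rng.standard_normal(30),
                           "fa_left": x, "fa_right": x})
        with pytest.raises(CollinearityError) as err:
            fit_outcome_model(ModelSpec("y", ["fa_left", "fa_right"]), df)
        assert {"fa_left", "fa_right"} <= set(err.value.columns)

    def test_interval_level_respected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"x": x, "y": 0.2 * x + rng.standard_normal(200)})
        wide = fit_outcome_model(
            ModelSpec("y", ["x"], interval_level=0.9917), df)
        narrow = fit_outcome_model(
            ModelSpec("y", ["x"], interval_level=0.80), df)
        assert (wide.table.loc["x", "upper"] - wide.table.loc["x", "lower"]) \
            > (narrow.table.loc["x", "upper"] - narrow.table.loc["x", "lower"])


class TestBayesBackend:
    @pytest.fixture(scope="class")
    def stage1(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        y = 0.3 * x + rng.standard_normal(400) * 0.5
        df = pd.DataFrame({"x": x, "y": y})
        spec = ModelSpec("y", ["x"], backend="bayes", n_steps=800,
                         n_burn=300, seed=1)
        return df, fit_outcome_model(spec, df)

    def test_wide_prior_matches_ols(self, stage1):
        df, res = stage1
        ols = fit_outcome_model(ModelSpec("y", ["x"]), df)
        assert res.coefficient("x") == pytest.approx(
            ols.coefficient("x"), abs=0.02)
        assert res.diagnostics["converged"]

    def test_posterior_to_prior_normal_family(self, stage1):
        _, res = stage1
        priors = posterior_to_prior(res)
        kind, mu, sd = priors["x"]
        assert kind == "normal"
        assert mu == pytest.approx(res.coefficient("x"), abs=1e-9)
        assert 0 < sd < 0.2

    def test_sequential_update_shrinks_small_stage2(self, stage1):
        # tiny second cohort with a different slope: the informative prior
        # from stage 1 pulls the estimate toward the stage-1 value
        _, res = stage1
        priors = posterior_to_prior(res)
        rng = np.random.default_rng(6)
        x2 = rng.standard_normal(12)
        y2 = -0.4 * x2 + rng.standard_normal(12) * 0.5
        df2 = pd.DataFrame({"x": x2, "y": y2})
        flat = fit_outcome_model(
            ModelSpec("y", ["x"], backend="bayes", n_steps=800, n_burn=300,
                      seed=2), df2)
        informed = fit_outcome_model(
            ModelSpec("y", ["x"], backend="bayes", n_steps=800, n_burn=300,
                      seed=2, coef_priors=priors), df2)
        assert abs(informed.coefficient("x") - res.coefficient("x")) \
            < abs(flat.coefficient("x") - res.coefficient("x"))

    def test_no_draws_error(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.standard_normal(20),
                           "y": rng.standard_normal(20)})
        ols = fit_outcome_model(ModelSpec("y", ["x"]), df)
        with pytest.raises(StatsError):
            posterior_to_prior(ols)


class TestCorrelationTable:
    def test_perfectly_correlated_columns(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        tab = correlation_table(df)
        assert tab.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(tab), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((10000, 2)), columns=["a", "b"])
        assert abs(correlation_table(df).loc["a", "b"]) < 0.05

    def test_listwise_deletion_and_minimum_n(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, 4], "b": [1.0, np.nan, 3, 4]})
        with pytest.raises(StatsError):
            correlation_table(df)
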