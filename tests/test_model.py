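"""Categorical-logit model: likelihood, priors, sampler, VIF, prediction."""

import numpy as np
import pandas as pd
import pytest

from huntniche.model import (BayesianCategoricalLogit,
                             categorical_log_likelihood, fit_categorical,
                             standardize, vif)


def simulate_direct(n, coef, seed=0, n_numeric=2):
    """Covariate table + prey drawn straight from the softmax model.

    ``coef`` maps category -> (intercept, b_group, b_x1, ..); the group
    indicator is Bernoulli(1/2) and numerics are standard normal.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"group": rng.integers(0, 2, n).astype(float)})
    for j in range(n_numeric):
        X[f"x{j}"] = rng.standard_normal(n)
    cats = ["anomalure"] + list(coef)
    eta = np.zeros((n, len(cats)))
    for k, c in enumerate(coef):
        b = np.asarray(coef[c], dtype=float)
        eta[:, k + 1] = b[0] + X.to_numpy() @ b[1:]
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    idx = (rng.random(n)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return X, pd.Series(np.asarray(cats)[idx])


class TestStandardize:
    def test_three_point_column(self):
        out, consts = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert out["a"].tolist() == [-1.0, 0.0, 1.0]
        assert consts["a"] == (2.0, 1.0)

    def test_idempotent_on_standardized_column(self):
        x = pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)})
        once, _ = standardize(x)
        twice, _ = standardize(once)
        assert np.allclose(once["a"], twice["a"], atol=1e-12)

    def test_constant_column_is_an_error(self):
        with pytest.raises(ValueError, match="'flat'"):
            standardize(pd.DataFrame({"flat": [3.0, 3.0, 3.0]}))


class TestLogLikelihood:
    def test_zero_coefficients_give_uniform_softmax(self):
        n = 7
        cov = pd.DataFrame(index=range(n))
        ll = categorical_log_likelihood(np.zeros((1, 2)), cov,
                                        np.zeros(n, dtype=int), terms=[])
        assert ll == pytest.approx(n * np.log(1 / 3))

    def test_saturating_intercept_drives_probability_to_one(self):
        cov = pd.DataFrame(index=[0])
        ll = categorical_log_likelihood(np.array([[30.0, 0.0]]), cov,
                                        np.array([1]), terms=[])
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_three_way_softmax(self):
        # linear predictors (0, 1, 2), observed category 3
        cov = pd.DataFrame(index=[0])
        ll = categorical_log_likelihood(np.array([[1.0, 2.0]]), cov,
                                        np.array([2]), terms=[])
        expect = np.log(np.e ** 2 / (1 + np.e + np.e ** 2))
        assert ll == pytest.approx(expect, abs=1e-6)
        assert ll == pytest.approx(-0.4076, abs=1e-3)

    def test_nonfinite_covariates_are_an_error(self):
        cov = pd.DataFrame({"x": [1.0, np.nan]})
        with pytest.raises(ValueError, match="non-finite"):
            categorical_log_likelihood(np.zeros((2, 2)), cov,
                                       np.array([0, 1]), terms=["x"])


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 400
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(np.column_stack([np.ones(n),
                                             rng.standard_normal((n, 3))]))
        v = vif(pd.DataFrame(q[:, 1:], columns=list("abc")))
        assert np.allclose(v, 1.0, atol=1e-9)

    def test_correlation_09_gives_closed_form(self):
        n = 1000
        rng = np.random.default_rng(1)
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= np.polyval(np.polyfit(x, e, 1), x)       # exactly orthogonal
        y = 0.9 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.81) * e / e.std()
        v = vif(pd.DataFrame({"x": x, "y": y}))
        assert v["x"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_duplicated_column_is_infinite(self):
        x = np.random.default_rng(2).standard_normal(100)
        v = vif(pd.DataFrame({"a": x, "b": x, "c": x[::-1]}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])


class TestSamplerAgainstGridOracle:
    def test_mcmc_matches_dense_grid_integration(self):
        from conftest import grid_posterior_2param
        rng = np.random.default_rng(3)
        n = 60
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.5 + 1.0 * x)))
        y = np.where(rng.random(n) < p, "b", "a")
        X = pd.DataFrame({"x0": x})
        est = BayesianCategoricalLogit(random_state=5, reference="a",
                                       standardize_numeric=False).fit(X, y)
        grid_mean, grid_sd = grid_posterior_2param(x, y == "b")
        assert np.allclose(est.coef_.ravel(), grid_mean, atol=0.05)
        assert np.allclose(est.se_.ravel(), grid_sd, atol=0.05)
        assert est.converged_


TRUTH = {"duiker": [-0.5, 1.5, 0.8, 0.0],
         "squirrel": [-1.0, 1.0, 0.0, -0.6]}


@pytest.fixture(scope="module")
def big_fit():
    X, y = simulate_direct(2000, TRUTH, seed=4)
    est = BayesianCategoricalLogit(random_state=6, reference="anomalure",
                                   standardize_numeric=False)
    return X, y, est.fit(X, y)


class TestFitRecovery:
    TRUTH = TRUTH

    def test_posterior_means_match_mle_oracle(self, big_fit):
        from scipy.optimize import minimize
        X, y, est = big_fit
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        y_index = y.map({"anomalure": 0, "duiker": 1, "squirrel": 2}).to_numpy()

        def nll(theta):
            B = theta.reshape(2, 4)
            return -categorical_log_likelihood(B.T, X, y_index,
                                               terms=list(X.columns))

        mle = minimize(nll, np.zeros(8), method="BFGS").x.reshape(2, 4)
        assert np.allclose(est.coef_, mle, atol=0.2)

    def test_retained_draw_count_and_reference_fixed_at_zero(self, big_fit):
        _, _, est = big_fit
        chains, draws, k1, p = est.draws_.shape
        assert chains * draws == est.chains * (est.iterations - est.warmup)
        assert k1 == 2 and p == 4          # reference category not sampled
        assert est.classes_[0] == "anomalure"

    def test_predicted_group_probabilities_recover_generative_truth(self, big_fit):
        _, _, est = big_fit
        probs = est.predict_group_probs(0)
        eta = np.array([0.0, self.TRUTH["duiker"][0], self.TRUTH["squirrel"][0]])
        expect = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(probs["mean"], expect, atol=0.05)
        assert probs["mean"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_per_draw_probabilities_sum_to_one(self, big_fit):
        X, _, est = big_fit
        Xd = est._transform_new(X.head(5))
        from scipy.special import softmax
        per_draw = softmax(est._linear_predictors(Xd), axis=2)
        assert np.allclose(per_draw.sum(axis=2), 1.0, atol=1e-12)

    def test_summary_table_shape_and_rhat(self, big_fit):
        _, _, est = big_fit
        summ = est.summary()
        assert len(summ) == 2 * 4
        assert (summ["rhat"] < 1.01).all()
        assert (summ["ci_low"] <= summ["estimate"]).all()
        assert (summ["estimate"] <= summ["ci_high"]).all()


def test_ci_width_shrinks_with_sample_size():
    truth = {"duiker": [-0.5, 1.0, 0.5, 0.0], "squirrel": [-0.8, 0.8, 0.0, 0.3]}
    widths = []
    for n in (250, 1000):
        X, y = simulate_direct(n, truth, seed=7)
        est = BayesianCategoricalLogit(random_state=8, reference="anomalure",
                                       standardize_numeric=False).fit(X, y)
        widths.append(float(np.mean(est.ci_[..., 1] - est.ci_[..., 0])))
    assert widths[1] < widths[0]


class TestValidation:
    def test_rejects_bad_mcmc_layout(self):
        X = pd.DataFrame({"x0": np.arange(30.0)})
        y = ["a", "b"] * 15
        with pytest.raises(ValueError, match="warmup"):
            BayesianCategoricalLogit(iterations=100, warmup=100).fit(X, y)
        with pytest.raises(ValueError, match="chains"):
            BayesianCategoricalLogit(chains=1).fit(X, y)

    def test_requires_minimum_observations(self):
        X = pd.DataFrame({"x0": np.arange(10.0)})
        with pytest.raises(ValueError, match="at least 20"):
            BayesianCategoricalLogit().fit(X, ["a", "b"] * 5)

    def test_complete_case_dropping_is_logged(self, caplog):
        rng = np.random.default_rng(9)
        X, y = simulate_direct(120, {"duiker": [0.0, 0.5, 0.2, 0.0],
                                     "squirrel": [0.0, 0.3, 0.0, 0.1]},
                               seed=10)
        cov = X.copy()
        cov.loc[:4, "x0"] = np.nan
        cov["prey"] = y
        fit = fit_categorical(cov.rename(columns={"x0": "mean_association",
                                                  "x1": "usage_difference"}),
                              "prey", seed=11, iterations=400, warmup=200)
        assert fit.n_dropped_ == 5
        assert fit.n_obs_ == 115
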