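"""Beta regression, LASSO path with AIC selection, and OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from attnov.exceptions import ConfigurationError, DomainError
from attnov.regression import (
    BetaRegression,
    LassoAIC,
    OLSRegression,
    RegressionSpec,
    fit_beta_regression,
    fit_lasso,
    fit_ols,
    select_lambda_aic,
    squeeze_unit_interval,
)


class TestSqueezeUnitInterval:
    @pytest.mark.parametrize(
        "y, n, expected",
        [(0.0, 200, 0.0025), (1.0, 200, 0.9975), (0.5, 200, 0.5), (0.5, 17, 0.5)],
    )
    def test_formula(self, y, n, expected):
        assert squeeze_unit_interval(y, n) == pytest.approx(expected, abs=1e-12)

    def test_array_default_n(self):
        y = np.array([0.0, 0.25, 1.0, 0.5])
        out = squeeze_unit_interval(y)
        assert out[0] == pytest.approx((0 * 3 + 0.5) / 4)
        assert np.all((out > 0) & (out < 1))


def _beta_data(n, seed, intercept=-1.0, slope=0.05, phi=6.0):
    rng = np.random.default_rng(seed)
    score = rng.integers(0, 21, size=n).astype(float)
    mu = expit(intercept + slope * score)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return pd.DataFrame({"area": np.clip(y, 1e-9, 1 - 1e-9), "score": score})


class TestBetaRegression:
    def test_recovers_generating_parameters(self):
        data = _beta_data(2000, seed=5)
        res = BetaRegression.from_dataframe(data, "area", ["score"]).fit()
        assert res.coefficients["score"] == pytest.approx(
            0.05, abs=2 * res.std_errors["score"]
        )
        assert res.phi == pytest.approx(6.0, rel=0.15)
        assert res.n == 2000
        assert res.log_likelihood > 0  # density values above 1 are common here

    def test_null_slope_not_significant_on_average(self):
        estimates = []
        for seed in range(20):
            data = _beta_data(400, seed=seed, slope=0.0)
            res = BetaRegression.from_dataframe(data, "area", ["score"]).fit()
            estimates.append(res.coefficients["score"])
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates)) < 2 * mc_se + 1e-3

    def test_boundary_values_squeezed_automatically(self):
        data = _beta_data(100, seed=2)
        data.loc[0, "area"] = 0.0
        data.loc[1, "area"] = 1.0
        res = BetaRegression.from_dataframe(data, "area", ["score"]).fit()
        assert np.isfinite(res.log_likelihood)

    def test_response_outside_unit_interval_rejected(self):
        data = pd.DataFrame({"y": [0.2, 1.4, 0.5] * 5, "x": list(range(15))})
        with pytest.raises(DomainError):
            BetaRegression.from_dataframe(data, "y", ["x"])

    def test_pseudo_r2_between_zero_and_one(self):
        res = BetaRegression.from_dataframe(_beta_data(500, seed=3), "area", ["score"]).fit()
        assert 0 <= res.pseudo_r2 <= 1
        assert "phi" in res.summary()

    def test_functional_wrapper(self):
        spec = RegressionSpec(dependent="area", predictors=("score",), family="beta")
        res = fit_beta_regression(_beta_data(300, seed=7), spec)
        assert set(res.coefficients) == {"Intercept", "score"}


def _lasso_data(n=200, seed=0, p=4, beta=(2.0, 0.0, -1.5, 0.0), noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ np.asarray(beta) + rng.normal(0, noise, size=n)
    cols = {f"x{j}": X[:, j] for j in range(p)}
    return pd.DataFrame({"y": y, **cols})


class TestLassoAIC:
    def test_large_lambda_kills_all_slopes(self):
        data = _lasso_data()
        path = LassoAIC.from_dataframe(data, "y", [f"x{j}" for j in range(4)]).fit_path([1e6])
        entry = path.entries[0]
        slopes = [v for k, v in entry.coefficients.items() if k != "Intercept"]
        assert slopes == [0.0] * 4
        assert entry.coefficients["Intercept"] == pytest.approx(data["y"].mean())

    def test_zero_lambda_equals_ols(self):
        data = _lasso_data()
        names = [f"x{j}" for j in range(4)]
        lasso0 = LassoAIC.from_dataframe(data, "y", names).fit_path([0.0]).entries[0]
        ols = OLSRegression.from_dataframe(data, "y", names).fit()
        for name in ("Intercept", *names):
            assert lasso0.coefficients[name] == pytest.approx(
                ols.coefficients[name], rel=1e-6, abs=1e-9
            )

    def test_soft_threshold_closed_form_single_predictor(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + rng.normal(0, 0.5, size=500)
        data = pd.DataFrame({"y": y, "x": x})
        beta_ols = float(x @ (y - y.mean()) / len(y))  # x has unit variance
        for lam in (0.1, 0.3, 0.5, abs(beta_ols) + 0.2):
            entry = LassoAIC.from_dataframe(data, "y", ["x"]).fit_path([lam]).entries[0]
            expected = np.sign(beta_ols) * max(abs(beta_ols) - lam, 0.0)
            # coefficient is reported per unit of x; x already standardized
            assert entry.coefficients["x"] == pytest.approx(expected, abs=1e-6)

    def test_path_l1_norm_shrinks_with_lambda(self):
        data = _lasso_data(seed=3)
        grid = [0.01, 0.05, 0.2, 0.8, 3.0]
        path = LassoAIC.from_dataframe(data, "y", [f"x{j}" for j in range(4)]).fit_path(grid)
        norms = [
            sum(abs(v) for k, v in e.coefficients.items() if k != "Intercept")
            for e in path
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_aic_selection_ties_to_smaller_lambda(self):
        data = _lasso_data(seed=4)
        names = [f"x{j}" for j in range(4)]
        path = LassoAIC.from_dataframe(data, "y", names).fit_path([0.05, 0.05])
        best = select_lambda_aic(path)
        assert best.lambda_best == 0.05

    def test_single_entry_path_returned(self):
        data = _lasso_data(seed=5)
        path = LassoAIC.from_dataframe(data, "y", ["x0", "x1", "x2", "x3"]).fit_path([0.2])
        assert select_lambda_aic(path) is path.entries[0]

    def test_support_recovery_sparse_truth(self):
        # 2 active of 8 predictors at generous SNR: AIC keeps the true support
        hits = 0
        grid = np.geomspace(1e-3, 2.0, 30)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 8))
            beta = np.zeros(8)
            beta[[1, 5]] = [1.0, -1.0]
            sigma = np.sqrt(2.0 / 5.0)  # SNR = var(signal)/var(noise) = 5
            y = X @ beta + rng.normal(0, sigma, size=500)
            data = pd.DataFrame({"y": y, **{f"x{j}": X[:, j] for j in range(8)}})
            best = LassoAIC.from_dataframe(data, "y", [f"x{j}" for j in range(8)]).fit(grid)
            active = {k for k, v in best.coefficients.items() if k != "Intercept" and v != 0}
            hits += {"x1", "x5"} <= active
        assert hits == 20

    def test_invariant_to_row_order(self):
        data = _lasso_data(seed=6)
        names = [f"x{j}" for j in range(4)]
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = LassoAIC.from_dataframe(data, "y", names).fit([0.1, 0.5])
        b = LassoAIC.from_dataframe(shuffled, "y", names).fit([0.1, 0.5])
        for name in a.coefficients:
            assert a.coefficients[name] == pytest.approx(b.coefficients[name], abs=1e-8)

    def test_empty_grid_rejected(self):
        data = _lasso_data()
        with pytest.raises(ConfigurationError):
            LassoAIC.from_dataframe(data, "y", ["x0"]).fit_path([])

    def test_functional_wrapper_spec_roundtrip(self):
        data = _lasso_data(seed=8)
        spec = RegressionSpec(
            dependent="y",
            predictors=("x0", "x1", "x2", "x3"),
            family="lasso",
            lambda_grid=(0.01, 0.1, 1.0),
        )
        best = select_lambda_aic(fit_lasso(data, spec))
        assert best.lambda_best in spec.lambda_grid


class TestOLS:
    def test_exact_fit(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 2.0, 4.0]})
        res = OLSRegression.from_dataframe(data, "y", ["x"]).fit()
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.coefficients["Intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_textbook_three_points(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 3.0]})
        res = OLSRegression.from_dataframe(data, "y", ["x"]).fit()
        assert res.coefficients["x"] == pytest.approx(1.5)
        assert res.coefficients["Intercept"] == pytest.approx(-1 / 6)

    def test_row_permutation_invariant(self):
        data = _lasso_data(seed=9)
        names = [f"x{j}" for j in range(4)]
        shuffled = data.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a = OLSRegression.from_dataframe(data, "y", names).fit()
        b = OLSRegression.from_dataframe(shuffled, "y", names).fit()
        for name in a.coefficients:
            assert a.coefficients[name] == pytest.approx(b.coefficients[name], abs=1e-10)

    def test_underdetermined_rejected(self):
        data = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(DomainError):
            OLSRegression.from_dataframe(data, "y", ["x"]).fit()

    def test_functional_wrapper(self):
        data = _lasso_data(seed=10)
        spec = RegressionSpec(dependent="y", predictors=("x0",), family="ols")
        res = fit_ols(data, spec)
        assert res.p_values["x0"] < 0.01


class TestRegressionSpec:
    def test_empty_predictors_rejected(self):
        with pytest.raises(ConfigurationError):
            RegressionSpec(dependent="y", predictors=())

    def test_unsorted_lambda_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            RegressionSpec(
                dependent="y", predictors=("x",), family="lasso", lambda_grid=(1.0, 0.1)
            )
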