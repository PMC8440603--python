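"""Regression models of the pipeline, statsmodels-style.

Three model families, each a Model class whose ``fit()`` returns a Results
object with coefficients, standard errors where defined, fit indices and a
``summary()`` table:

* :class:`BetaRegression` — maximum-likelihood beta regression for a
  unit-interval response (the area ratio), logit mean link and a single
  precision parameter ``phi``; the reported pseudo-R² is the squared
  correlation between the link-transformed response and the fitted linear
  predictor (Ferrari–Cribari-Neto style).
* :class:`LassoAIC` — an L1-penalised least-squares path over a lambda grid
  with the best lambda selected by AIC, where the model degrees of freedom
  are counted as the number of nonzero coefficients (the standard LASSO df
  estimator).  Predictors are standardized internally; coefficients are
  reported on the original scale.
* :class:`OLSRegression` — ordinary least squares with classical standard
  errors and two-sided p-values.

Functional wrappers (``fit_beta_regression``, ``fit_lasso``,
``select_lambda_aic``, ``fit_ols``) mirror the same operations on a
DataFrame + :class:`RegressionSpec` pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.linear_model import Lasso

from .exceptions import ConfigurationError, DomainError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "squeeze_unit_interval",
    "BetaRegression",
    "BetaRegressionResults",
    "LassoAIC",
    "LassoPath",
    "LassoAICResults",
    "OLSRegression",
    "OLSResults",
    "fit_beta_regression",
    "fit_lasso",
    "select_lambda_aic",
    "fit_ols",
]

_INTERCEPT = "Intercept"


@dataclass(frozen=True)
class RegressionSpec:
    """Declarative description of one regression stage."""

    dependent: str
    predictors: tuple[str, ...]
    family: str = "ols"  # {"beta", "ols", "lasso"}
    link: str = "logit"
    lambda_grid: tuple[float, ...] = ()
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ConfigurationError("predictors must be nonempty")
        if self.family not in ("beta", "ols", "lasso"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "beta" and self.link != "logit":
            raise ConfigurationError("beta regression supports only the logit link")
        if list(self.lambda_grid) != sorted(self.lambda_grid):
            raise ConfigurationError("lambda_grid must be sorted ascending")


def squeeze_unit_interval(y, n: int | None = None):
    """Compress [0, 1] values into (0, 1): ``y' = (y (n - 1) + 0.5) / n``.

    The Smithson–Verkuilen boundary compression; ``n`` defaults to the
    sample size.  Needed because the beta likelihood is undefined at exactly
    0 or 1.
    """
    arr = np.asarray(y, dtype=float)
    if n is None:
        n = arr.size
    if n < 2:
        raise DomainError("squeeze requires n >= 2")
    out = (arr * (n - 1) + 0.5) / n
    return float(out) if np.isscalar(y) else out


def _design(data: pd.DataFrame, dependent: str, predictors: Sequence[str]):
    missing = [c for c in (dependent, *predictors) if c not in data.columns]
    if missing:
        raise ConfigurationError(f"columns not in data: {missing}")
    sub = data[[dependent, *predictors]]
    if sub.isna().any().any():
        raise DomainError("missing values in regression columns")
    y = sub[dependent].to_numpy(dtype=float)
    X = sub[list(predictors)].to_numpy(dtype=float)
    return y, X


# ---------------------------------------------------------------------------
# Beta regression
# ---------------------------------------------------------------------------


class BetaRegression:
    """Beta regression of a (0,1) response with logit mean link.

    The mean model is ``logit(mu_i) = x_i' beta`` with a constant precision
    ``phi``, so ``y_i ~ Beta(mu_i phi, (1 - mu_i) phi)``.  Responses exactly
    on the boundary are compressed into (0, 1) automatically (with a logged
    notice) via :func:`squeeze_unit_interval`.
    """

    def __init__(self, endog, exog, exog_names: Sequence[str]):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(exog_names)
        if self.exog.ndim != 2 or self.exog.shape[1] != len(self.exog_names):
            raise ConfigurationError("exog shape does not match exog_names")
        if np.any((self.endog < 0) | (self.endog > 1)):
            raise DomainError("beta regression requires a response in [0, 1]")
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            logger.info("boundary response values present; applying unit-interval squeeze")
            self.endog = squeeze_unit_interval(self.endog)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, dependent: str, predictors: Sequence[str]
    ) -> "BetaRegression":
        y, X = _design(data, dependent, predictors)
        X = np.column_stack([np.ones(len(y)), X])
        return cls(y, X, [_INTERCEPT, *predictors])

    def fit(self, maxiter: int = 500) -> "BetaRegressionResults":
        from statsmodels.othermod.betareg import BetaModel

        model = BetaModel(self.endog, self.exog)
        try:
            with np.errstate(all="ignore"):
                res = model.fit(maxiter=maxiter, disp=False)
        except Exception as exc:  # pragma: no cover - degenerate designs
            raise FitError(f"beta regression failed: {exc}") from exc
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        if not converged or not np.all(np.isfinite(res.params)):
            raise FitError(
                "beta regression did not converge "
                f"(retvals: {getattr(res, 'mle_retvals', {})})"
            )
        k = len(self.exog_names)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        coef = dict(zip(self.exog_names, params[:k]))
        se = dict(zip(self.exog_names, bse[:k]))
        pvals = dict(zip(self.exog_names, np.asarray(res.pvalues)[:k]))
        # precision parameter is estimated on the log scale; delta-method SE
        phi = float(np.exp(params[k]))
        phi_se = float(phi * bse[k])
        linpred = self.exog @ params[:k]
        pseudo_r2 = float(np.corrcoef(special.logit(self.endog), linpred)[0, 1] ** 2)
        return BetaRegressionResults(
            coefficients=coef,
            std_errors=se,
            p_values=pvals,
            phi=phi,
            phi_se=phi_se,
            pseudo_r2=pseudo_r2,
            log_likelihood=float(res.llf),
            aic=float(res.aic),
            n=len(self.endog),
            model=self,
        )


@dataclass
class BetaRegressionResults:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    phi: float
    phi_se: float
    pseudo_r2: float
    log_likelihood: float
    aic: float
    n: int
    model: BetaRegression = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Beta regression (logit link, constant precision)",
            f"n = {self.n}   logLik = {self.log_likelihood:.3f}   "
            f"pseudo-R2 = {self.pseudo_r2:.3f}",
            f"{'term':<38}{'coef':>10}{'se':>10}{'p':>10}",
        ]
        for name, b in self.coefficients.items():
            lines.append(
                f"{name:<38}{b:>10.3f}{self.std_errors[name]:>10.3f}"
                f"{self.p_values[name]:>10.3g}"
            )
        lines.append(f"{'phi':<38}{self.phi:>10.2f}{self.phi_se:>10.2f}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "phi": self.phi,
            "phi_se": self.phi_se,
            "pseudo_r2": self.pseudo_r2,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# LASSO with AIC-selected lambda
# ---------------------------------------------------------------------------


@dataclass
class LassoAICResults:
    """One point of the LASSO path (original-scale coefficients)."""

    coefficients: dict[str, float]
    lambda_: float
    aic: float
    rss: float
    n: int
    n_active: int
    lambda_best: float | None = None

    def summary(self) -> str:
        lines = [
            f"LASSO (lambda = {self.lambda_:.4g}, AIC = {self.aic:.2f}, "
            f"{self.n_active} active terms incl. intercept)",
            f"{'term':<54}{'coef':>12}",
        ]
        for name, b in self.coefficients.items():
            shown = f"{b:.3f}" if b != 0 else "-"
            lines.append(f"{name:<54}{shown:>12}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "lambda_best": self.lambda_best,
            "aic": self.aic,
            "n": self.n,
        }


@dataclass
class LassoPath:
    entries: list[LassoAICResults]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


class LassoAIC:
    """L1-penalised least squares over a lambda grid, lambda chosen by AIC.

    The penalty applies to standardized slopes (unit-variance predictors);
    the intercept is unpenalised and all coefficients are reported on the
    original predictor scale.  The objective at penalty ``lam`` is
    ``(1/2n) ||y - b0 - Xb||^2 + lam ||b_std||_1``, so for a single
    unit-variance predictor the solution is the soft-thresholded OLS slope
    ``sign(bhat) max(|bhat| - lam, 0)``.
    """

    def __init__(self, endog, exog, exog_names: Sequence[str], standardize: bool = True):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(exog_names)
        self.standardize = standardize
        if self.exog.shape[1] < 1:
            raise ConfigurationError("at least one predictor required")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        dependent: str,
        predictors: Sequence[str],
        standardize: bool = True,
    ) -> "LassoAIC":
        y, X = _design(data, dependent, predictors)
        return cls(y, X, list(predictors), standardize=standardize)

    def fit_path(self, lambda_grid: Sequence[float]) -> LassoPath:
        grid = [float(l) for l in lambda_grid]
        if not grid:
            raise ConfigurationError("lambda_grid is empty")
        if np.any(np.asarray(grid) < 0):
            raise ConfigurationError("lambda values must be nonnegative")
        y = self.endog
        X = self.exog
        n = len(y)
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        if self.standardize:
            if np.any(x_sd == 0):
                bad = [nm for nm, s in zip(self.exog_names, x_sd) if s == 0]
                raise DomainError(f"constant predictors cannot be standardized: {bad}")
            Z = (X - x_mean) / x_sd
        else:
            Z = X - x_mean
            x_sd = np.ones_like(x_sd)
        y_mean = y.mean()
        yc = y - y_mean

        entries = []
        for lam in sorted(grid):
            if lam == 0.0:
                beta_std, *_ = np.linalg.lstsq(Z, yc, rcond=None)
            else:
                las = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-10)
                las.fit(Z, yc)
                beta_std = las.coef_
            beta = beta_std / x_sd
            intercept = y_mean - float(x_mean @ beta)
            resid = y - intercept - X @ beta
            rss = float(resid @ resid)
            k = 1 + int(np.count_nonzero(beta_std))
            aic = n * np.log(rss / n) + 2 * k
            coefs = {_INTERCEPT: intercept}
            coefs.update(dict(zip(self.exog_names, beta)))
            entries.append(
                LassoAICResults(
                    coefficients=coefs,
                    lambda_=lam,
                    aic=float(aic),
                    rss=rss,
                    n=n,
                    n_active=k,
                )
            )
        return LassoPath(entries)

    def fit(self, lambda_grid: Sequence[float]) -> LassoAICResults:
        return select_lambda_aic(self.fit_path(lambda_grid))


def select_lambda_aic(path: LassoPath) -> LassoAICResults:
    """The path entry minimising AIC; ties go to the smaller lambda."""
    entries = list(path)
    if not entries:
        raise ConfigurationError("empty lasso path")
    best = min(entries, key=lambda e: (e.aic, e.lambda_))
    best.lambda_best = best.lambda_
    return best


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


@dataclass
class OLSResults:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    log_likelihood: float
    aic: float
    n: int

    def summary(self) -> str:
        lines = [
            f"OLS   n = {self.n}   R2 = {self.r_squared:.3f}",
            f"{'term':<38}{'coef':>10}{'se':>10}{'p':>10}",
        ]
        for name, b in self.coefficients.items():
            lines.append(
                f"{name:<38}{b:>10.3f}{self.std_errors[name]:>10.3f}"
                f"{self.p_values[name]:>10.3g}"
            )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
        }


class OLSRegression:
    """Ordinary least squares with classical SEs and two-sided p-values."""

    def __init__(self, endog, exog, exog_names: Sequence[str]):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.exog_names = list(exog_names)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, dependent: str, predictors: Sequence[str]
    ) -> "OLSRegression":
        y, X = _design(data, dependent, predictors)
        X = np.column_stack([np.ones(len(y)), X])
        return cls(y, X, [_INTERCEPT, *predictors])

    def fit(self) -> OLSResults:
        import statsmodels.api as sm

        n, p = self.exog.shape
        if n <= p:
            raise DomainError(f"n = {n} observations cannot fit {p} parameters")
        res = sm.OLS(self.endog, self.exog).fit()
        return OLSResults(
            coefficients=dict(zip(self.exog_names, res.params)),
            std_errors=dict(zip(self.exog_names, res.bse)),
            p_values=dict(zip(self.exog_names, res.pvalues)),
            r_squared=float(res.rsquared),
            log_likelihood=float(res.llf),
            aic=float(res.aic),
            n=n,
        )


# ---------------------------------------------------------------------------
# Functional wrappers over (data, spec)
# ---------------------------------------------------------------------------


def fit_beta_regression(data: pd.DataFrame, spec: RegressionSpec) -> BetaRegressionResults:
    if spec.family != "beta":
        raise ConfigurationError(f"spec family is {spec.family!r}, expected 'beta'")
    return BetaRegression.from_dataframe(data, spec.dependent, spec.predictors).fit()


def fit_lasso(data: pd.DataFrame, spec: RegressionSpec) -> LassoPath:
    if spec.family != "lasso":
        raise ConfigurationError(f"spec family is {spec.family!r}, expected 'lasso'")
    model = LassoAIC.from_dataframe(
        data, spec.dependent, spec.predictors, standardize=spec.standardize
    )
    return model.fit_path(spec.lambda_grid)


def fit_ols(data: pd.DataFrame, spec: RegressionSpec) -> OLSResults:
    if spec.family != "ols":
        raise ConfigurationError(f"spec family is {spec.family!r}, expected 'ols'")
    return OLSRegression.from_dataframe(data, spec.dependent, spec.predictors).fit()


def default_lambda_grid(num: int = 50, lo: float = 1e-3, hi: float = 10.0) -> tuple[float, ...]:
    """Log-spaced lambda grid, ascending."""
    return tuple(np.geomspace(lo, hi, num))
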