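"""Two-part structural path model (mediation analysis).

The model decomposes the effect of a predictor (amount of professional
knowledge) on an outcome (creative-performance novelty score) into a direct
path and an indirect path through a mediator (the area-ratio attention
proxy):

* part 1: ``mediator ~ knowledge (+ covariates)`` gives path ``a``;
* part 2: ``outcome ~ mediator + knowledge (+ covariates)`` gives the
  mediator path ``b`` and the direct path ``c'``;
* the indirect effect is the product ``a * b`` and the total effect comes
  from ``outcome ~ knowledge (+ covariates)``.

With OLS path regressions and identical covariate sets in every part, the
mediation identity ``total = c' + a*b`` holds to machine precision; this
estimator gives the same point estimates as a saturated linear structural
equation model for this graph.  Uncertainty for the indirect effect is
available as the Sobel (delta-method) standard error or as a seeded
nonparametric bootstrap over participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError
from .regression import OLSRegression

__all__ = ["PathModel", "PathModelResult", "fit_path_model"]


@dataclass
class PathModelResult:
    """Direct, indirect and total effects with SEs and p-values."""

    a: float
    b: float
    c_prime: float
    total: float
    indirect: float
    std_errors: dict[str, float]
    p_values: dict[str, float]
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("a (knowledge -> mediator)", self.a),
            ("b (mediator -> outcome)", self.b),
            ("c' (direct)", self.c_prime),
            ("indirect (a*b)", self.indirect),
            ("total", self.total),
        ]
        keymap = {
            "a (knowledge -> mediator)": "a",
            "b (mediator -> outcome)": "b",
            "c' (direct)": "c_prime",
            "indirect (a*b)": "indirect",
            "total": "total",
        }
        lines = [
            f"Path model (OLS paths)   n = {self.n}",
            f"{'path':<30}{'est':>10}{'se':>10}{'p':>10}",
        ]
        for label, est in rows:
            key = keymap[label]
            se = self.std_errors.get(key, float("nan"))
            p = self.p_values.get(key, float("nan"))
            lines.append(f"{label:<30}{est:>10.4f}{se:>10.4f}{p:>10.3g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c_prime": self.c_prime,
            "indirect": self.indirect,
            "total": self.total,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n": self.n,
        }


class PathModel:
    """Mediation path model fitted by seemingly-unrelated OLS regressions."""

    def __init__(self, knowledge, mediator, outcome, covariates: pd.DataFrame | None = None):
        self.knowledge = np.asarray(knowledge, dtype=float)
        self.mediator = np.asarray(mediator, dtype=float)
        self.outcome = np.asarray(outcome, dtype=float)
        n = self.knowledge.size
        if not (self.mediator.size == n == self.outcome.size):
            raise DomainError("knowledge, mediator and outcome must have equal length")
        if n < 10:
            raise DomainError(f"need at least 10 observations, got {n}")
        if np.std(self.mediator) == 0:
            raise DomainError("mediator is constant")
        if covariates is not None:
            covariates = pd.DataFrame(covariates)
            if len(covariates) != n:
                raise DomainError("covariate table length mismatch")
        self.covariates = covariates

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        knowledge: str,
        mediator: str,
        outcome: str,
        covariates: list[str] | None = None,
    ) -> "PathModel":
        cov = data[covariates] if covariates else None
        return cls(data[knowledge], data[mediator], data[outcome], cov)

    def _cov_block(self):
        if self.covariates is None:
            return np.empty((self.knowledge.size, 0)), []
        return self.covariates.to_numpy(dtype=float), list(self.covariates.columns)

    def fit(self, ci: str = "delta", n_boot: int = 5000, seed: int | None = None) -> PathModelResult:
        """Fit the three path regressions.

        ``ci="delta"`` uses the Sobel SE for the indirect effect;
        ``ci="bootstrap"`` adds a percentile bootstrap SE/CI over ``n_boot``
        seeded resamples of participants.
        """
        if ci not in ("delta", "bootstrap"):
            raise ConfigurationError(f"unknown ci method {ci!r}")
        C, cov_names = self._cov_block()
        n = self.knowledge.size
        ones = np.ones(n)

        def _ols(y, cols, names):
            X = np.column_stack([ones, *cols])
            return OLSRegression(y, X, ["Intercept", *names]).fit()

        part1 = _ols(self.mediator, [self.knowledge, C], ["knowledge", *cov_names])
        part2 = _ols(
            self.outcome,
            [self.mediator, self.knowledge, C],
            ["mediator", "knowledge", *cov_names],
        )
        total_fit = _ols(self.outcome, [self.knowledge, C], ["knowledge", *cov_names])

        a = part1.coefficients["knowledge"]
        b = part2.coefficients["mediator"]
        c_prime = part2.coefficients["knowledge"]
        total = total_fit.coefficients["knowledge"]
        indirect = a * b

        se_a = part1.std_errors["knowledge"]
        se_b = part2.std_errors["mediator"]
        sobel_se = math.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
        std_errors = {
            "a": se_a,
            "b": se_b,
            "c_prime": part2.std_errors["knowledge"],
            "total": total_fit.std_errors["knowledge"],
            "indirect": sobel_se,
        }
        p_values = {
            "a": part1.p_values["knowledge"],
            "b": part2.p_values["mediator"],
            "c_prime": part2.p_values["knowledge"],
            "total": total_fit.p_values["knowledge"],
            "indirect": 2 * stats.norm.sf(abs(indirect) / sobel_se) if sobel_se > 0 else 1.0,
        }
        cis: dict[str, tuple[float, float]] = {}

        if ci == "bootstrap":
            rng = np.random.default_rng(seed)
            boot = np.empty(n_boot)
            X_parts = (self.knowledge, self.mediator, self.outcome)
            for i in range(n_boot):
                idx = rng.integers(0, n, size=n)
                k_b, m_b, y_b = (arr[idx] for arr in X_parts)
                C_b = C[idx]
                f1 = _ols(m_b, [k_b, C_b], ["knowledge", *cov_names])
                f2 = _ols(y_b, [m_b, k_b, C_b], ["mediator", "knowledge", *cov_names])
                boot[i] = f1.coefficients["knowledge"] * f2.coefficients["mediator"]
            std_errors["indirect"] = float(np.std(boot, ddof=1))
            lo, hi = np.quantile(boot, [0.025, 0.975])
            cis["indirect"] = (float(lo), float(hi))
            # percentile-bootstrap two-sided p for the null of no indirect effect
            frac = np.mean(boot < 0)
            p_values["indirect"] = float(min(1.0, 2 * min(frac, 1 - frac) + 1 / n_boot))

        return PathModelResult(
            a=float(a),
            b=float(b),
            c_prime=float(c_prime),
            total=float(total),
            indirect=float(indirect),
            std_errors={k: float(v) for k, v in std_errors.items()},
            p_values={k: float(v) for k, v in p_values.items()},
            n=n,
            ci=cis,
        )


def fit_path_model(
    knowledge,
    mediator,
    outcome,
    covariates: pd.DataFrame | None = None,
    estimator: str = "ols_paths",
    ci: str = "delta",
    n_boot: int = 5000,
    seed: int | None = None,
) -> PathModelResult:
    """Functional wrapper around :class:`PathModel`."""
    if estimator != "ols_paths":
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    return PathModel(knowledge, mediator, outcome, covariates).fit(
        ci=ci, n_boot=n_boot, seed=seed
    )
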