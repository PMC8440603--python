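"""Group-level comparisons: quantile splits, t-tests with effect size r,
bootstrap resampling, and metric correlation matrices.

The analysis splits participants into the top and bottom quantile (default
25%) of one metric and compares another metric between the two groups.
Unit-interval metrics (area ratios) may be variance-stabilised before the
test with the transform ``x -> arcsin(x^2)``.  Effect sizes are reported as
``r = sqrt(t^2 / (t^2 + df))``, the standard t-to-r conversion.  For skewed
outcomes (ordinal rating medians) a seeded bootstrap comparison is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError, FitError

__all__ = [
    "arcsine_transform",
    "GroupSplit",
    "quartile_split",
    "ComparisonResult",
    "two_sample_t",
    "compare_groups",
    "bootstrap_compare",
    "correlation_matrix",
]


def arcsine_transform(x):
    """Variance-stabilising transform ``arcsin(x^2)`` for ratios in [0, 1].

    Strictly increasing on [0, 1] with range [0, pi/2]; values outside
    [0, 1] raise :class:`DomainError`.
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError("arcsine transform requires values in [0, 1]")
    out = np.arcsin(arr**2)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


@dataclass(frozen=True)
class GroupSplit:
    """Top- and bottom-quantile id groups on one metric."""

    metric_name: str
    top_ids: tuple
    bottom_ids: tuple
    quantile: float


def quartile_split(
    values: pd.DataFrame, quantile: float = 0.25, metric: str | None = None
) -> GroupSplit:
    """Split ids into the top and bottom ``quantile`` of a metric.

    ``values`` needs an id column (first) and a metric column (second, or
    named by ``metric``).  Rows are sorted by (metric, id) so ties break
    deterministically by id; each group has ``floor(quantile * n)`` members.
    """
    if not 0 < quantile <= 0.5:
        raise ConfigurationError(f"quantile must be in (0, 0.5], got {quantile}")
    id_col = values.columns[0]
    metric = metric or values.columns[1]
    n = len(values)
    k = int(math.floor(quantile * n))
    if k < 1:
        raise DomainError(
            f"{n} rows are too few for a {quantile:.0%} split (group size 0)"
        )
    ordered = values.sort_values([metric, id_col], kind="mergesort")
    bottom = tuple(ordered[id_col].iloc[:k])
    top = tuple(ordered[id_col].iloc[-k:])
    return GroupSplit(metric_name=metric, top_ids=top, bottom_ids=bottom, quantile=quantile)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison with t statistic and effect size r."""

    mean_top: float
    mean_bottom: float
    mean_top_transformed: float
    mean_bottom_transformed: float
    t: float
    df: float
    p_value: float
    effect_r: float
    n_top: int
    n_bottom: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _effect_r(t: float, df: float) -> float:
    return math.sqrt(t * t / (t * t + df)) if df > 0 else 0.0


def two_sample_t(a, b, variant: str = "student") -> ComparisonResult:
    """Two-sided two-sample t-test with effect size ``r``.

    ``variant="student"`` uses the pooled-variance test with
    ``df = n_a + n_b - 2``; ``"welch"`` uses the Welch–Satterthwaite df.
    When both groups have zero variance and equal means, ``t = 0`` by
    convention; zero pooled variance with unequal means raises
    :class:`FitError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")

    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            df = float(a.size + b.size - 2)
            return ComparisonResult(
                mean_top=float(a.mean()),
                mean_bottom=float(b.mean()),
                mean_top_transformed=float(a.mean()),
                mean_bottom_transformed=float(b.mean()),
                t=0.0,
                df=df,
                p_value=1.0,
                effect_r=0.0,
                n_top=a.size,
                n_bottom=b.size,
            )
        raise FitError("zero variance in both groups with unequal means")

    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    t = float(res.statistic)
    df = float(res.df)
    return ComparisonResult(
        mean_top=float(a.mean()),
        mean_bottom=float(b.mean()),
        mean_top_transformed=float(a.mean()),
        mean_bottom_transformed=float(b.mean()),
        t=t,
        df=df,
        p_value=float(res.pvalue),
        effect_r=_effect_r(t, df),
        n_top=a.size,
        n_bottom=b.size,
    )


def compare_groups(
    data: pd.DataFrame,
    split_by: str,
    metric: str,
    quantile: float = 0.25,
    transform: str | None = None,
    variant: str = "student",
    id_col: str | None = None,
) -> ComparisonResult:
    """Quantile-split ``data`` on ``split_by`` and t-test ``metric``.

    ``transform="arcsine_x2"`` applies the arcsine transform to the metric
    before the test; group means are reported on both the raw and the
    transformed scale.
    """
    id_col = id_col or data.columns[0]
    split = quartile_split(data[[id_col, split_by]], quantile=quantile)
    indexed = data.set_index(id_col)
    raw_top = indexed.loc[list(split.top_ids), metric].to_numpy(dtype=float)
    raw_bottom = indexed.loc[list(split.bottom_ids), metric].to_numpy(dtype=float)
    if transform in (None, "none"):
        top, bottom = raw_top, raw_bottom
    elif transform == "arcsine_x2":
        top, bottom = arcsine_transform(raw_top), arcsine_transform(raw_bottom)
    else:
        raise ConfigurationError(f"unknown transform {transform!r}")
    res = two_sample_t(top, bottom, variant=variant)
    return ComparisonResult(
        mean_top=float(raw_top.mean()),
        mean_bottom=float(raw_bottom.mean()),
        mean_top_transformed=float(np.mean(top)),
        mean_bottom_transformed=float(np.mean(bottom)),
        t=res.t,
        df=res.df,
        p_value=res.p_value,
        effect_r=res.effect_r,
        n_top=res.n_top,
        n_bottom=res.n_bottom,
    )


def bootstrap_compare(
    a,
    b,
    B: int = 10_000,
    seed: int | None = None,
    statistic: str = "mean_diff",
    ci_level: float = 0.95,
) -> dict:
    """Seeded bootstrap comparison of two groups.

    Each group is resampled with replacement ``B`` times.  The two-sided
    p-value is the percentile position of 0 in the null-centred bootstrap
    distribution of the statistic (``"mean_diff"`` or the t statistic
    ``"t"``), and the CI is the percentile interval of the statistic.
    """
    if B < 100:
        raise ConfigurationError(f"B must be at least 100, got {B}")
    if statistic not in ("mean_diff", "t"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)

    def stat(x, y):
        if statistic == "mean_diff":
            return x.mean(axis=-1) - y.mean(axis=-1)
        va = x.var(axis=-1, ddof=1) / x.shape[-1]
        vb = y.var(axis=-1, ddof=1) / y.shape[-1]
        denom = np.sqrt(va + vb)
        diff = x.mean(axis=-1) - y.mean(axis=-1)
        return np.divide(diff, denom, out=np.zeros_like(diff + 0.0), where=denom > 0)

    observed = float(stat(a, b))
    ra = rng.choice(a, size=(B, a.size), replace=True)
    rb = rng.choice(b, size=(B, b.size), replace=True)
    boot = stat(ra, rb)
    # null-centred two-sided percentile p; +1 correction avoids p = 0
    centred = boot - observed
    p = (np.count_nonzero(np.abs(centred) >= abs(observed)) + 1) / (B + 1)
    alpha = 1 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "stat": observed,
        "p_value": float(min(1.0, p)),
        "ci": (float(lo), float(hi)),
        "B": B,
        "statistic": statistic,
    }


def correlation_matrix(
    table: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete correlation matrix with two-sided p-values.

    Returns ``(corr, pvalues)`` data frames over the numeric columns of
    ``table``; at least 3 complete rows per pair are required.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    cols = table.select_dtypes(include=[np.number]).columns
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            pair = table[[ci, cj]].dropna()
            if len(pair) < 3:
                raise DomainError(
                    f"columns {ci!r}/{cj!r} share fewer than 3 complete rows"
                )
            r, p = func(pair[ci], pair[cj])
            corr.loc[ci, cj] = corr.loc[cj, ci] = float(r)
            pvals.loc[ci, cj] = pvals.loc[cj, ci] = float(p)
    return corr, pvals
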