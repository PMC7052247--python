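"""The statistical battery: OLS with per-coefficient t-tests,
SEM-weighted least squares on CCV aggregates, pooled two-sample t-test
and one-way ANOVA, all at alpha = 0.01 (chosen to compensate for the
multiplicity of comparisons).

Regressions are fitted with statsmodels behind this surface; the
pooled t and ANOVA come from scipy.stats with dfs made explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TermResult",
    "StatResult",
    "CCVAggregate",
    "ols_regression",
    "wls_regression",
    "two_sample_ttest",
    "one_way_anova",
    "aggregate_by_ccv",
]

ALPHA = 0.01


@dataclass(frozen=True)
class TermResult:
    name: str
    estimate: float
    se: float
    statistic: float
    df: float
    p: float


@dataclass(frozen=True)
class StatResult:
    """One test or model fit: per-term estimates and test statistics."""

    kind: str  # ols | wls | ttest | anova
    terms: tuple[TermResult, ...]
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        for t in self.terms:
            if t.df <= 0:
                raise ValueError(f"term {t.name}: df must be positive")
            if not (0.0 <= t.p <= 1.0):
                raise ValueError(f"term {t.name}: p outside [0, 1]")

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def significant(self, name: str) -> bool:
        return self.term(name).p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([t.__dict__ for t in self.terms])
        df["kind"] = self.kind
        df["significant"] = df["p"] < self.alpha
        return df


@dataclass(frozen=True)
class CCVAggregate:
    """Per-CCV mean and SEM of one or more variables (SEM = SD/sqrt(n))."""

    ccv: str
    n: int
    means: dict
    sems: dict

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("aggregate needs at least 2 trials")


def _frame(y, predictors) -> tuple[np.ndarray, pd.DataFrame]:
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors)
    if len(X) != y.size:
        raise ValueError("y and predictors must have equal length")
    return y, X


def ols_regression(y, predictors, alpha: float = ALPHA) -> StatResult:
    """Multiple linear regression with two-sided t-tests per
    coefficient; residual df = n - p - 1 (intercept included)."""
    y, X = _frame(y, predictors)
    Xc = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, Xc).fit()
    return _from_sm(fit, "ols", alpha)


def _from_sm(fit, kind: str, alpha: float) -> StatResult:
    terms = tuple(
        TermResult(
            name=str(name),
            estimate=float(fit.params[name]),
            se=float(fit.bse[name]),
            statistic=float(fit.tvalues[name]),
            df=float(fit.df_resid),
            p=float(fit.pvalues[name]),
        )
        for name in fit.params.index
    )
    return StatResult(kind=kind, terms=terms, alpha=alpha)


def wls_regression(
    aggregates: list[CCVAggregate],
    y_var: str,
    x_var: str,
    alpha: float = ALPHA,
) -> StatResult:
    """Simple regression across CCV aggregates weighted by the
    statistical errors of the dependent variable: w = 1 / SEM(y)^2.

    With the 15 analysis CCVs the slope t-test has df = 13. Equal SEMs
    reduce the fit to ordinary least squares exactly.
    """
    if len(aggregates) < 3:
        raise ValueError("need at least 3 aggregates")
    y = np.array([a.means[y_var] for a in aggregates])
    x = np.array([a.means[x_var] for a in aggregates])
    sem = np.array([a.sems[y_var] for a in aggregates])
    if np.any(sem <= 0):
        raise ValueError("SEM of the dependent variable must be positive")
    Xc = sm.add_constant(pd.DataFrame({x_var: x}))
    fit = sm.WLS(y, Xc, weights=1.0 / sem**2).fit()
    return _from_sm(fit, "wls", alpha)


def two_sample_ttest(a, b, alpha: float = ALPHA) -> StatResult:
    """Pooled-variance Student t-test, df = n1 + n2 - 2, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    df = a.size + b.size - 2
    var_pooled = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    diff = a.mean() - b.mean()
    if var_pooled == 0.0:
        if diff != 0.0:
            raise ZeroDivisionError("zero pooled variance with unequal means")
        t_stat, p, se = 0.0, 1.0, 0.0
    else:
        se = float(np.sqrt(var_pooled * (1.0 / a.size + 1.0 / b.size)))
        t_stat = float(diff / se)
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    term = TermResult("mean_difference", float(diff), se, t_stat, df, p)
    return StatResult(kind="ttest", terms=(term,), alpha=alpha)


def one_way_anova(groups, alpha: float = ALPHA) -> StatResult:
    """One-way ANOVA over k groups: F with (k - 1, N - k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    f_stat, p = stats.f_oneway(*groups)
    term = TermResult(
        name="between_groups",
        estimate=float(f_stat),
        se=float("nan"),
        statistic=float(f_stat),
        df=float(n_total - k),  # denominator df; numerator df = k - 1
        p=float(p),
    )
    return StatResult(kind="anova", terms=(term,), alpha=alpha)


def aggregate_by_ccv(
    records: pd.DataFrame, variables, min_n: int = 2
) -> list[CCVAggregate]:
    """Per-CCV mean and SEM of each variable, across participants and
    repetitions. CCVs with fewer than ``min_n`` valid trials are
    dropped with a warning."""
    import warnings

    out = []
    for ccv, group in records.groupby("ccv", sort=True):
        n = len(group)
        if n < min_n:
            warnings.warn(f"{ccv}: only {n} trial(s); dropped from aggregates")
            continue
        means, sems = {}, {}
        for var in variables:
            vals = group[var].dropna()
            if len(vals) < min_n:
                warnings.warn(f"{ccv}: fewer than {min_n} values of {var}")
                continue
            means[var] = float(vals.mean())
            sems[var] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        out.append(CCVAggregate(ccv=str(ccv), n=n, means=means, sems=sems))
    return out
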