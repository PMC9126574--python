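"""Variable screening for the head-circumference cutoff model.

Step one of the cutoff definition asks which covariates are associated
with HC: Spearman rank correlations for the continuous covariates, an
independent-samples t-test for sex, and a multivariate ordinary
least-squares regression of HC on all candidates. The three statistics
are implemented from first principles (average ranks + Pearson formula,
pooled-variance t, normal equations); only the t distribution's tail
function is taken from scipy.

Significance is judged two-tailed at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, StatisticError

__all__ = [
    "ScreeningResult",
    "ScreeningReport",
    "average_ranks",
    "spearman_rho",
    "two_sample_t",
    "ols_fit",
    "screen_variables",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ScreeningResult:
    """One association test: estimate, interval (OLS only), p-value."""

    variable: str
    method: str  # "spearman" | "t_test" | "ols"
    estimate: float
    p_value: float
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "method": self.method,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class ScreeningReport:
    results: list[ScreeningResult]
    significant: set[str]

    def to_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "significant": sorted(self.significant),
        }


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean of the tied ranks."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> ScreeningResult:
    """Spearman rank correlation with a t-approximation p-value.

    rho is the Pearson correlation of average-ranked values; the
    p-value uses t = rho * sqrt((n-2)/(1-rho^2)) on n − 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise StatisticError(f"need at least 3 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatisticError("inputs must be finite")
    rx, ry = average_ranks(x), average_ranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0.0:
        raise StatisticError("correlation undefined for a constant vector")
    rho = float((sx @ sy) / denom)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return ScreeningResult(variable="", method="spearman", estimate=rho, p_value=p)


def two_sample_t(values_a, values_b, welch: bool = False) -> ScreeningResult:
    """Independent-samples t-test (pooled variance by default).

    With ``welch=True`` uses Welch's unequal-variance statistic and
    Satterthwaite degrees of freedom instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            return _degenerate_t(ma, mb)
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0.0:
            return _degenerate_t(ma, mb)
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ScreeningResult(variable="", method="t_test", estimate=float(t), p_value=p)


def _degenerate_t(ma: float, mb: float) -> ScreeningResult:
    if ma == mb:
        return ScreeningResult(variable="", method="t_test", estimate=0.0, p_value=1.0)
    raise StatisticError("zero variance in both groups with unequal means")


def ols_fit(outcome, predictors: pd.DataFrame | dict) -> list[ScreeningResult]:
    """Ordinary least squares with 95% CIs via the t distribution.

    ``predictors`` maps names to columns; an intercept is always added.
    Coefficients solve the normal equations; the covariance of the
    estimates is s² (XᵀX)⁻¹ with s² = RSS/(n − p − 1). Rank-deficient
    designs raise :class:`CollinearityError` naming offending columns.
    """
    X_named = pd.DataFrame(predictors)
    y = np.asarray(outcome, dtype=float)
    n, p = X_named.shape
    if y.shape != (n,):
        raise StatisticError("outcome length does not match predictors")
    if n <= p + 1:
        raise StatisticError(
            f"need more than {p + 1} observations for {p} predictors, got {n}"
        )
    names = ["intercept", *X_named.columns.astype(str)]
    X = np.column_stack([np.ones(n), X_named.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient; offending column(s): "
            + ", ".join(_collinear_columns(X, names))
        )
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tcrit = float(stats.t.ppf(0.975, df))
    results = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, name in enumerate(names):
            if se[i] == 0.0:
                pval = 0.0 if beta[i] != 0.0 else 1.0
            else:
                tval = beta[i] / se[i]
                pval = float(2.0 * stats.t.sf(abs(tval), df))
            results.append(
                ScreeningResult(
                    variable=name,
                    method="ols",
                    estimate=float(beta[i]),
                    ci_low=float(beta[i] - tcrit * se[i]),
                    ci_high=float(beta[i] + tcrit * se[i]),
                    p_value=pval,
                )
            )
    return results


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (excluding the intercept)."""
    full = np.linalg.matrix_rank(X)
    offending = []
    for i in range(1, X.shape[1]):
        reduced = np.delete(X, i, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            offending.append(names[i])
    return offending or names[1:]


def screen_variables(cohort: pd.DataFrame) -> ScreeningReport:
    """Run the full screening battery on a cohort.

    Spearman correlations of HC with brain volume, height, age and
    education; a pooled t-test of HC by sex; then one multivariate OLS
    of HC on brain volume, age, sex (female = 1) education, and height
    in cm. A variable is reported significant if it crosses alpha in
    the multivariate model (the intercept is never included).
    """
    if cohort.empty:
        raise StatisticError("cohort is empty")
    hc = cohort["hc_cm"].to_numpy(dtype=float)
    results: list[ScreeningResult] = []
    for name, column in (
        ("brain_volume_ml", "brain_volume_ml"),
        ("height_m", "height_m"),
        ("age", "age"),
        ("education_years", "education_years"),
    ):
        r = spearman_rho(cohort[column].to_numpy(dtype=float), hc)
        results.append(
            ScreeningResult(name, "spearman", r.estimate, r.p_value)
        )
    male = cohort.loc[cohort["sex"] == "male", "hc_cm"].to_numpy(dtype=float)
    female = cohort.loc[cohort["sex"] == "female", "hc_cm"].to_numpy(dtype=float)
    t = two_sample_t(male, female)
    results.append(ScreeningResult("sex", "t_test", t.estimate, t.p_value))

    predictors = pd.DataFrame(
        {
            "brain_volume_ml": cohort["brain_volume_ml"].to_numpy(dtype=float),
            "age": cohort["age"].to_numpy(dtype=float),
            "sex_female": (cohort["sex"] == "female").to_numpy(dtype=float),
            "education_years": cohort["education_years"].to_numpy(dtype=float),
            "height_cm": cohort["height_m"].to_numpy(dtype=float) * 100.0,
        }
    )
    ols = ols_fit(hc, predictors)
    results.extend(ols)
    significant = {r.variable for r in ols if r.variable != "intercept" and r.significant}
    return ScreeningReport(results=results, significant=significant)
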