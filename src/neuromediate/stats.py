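"""Phenotype-level statistics.

Outlier exclusion by the 3-IQR-from-the-mean rule, covariate residualization,
partial correlation, incremental R² of a polygenic score over nuisance
covariates, and the a-priori sample size for a fixed-model multiple-regression
F test via the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class PowerQuery:
    """A-priori power query for the R²-deviation-from-zero F test.

    f2 is Cohen's effect size f² = R²/(1−R²); the test has numerator df equal
    to the number of predictors and noncentrality λ = f²·N.
    """

    f2: float
    alpha: float = 0.05
    power: float = 0.95
    n_predictors: int = 1

    def __post_init__(self) -> None:
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.alpha < self.power < 1:
            raise ValueError("power target must lie in (alpha, 1)")
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")


@dataclass
class OutlierReport:
    """Per-analysis-stream exclusions; a flagged subject is dropped wholesale."""

    excluded: dict[str, list[str]]  # stream -> subject ids

    def n_excluded(self, stream: str) -> int:
        return len(self.excluded.get(stream, []))


def flag_outliers(values) -> np.ndarray:
    """Flag values deviating more than three interquartile ranges from the mean.

    Quartiles use linear interpolation between order statistics (the numpy
    default).  A constant vector has IQR 0 and deviations 0, so nothing is
    flagged.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values to estimate quartiles")
    v = values[finite]
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    flags = np.zeros(values.shape, dtype=bool)
    flags[finite] = np.abs(v - v.mean()) > 3 * iqr
    return flags


def _design(covariates, n: int) -> np.ndarray:
    """Covariate matrix with an intercept column prepended; validates rank."""
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    X = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column that adds no rank
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"covariate column {j - 1} is collinear with the others")
        raise ValueError("rank-deficient covariate matrix")
    return X


def residualize(values, covariates=None, standardize: bool = False) -> np.ndarray:
    """Least-squares residuals of ``values`` on [intercept, covariates].

    Residuals have mean 0 and are orthogonal to every covariate column; with
    ``standardize=True`` they are additionally z-scored.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    X = _design(covariates, n)
    if n <= X.shape[1]:
        raise ValueError("need more observations than covariates plus intercept")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    if standardize:
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance residuals cannot be standardized")
        resid = resid / sd
    return resid


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized x and y, with 2-tailed p.

    The p-value accounts for the covariate degrees of freedom: with k
    covariates, df = n − 2 − k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    if rx.std(ddof=1) == 0 or ry.std(ddof=1) == 0:
        raise ValueError("zero-variance residuals: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    df = len(x) - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for a p-value")
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    tstat = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = 2 * stats.t.sf(abs(tstat), df)
    return r, float(p)


def incremental_r2(outcome, covariates, predictor) -> float:
    """ΔR² from adding ``predictor`` to the covariate-only regression.

    Equals the squared semi-partial correlation of the predictor with the
    outcome; non-negative in sample by nesting.
    """
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.shape[0]
    X0 = _design(covariates, n)
    pred = np.asarray(predictor, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    X1 = np.column_stack([X0, pred])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        # predictor inside the covariate span: adds nothing
        return 0.0
    r2_0 = sm.OLS(outcome, X0).fit().rsquared
    r2_1 = sm.OLS(outcome, X1).fit().rsquared
    return float(max(r2_1 - r2_0, 0.0))


def f_test_power(n: int, query: PowerQuery) -> float:
    """Power of the fixed-model R²-deviation F test at total sample size n.

    Noncentrality λ = f²·n, df1 = number of predictors, df2 = n − predictors − 1.
    """
    df1 = query.n_predictors
    df2 = n - query.n_predictors - 1
    if df2 < 1:
        return 0.0
    crit = stats.f.isf(query.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, query.f2 * n))


def required_sample_size(query: PowerQuery, n_max: int = 1_000_000) -> int:
    """Smallest N whose F-test power reaches the target.

    Scans N upward from the minimal admissible size (predictors + 2, one
    residual df); power is non-decreasing in N so the first hit is minimal.
    """
    n = query.n_predictors + 2
    while n <= n_max:
        if f_test_power(n, query) >= query.power:
            return n
        n += 1
    raise ValueError(f"target power not attainable below N={n_max}")


def stream_outliers(
    table: pd.DataFrame, streams: dict[str, list[str]], id_col: str = "subject"
) -> OutlierReport:
    """Apply the 3-IQR rule per analysis stream.

    ``streams`` maps a stream name (e.g. "anatomical") to the variables whose
    outliers exclude a subject from that stream; a subject flagged on any of
    them is removed from that stream only.
    """
    excluded: dict[str, list[str]] = {}
    for stream, variables in streams.items():
        flagged = np.zeros(len(table), dtype=bool)
        for var in variables:
            flagged |= flag_outliers(table[var].to_numpy())
        excluded[stream] = table.loc[flagged, id_col].astype(str).tolist()
    return OutlierReport(excluded=excluded)
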