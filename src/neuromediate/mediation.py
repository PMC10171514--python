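"""Mediation models linking a polygenic score to intelligence via brain metrics.

Two layers:

* :func:`mediate_single` — the classic product-of-coefficients model for one
  mediator (a: X→M; b: M→Y adjusted for X; c′: direct effect), with Sobel,
  heteroskedasticity-robust, or percentile-bootstrap uncertainty.

* :func:`regularized_mediation` — exploratory mediation over hundreds of
  candidate mediators.  Path b is an elastic-net regression of the outcome on
  all mediators with the exposure included *unpenalized*; path a is a
  multi-response penalized regression of the mediators on the exposure with a
  shared penalty.  Candidates whose penalized product |a_j·b_j| clears a
  threshold are selected and refit without penalty for debiased effect sizes.

Penalties use the glmnet parameterization
``(1/2n)·RSS + λ(α·|β|₁ + (1−α)/2·|β|₂²)`` with the mixing weight α chosen by
``elastic_net_mixing``; λ is picked by k-fold cross-validation at the minimum
mean squared prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV, LinearRegression
from sklearn.model_selection import KFold


@dataclass
class MediationPaths:
    """Estimated paths of a single-mediator model with uncertainty."""

    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    se: dict = field(default_factory=dict)  # path -> standard error
    p: dict = field(default_factory=dict)  # path -> p-value
    ci_indirect: tuple[float, float] | None = None  # bootstrap percentile CI
    n: int = 0


@dataclass
class RegularizedMediationConfig:
    """Settings for exploratory mediation by regularization."""

    k_folds: int = 80
    mediation_threshold: float = 0.001  # on |a_j * b_j|
    path_threshold: float = 0.01  # on |a_j| or |b_j| alone
    elastic_net_mixing: float = 0.5  # 1 = lasso, 0 = ridge
    n_penalties: int = 100
    penalty_eps: float = 1e-3  # smallest / largest penalty ratio
    cv_seed: int = 0
    penalty_override: float | None = None  # fixed λ instead of CV (0 = OLS)
    path_a_direction: str = "mediators_on_x"  # or "x_on_mediators"

    def __post_init__(self) -> None:
        if self.mediation_threshold <= 0 or self.path_threshold <= 0:
            raise ValueError("selection thresholds must be positive")
        if not 0 <= self.elastic_net_mixing <= 1:
            raise ValueError("elastic_net_mixing must lie in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.path_a_direction not in ("mediators_on_x", "x_on_mediators"):
            raise ValueError("unknown path_a_direction")


@dataclass
class RegularizedMediationResult:
    """Penalized estimates, the selected set, and the unpenalized refit."""

    mediator_ids: list[str]
    a: np.ndarray  # penalized a_j
    b: np.ndarray  # penalized b_j
    indirect: np.ndarray  # a_j * b_j
    c_prime_penalized: float
    selected: list[str]
    a_nonzero: list[str]
    b_nonzero: list[str]
    penalty_a: float
    penalty_b: float
    refit: "RefitResult | None"
    n: int


@dataclass
class RefitResult:
    """Unpenalized joint refit on the selected mediators."""

    paths: dict[str, MediationPaths]  # per selected mediator
    c_prime: float
    c_prime_se: float
    c_prime_p: float
    n: int


def _ols(y, X):
    return sm.OLS(np.asarray(y, float), sm.add_constant(np.asarray(X, float))).fit()


def mediate_single(
    x,
    m,
    y,
    covariates=None,
    robust: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> MediationPaths:
    """Product-of-coefficients mediation for a single mediator.

    a comes from ``m ~ x + covariates``; b and c′ from
    ``y ~ m + x + covariates``; the total effect from ``y ~ x + covariates``.
    For complete-case OLS these satisfy total = c′ + a·b exactly.  The
    indirect-effect standard error is the Sobel (delta-method) value
    sqrt(a²·se_b² + b²·se_a²); with ``n_boot > 0`` a seeded percentile
    bootstrap CI for a·b is added.  ``robust=True`` switches all regression
    standard errors to HC3.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    cov = None if covariates is None else np.asarray(covariates, float)

    def design(*cols):
        mats = [np.asarray(c, float).reshape(n, -1) for c in cols]
        if cov is not None:
            mats.append(cov.reshape(n, -1))
        return np.column_stack(mats)

    Xa = design(x)
    Xb = design(m, x)
    if np.linalg.matrix_rank(sm.add_constant(Xb)) < Xb.shape[1] + 1:
        raise ValueError("rank-deficient design: mediator is collinear with the exposure")

    fit_a = _ols(m, Xa)
    fit_b = _ols(y, Xb)
    fit_c = _ols(y, Xa)
    if robust:
        fit_a = fit_a.get_robustcov_results(cov_type="HC3")
        fit_b = fit_b.get_robustcov_results(cov_type="HC3")
        fit_c = fit_c.get_robustcov_results(cov_type="HC3")

    a, se_a, p_a = fit_a.params[1], fit_a.bse[1], fit_a.pvalues[1]
    b, se_b, p_b = fit_b.params[1], fit_b.bse[1], fit_b.pvalues[1]
    cp, se_cp, p_cp = fit_b.params[2], fit_b.bse[2], fit_b.pvalues[2]
    total, se_tot, p_tot = fit_c.params[1], fit_c.bse[1], fit_c.pvalues[1]

    indirect = a * b
    se_ind = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    p_ind = 2 * stats.norm.sf(abs(indirect) / se_ind) if se_ind > 0 else np.nan

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            cb = None if cov is None else cov[idx]
            xa = np.column_stack([x[idx].reshape(-1, 1)] + ([cb] if cb is not None else []))
            xb = np.column_stack(
                [m[idx].reshape(-1, 1), x[idx].reshape(-1, 1)] + ([cb] if cb is not None else [])
            )
            ab = _ols(m[idx], xa).params[1] * _ols(y[idx], xb).params[1]
            draws[i] = ab
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))

    return MediationPaths(
        a=float(a),
        b=float(b),
        c_prime=float(cp),
        indirect=float(indirect),
        total=float(total),
        se={"a": float(se_a), "b": float(se_b), "c_prime": float(se_cp),
            "indirect": se_ind, "total": float(se_tot)},
        p={"a": float(p_a), "b": float(p_b), "c_prime": float(p_cp),
           "indirect": float(p_ind), "total": float(p_tot)},
        ci_indirect=ci,
        n=n,
    )


def _check_standardized(name: str, arr: np.ndarray) -> None:
    mu = np.abs(arr.mean(axis=0)).max()
    sd = arr.std(axis=0, ddof=1)
    if mu > 0.05 or np.abs(sd - 1).max() > 0.05:
        raise ValueError(
            f"{name} must be standardized (mean 0, sd 1) and residualized for "
            f"covariates before regularized mediation"
        )


def _sklearn_alpha(lam: float, l1_ratio: float) -> float:
    # sklearn's objective is (1/2n)RSS + alpha*(l1_ratio*|b|1 + (1-l1_ratio)/2*|b|2^2),
    # identical to the glmnet form used here, so alpha == lambda.
    return lam


def _path_b(y, M, x, config: RegularizedMediationConfig):
    """Elastic net of y on all mediators with x unpenalized.

    Leaving x unpenalized is equivalent (by profiling the x coefficient out of
    the objective) to the penalized regression of x-residualized y on
    x-residualized mediators; the x coefficient is then recovered by OLS on
    what the penalized fit leaves unexplained.
    """
    n = y.shape[0]
    px = x / (x @ x)
    y_t = y - x * (px @ y)
    M_t = M - np.outer(x, px @ M)
    l1 = config.elastic_net_mixing
    if config.penalty_override is not None:
        lam = config.penalty_override
        if lam == 0:
            model = LinearRegression(fit_intercept=True).fit(M_t, y_t)
        else:
            model = ElasticNet(
                alpha=_sklearn_alpha(lam, l1), l1_ratio=l1, fit_intercept=True, max_iter=50_000
            ).fit(M_t, y_t)
        b = model.coef_
    else:
        cv = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.cv_seed)
        model = ElasticNetCV(
            l1_ratio=l1,
            alphas=config.n_penalties,
            eps=config.penalty_eps,
            cv=cv,
            fit_intercept=True,
            max_iter=50_000,
        ).fit(M_t, y_t)
        b = model.coef_
        lam = float(model.alpha_)
    theta = float(px @ (y - M @ b))  # unpenalized direct-effect coefficient
    return np.asarray(b, float), theta, float(lam)


def _soft(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _enet_a_closed_form(M, x, lam, l1):
    """Per-mediator elastic net of m_j on the single predictor x.

    With one predictor the coordinate-descent solution is a single
    soft-threshold: a_j = S(mean(x·m_j), λα) / (mean(x²) + λ(1−α)).
    """
    n = x.shape[0]
    xm = (x @ M) / n
    sxx = float(x @ x) / n
    return _soft(xm, lam * l1) / (sxx + lam * (1 - l1))


def _path_a(M, x, config: RegularizedMediationConfig):
    """Multi-response shared-penalty regression of the mediators on x.

    A single λ is shared across mediators and chosen by k-fold CV minimizing
    the total out-of-fold MSE summed over mediators.  With one predictor per
    response the solution per mediator is a closed-form soft-threshold, so no
    iterative solver is needed.
    """
    n, p = M.shape
    l1 = config.elastic_net_mixing
    if config.penalty_override is not None:
        lam = config.penalty_override
        return _enet_a_closed_form(M, x, lam, l1), float(lam)
    xm_abs = np.abs((x @ M) / n)
    lam_max = xm_abs.max() / max(l1, 1e-3)
    if lam_max <= 0:
        return np.zeros(p), 0.0
    grid = np.geomspace(lam_max, lam_max * config.penalty_eps, config.n_penalties)
    cv = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.cv_seed)
    err = np.zeros(grid.size)
    for train, test in cv.split(x):
        a_grid = np.stack(
            [_enet_a_closed_form(M[train], x[train], lam, l1) for lam in grid]
        )  # (n_lam, p)
        resid = M[test][None, :, :] - x[test][None, :, None] * a_grid[:, None, :]
        err += (resid**2).sum(axis=(1, 2))
    lam = float(grid[int(np.argmin(err))])
    return _enet_a_closed_form(M, x, lam, l1), lam


def _path_a_reversed(M, x, config: RegularizedMediationConfig):
    """Alternative formulation: elastic net of x on all mediators jointly."""
    l1 = config.elastic_net_mixing
    if config.penalty_override is not None:
        lam = config.penalty_override
        if lam == 0:
            model = LinearRegression().fit(M, x)
        else:
            model = ElasticNet(alpha=lam, l1_ratio=l1, max_iter=50_000).fit(M, x)
        return np.asarray(model.coef_, float), float(lam)
    cv = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.cv_seed)
    model = ElasticNetCV(
        l1_ratio=l1, alphas=config.n_penalties, eps=config.penalty_eps, cv=cv, max_iter=50_000
    ).fit(M, x)
    return np.asarray(model.coef_, float), float(model.alpha_)


def regularized_mediation(
    x,
    M,
    y,
    config: RegularizedMediationConfig | None = None,
    mediator_ids: list[str] | None = None,
) -> RegularizedMediationResult:
    """Exploratory mediation by regularization over p candidate mediators.

    All inputs must already be standardized and residualized for nuisance
    covariates (checked).  Candidates with penalized |a_j·b_j| above
    ``mediation_threshold`` are selected and refit without penalty; path-level
    non-zero sets use ``path_threshold`` on |a_j| and |b_j| separately.
    """
    if config is None:
        config = RegularizedMediationConfig()
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    M = np.asarray(M, float)
    n, p = M.shape
    if mediator_ids is None:
        mediator_ids = [f"m{j}" for j in range(p)]
    if len(mediator_ids) != p:
        raise ValueError("mediator_ids length must match the mediator matrix")
    if config.k_folds > n:
        raise ValueError(f"k_folds={config.k_folds} exceeds n={n}")
    if np.any(M.std(axis=0) == 0):
        raise ValueError("zero-variance mediator column")
    _check_standardized("x", x[:, None])
    _check_standardized("y", y[:, None])
    _check_standardized("mediators", M)

    b, c_prime_pen, lam_b = _path_b(y, M, x, config)
    if config.path_a_direction == "mediators_on_x":
        a, lam_a = _path_a(M, x, config)
    else:
        a, lam_a = _path_a_reversed(M, x, config)

    ab = a * b
    sel = np.abs(ab) > config.mediation_threshold
    selected = [mediator_ids[j] for j in np.flatnonzero(sel)]
    a_nonzero = [mediator_ids[j] for j in np.flatnonzero(np.abs(a) > config.path_threshold)]
    b_nonzero = [mediator_ids[j] for j in np.flatnonzero(np.abs(b) > config.path_threshold)]

    refit = None
    if selected:
        if len(selected) > n - 2:
            raise ValueError(
                f"{len(selected)} mediators selected with n={n}: unpenalized refit impossible"
            )
        refit = refit_selected(x, M[:, sel], y, mediator_ids=selected)

    return RegularizedMediationResult(
        mediator_ids=list(mediator_ids),
        a=a,
        b=b,
        indirect=ab,
        c_prime_penalized=float(c_prime_pen),
        selected=selected,
        a_nonzero=a_nonzero,
        b_nonzero=b_nonzero,
        penalty_a=float(lam_a),
        penalty_b=float(lam_b),
        refit=refit,
        n=n,
    )


def refit_selected(
    x, M_selected, y, covariates=None, mediator_ids: list[str] | None = None
) -> RefitResult:
    """Unpenalized joint refit of the selected mediators (debiased effects).

    a_j from per-mediator regression ``m_j ~ x (+ covariates)``; all b_j and
    the shared c′ from the joint regression ``y ~ M_selected + x
    (+ covariates)``.  With exactly one selected mediator this reproduces
    :func:`mediate_single`.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    M = np.asarray(M_selected, float)
    if M.ndim == 1:
        M = M[:, None]
    n, k = M.shape
    if k == 0:
        raise ValueError("empty selection: nothing to refit")
    if k > n - 2:
        raise ValueError("more selected mediators than the refit can support")
    if mediator_ids is None:
        mediator_ids = [f"m{j}" for j in range(k)]
    cov = None if covariates is None else np.asarray(covariates, float)

    cols = [M, x[:, None]] + ([cov.reshape(n, -1)] if cov is not None else [])
    fit_joint = _ols(y, np.column_stack(cols))
    paths: dict[str, MediationPaths] = {}
    cp = float(fit_joint.params[1 + k])
    cp_se = float(fit_joint.bse[1 + k])
    cp_p = float(fit_joint.pvalues[1 + k])
    for j, mid in enumerate(mediator_ids):
        xa_cols = [x[:, None]] + ([cov.reshape(n, -1)] if cov is not None else [])
        fit_a = _ols(M[:, j], np.column_stack(xa_cols))
        a, se_a, p_a = float(fit_a.params[1]), float(fit_a.bse[1]), float(fit_a.pvalues[1])
        b, se_b, p_b = (
            float(fit_joint.params[1 + j]),
            float(fit_joint.bse[1 + j]),
            float(fit_joint.pvalues[1 + j]),
        )
        ind = a * b
        se_ind = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
        paths[mid] = MediationPaths(
            a=a,
            b=b,
            c_prime=cp,
            indirect=ind,
            total=cp + ind if k == 1 else np.nan,
            se={"a": se_a, "b": se_b, "c_prime": cp_se, "indirect": se_ind},
            p={"a": p_a, "b": p_b, "c_prime": cp_p,
               "indirect": float(2 * stats.norm.sf(abs(ind) / se_ind)) if se_ind > 0 else np.nan},
            n=n,
        )
    return RefitResult(paths=paths, c_prime=cp, c_prime_se=cp_se, c_prime_p=cp_p, n=n)


def selection_metrics(selected: list[str], true_mediators: list[str], candidates: list[str]):
    """Sensitivity, specificity and FDR of a selected mediator set.

    All three id lists refer to the same candidate universe; unknown ids are
    rejected.
    """
    cand = set(candidates)
    sel = set(selected)
    truth = set(true_mediators) & cand
    if not sel <= cand:
        raise ValueError(f"selected ids outside the candidate set: {sorted(sel - cand)}")
    tp = len(sel & truth)
    fp = len(sel - truth)
    fn = len(truth - sel)
    tn = len(cand) - tp - fp - fn
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return {"sensitivity": sensitivity, "specificity": specificity, "fdr": fdr,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}
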