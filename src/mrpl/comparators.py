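"""Reference one-sample MR estimators used as benchmarks.

All are variants of two-stage least squares on standardized data (no
intercepts): Multi-2SLS fits every exposure on the full instrument matrix
and regresses the outcome on all fitted exposures jointly; Uni-2SLS
repeats univariable 2SLS per exposure with that exposure's own associated
instruments; PRS-2SLS collapses those instruments to their unweighted
row-mean allele score; the MV-IWAS-like estimator predicts each exposure
from only its own instruments but keeps the joint second stage. P-values
are conventional second-stage OLS t-tests (deliberately naive — this is
the usage being benchmarked). Penalized variants replace the second stage
with ridge / elastic-net / LARS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LarsCV, Ridge, enet_path
from sklearn.model_selection import KFold

from .lasso import _quiet_cd, default_lambda_grid, lasso_fit

__all__ = ["EstimatorResult", "multi_2sls", "uni_2sls", "prs_2sls",
           "mv_iwas_like", "pls_penalty_variant", "COMPARATORS"]


@dataclass
class EstimatorResult:
    method: str
    beta: np.ndarray
    p: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _ols(design, y):
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _second_stage(Xhat, Y, X_orig=None):
    """Second-stage OLS with conventional 2SLS t-tests.

    The error variance uses the structural residual Y - X beta (original
    exposures), as in textbook 2SLS output; passing X_orig=None falls back
    to the fitted-design residual.
    """
    n, k = Xhat.shape
    gram = Xhat.T @ Xhat
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular second-stage design") from exc
    beta = ginv @ (Xhat.T @ Y)
    resid = Y - (Xhat if X_orig is None else X_orig) @ beta
    dof = max(n - k, 1)
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(ginv) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return beta, p


def multi_2sls(G, X, Y, pair_mask=None) -> EstimatorResult:
    """Joint 2SLS: beta = [X'P X]^{-1} X'P Y with P the projection on col(G)."""
    G = np.asarray(G, float)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    Xhat = G @ _ols(G, X)
    beta, p = _second_stage(Xhat, Y, X_orig=X)
    return EstimatorResult("multi2sls", beta=beta, p=p)


def _single_iv_2sls(g_mat, xk, Y):
    xhat = g_mat @ _ols(g_mat, xk)
    beta, p = _second_stage(xhat[:, None], Y, X_orig=xk[:, None])
    return float(beta[0]), float(p[0])


def uni_2sls(G, X, Y, pair_mask) -> EstimatorResult:
    """Per-exposure 2SLS restricted to that exposure's own instruments."""
    G = np.asarray(G, float)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    k = X.shape[1]
    beta = np.full(k, np.nan)
    p = np.full(k, np.nan)
    for j in range(k):
        cols = np.flatnonzero(pair_mask[:, j])
        if cols.size == 0:
            warnings.warn(f"exposure {j} has no instruments; skipped", stacklevel=2)
            continue
        beta[j], p[j] = _single_iv_2sls(G[:, cols], X[:, j], Y)
    return EstimatorResult("uni2sls", beta=beta, p=p)


def prs_2sls(G, X, Y, pair_mask) -> EstimatorResult:
    """Univariable 2SLS with the unweighted mean allele score as instrument."""
    G = np.asarray(G, float)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    k = X.shape[1]
    beta = np.full(k, np.nan)
    p = np.full(k, np.nan)
    for j in range(k):
        cols = np.flatnonzero(pair_mask[:, j])
        if cols.size == 0:
            warnings.warn(f"exposure {j} has no instruments; skipped", stacklevel=2)
            continue
        score = G[:, cols].mean(axis=1)
        beta[j], p[j] = _single_iv_2sls(score[:, None], X[:, j], Y)
    return EstimatorResult("prs2sls", beta=beta, p=p)


def mv_iwas_like(G, X, Y, pair_mask) -> EstimatorResult:
    """Exposure-specific first stages, joint second stage."""
    G = np.asarray(G, float)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).ravel()
    n, k = X.shape
    Xhat = np.zeros((n, k))
    kept = []
    for j in range(k):
        cols = np.flatnonzero(pair_mask[:, j])
        if cols.size == 0:
            warnings.warn(f"exposure {j} has no instruments; skipped", stacklevel=2)
            continue
        Xhat[:, j] = G[:, cols] @ _ols(G[:, cols], X[:, j])
        kept.append(j)
    kept = np.array(kept, dtype=int)
    beta = np.full(k, np.nan)
    p = np.full(k, np.nan)
    b, pv = _second_stage(Xhat[:, kept], Y, X_orig=X[:, kept])
    beta[kept] = b
    p[kept] = pv
    return EstimatorResult("mviwas", beta=beta, p=p)


_L1_RATIO_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def pls_penalty_variant(Xhat, Y, penalty: str, folds: int = 10, seed: int = 0,
                        l1_ratio_grid=None) -> EstimatorResult:
    """Second-stage ridge / elastic-net / LARS alternatives (estimation only).

    Ridge and elastic-net are tuned by 10-fold CV over the same
    un-normalized penalty grid as the Lasso stage; the elastic-net mixing
    parameter is CV-selected over ``l1_ratio_grid`` (default 0.1..0.9).
    """
    Xhat = np.asarray(Xhat, float)
    Y = np.asarray(Y, float).ravel()
    n = Xhat.shape[0]
    grid = default_lambda_grid()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    if penalty == "ridge":
        sse = np.zeros(grid.size)
        for train, test in kf.split(Xhat):
            for i, lam in enumerate(grid):
                model = Ridge(alpha=lam, fit_intercept=False)
                model.fit(Xhat[train], Y[train])
                sse[i] += np.sum((Y[test] - model.predict(Xhat[test])) ** 2)
        i_opt = int(np.flatnonzero(sse <= sse.min() * (1 + 1e-12))[0])
        model = Ridge(alpha=grid[i_opt], fit_intercept=False).fit(Xhat, Y)
        return EstimatorResult("pls_ridge", beta=model.coef_,
                               extra={"lambda_opt": float(grid[i_opt])})
    if penalty == "elasticnet":
        ratios = _L1_RATIO_GRID if l1_ratio_grid is None else tuple(l1_ratio_grid)
        best = (np.inf, None, None)
        for ratio in ratios:
            sse = np.zeros(grid.size)
            with _quiet_cd():
                for train, test in kf.split(Xhat):
                    a = grid / (2.0 * train.size)
                    _, coefs, _ = enet_path(Xhat[train], Y[train], alphas=a,
                                            l1_ratio=ratio)
                    resid = Y[test, None] - Xhat[test] @ coefs
                    sse += np.sum(resid ** 2, axis=0)
            i_opt = int(np.flatnonzero(sse <= sse.min() * (1 + 1e-12))[0])
            if sse[i_opt] < best[0]:
                best = (sse[i_opt], ratio, i_opt)
        _, ratio, i_opt = best
        with _quiet_cd():
            _, coefs, _ = enet_path(Xhat, Y, alphas=grid / (2.0 * n),
                                    l1_ratio=ratio, max_iter=20000, tol=1e-10)
        return EstimatorResult("pls_elasticnet", beta=coefs[:, i_opt],
                               extra={"lambda_opt": float(grid[i_opt]),
                                      "l1_ratio": ratio})
    if penalty == "lars":
        model = LarsCV(fit_intercept=False, cv=kf)
        model.fit(Xhat, Y)
        return EstimatorResult("pls_lars", beta=model.coef_)
    if penalty == "lasso":
        fit = lasso_fit(Xhat, Y, folds=folds, seed=seed)
        return EstimatorResult("pls_lasso", beta=fit.beta,
                               extra={"lambda_opt": fit.lambda_opt})
    raise ValueError(f"unknown penalty {penalty!r}")


COMPARATORS = {
    "multi2sls": multi_2sls,
    "uni2sls": uni_2sls,
    "prs2sls": prs_2sls,
    "mviwas": mv_iwas_like,
}
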