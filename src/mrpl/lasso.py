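"""Second-stage Lasso of the outcome on genetically fitted exposures.

The objective is the un-normalized penalized RSS

    ||Y - Xhat beta||_2^2 + lambda ||beta||_1,

with lambda searched over 100 log-spaced points spanning 1e-2 .. 1e10 and
chosen by 10-fold CV (ties prefer the larger lambda, i.e. the sparser
model). The solver is scikit-learn coordinate descent, whose mean-loss
penalty alpha relates to the objective above by lambda = 2 N alpha; the
reported grid and optimum are in un-normalized units.

Per-exposure p-values come from the de-sparsified (debiased) Lasso: a
nodewise Lasso of each column on the others yields a relaxed projection
direction Z_j, and

    b_j = beta_j + Z_j'(Y - Xhat beta) / (Z_j' Xhat_j)

is asymptotically normal with standard error sigma_eps ||Z_j|| / |Z_j' Xhat_j|.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import KFold


@contextmanager
def _quiet_cd():
    # the bottom of the penalty grid (1e-2 un-normalized) is effectively
    # unpenalized; coordinate descent may hit max_iter there without
    # affecting the CV-selected solution
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield

__all__ = ["LassoFit", "DesparsifiedResult", "default_lambda_grid",
           "lasso_fit", "desparsify", "call_causal"]


def default_lambda_grid(num: int = 100) -> np.ndarray:
    """Descending penalty grid, exponents uniform on [-2, 10]."""
    return np.logspace(10, -2, num)


@dataclass
class LassoFit:
    beta: np.ndarray
    lambda_opt: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray
    active_set: np.ndarray

    @property
    def n_active(self) -> int:
        return int(self.active_set.size)


@dataclass
class DesparsifiedResult:
    beta_debiased: np.ndarray
    se: np.ndarray
    p: np.ndarray
    theta_hat: np.ndarray
    sigma_eps: float


def _check_design(Xhat):
    Xhat = np.asarray(Xhat, dtype=float)
    if Xhat.ndim != 2:
        raise ValueError("Xhat must be 2-D")
    spread = Xhat.max(axis=0) - Xhat.min(axis=0)
    if np.any(spread == 0):
        j = int(np.flatnonzero(spread == 0)[0])
        raise ValueError(f"constant fitted-exposure column at index {j}")
    return Xhat


def lasso_fit(Xhat, Y, folds: int = 10, seed: int = 0,
              lambda_grid: np.ndarray | None = None) -> LassoFit:
    """CV-tuned Lasso over the un-normalized lambda grid (no intercept,
    no internal re-standardization)."""
    Xhat = _check_design(Xhat)
    Y = np.asarray(Y, dtype=float).ravel()
    n = Xhat.shape[0]
    grid = default_lambda_grid() if lambda_grid is None else np.sort(
        np.asarray(lambda_grid, float))[::-1]
    alphas = grid / (2.0 * n)   # sklearn mean-loss parameterization
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(grid.size)
    with _quiet_cd():
        for train, test in kf.split(Xhat):
            a = grid / (2.0 * train.size)
            _, coefs, _ = lasso_path(Xhat[train], Y[train], alphas=a)
            resid = Y[test, None] - Xhat[test] @ coefs
            sse += np.sum(resid ** 2, axis=0)
    cv_mse = sse / n
    best = cv_mse.min()
    # ties -> sparser model; grid is descending so the first near-minimum
    # is the largest lambda
    i_opt = int(np.flatnonzero(cv_mse <= best * (1 + 1e-12))[0])
    with _quiet_cd():
        # tight tolerance so the reported solution satisfies the KKT
        # conditions of the un-normalized objective to ~1e-6
        _, coefs_full, _ = lasso_path(Xhat, Y, alphas=alphas[:i_opt + 1],
                                      max_iter=20000, tol=1e-10)
    beta = coefs_full[:, i_opt]
    return LassoFit(beta=beta, lambda_opt=float(grid[i_opt]), lambda_grid=grid,
                    cv_mse=cv_mse, active_set=np.flatnonzero(beta != 0))


def _noise_sd(Xhat, Y, beta, n_active) -> float:
    resid = Y - Xhat @ beta
    dof = max(Xhat.shape[0] - n_active, 1)
    return float(np.linalg.norm(resid) / np.sqrt(dof))


def desparsify(Xhat, Y, fit: LassoFit, folds: int = 10,
               seed: int = 0) -> DesparsifiedResult:
    """Bias-corrected Lasso coefficients with normal-approximation p-values.

    Each nodewise penalty is selected by CV on the same fold stream. With a
    single exposure the construction degenerates to simple-regression
    inference (Z_1 = Xhat_1), which is the documented behaviour rather than
    an error.
    """
    Xhat = _check_design(Xhat)
    Y = np.asarray(Y, dtype=float).ravel()
    n, k = Xhat.shape
    resid = Y - Xhat @ fit.beta
    sigma_eps = _noise_sd(Xhat, Y, fit.beta, fit.n_active)
    beta_deb = np.empty(k)
    se = np.empty(k)
    theta = np.zeros((k, k))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for j in range(k):
        if k == 1:
            z = Xhat[:, 0].copy()
            w = np.array([1.0])
        else:
            others = np.delete(np.arange(k), j)
            node = LassoCV(fit_intercept=False, cv=kf, alphas=50)
            with _quiet_cd():
                node.fit(Xhat[:, others], Xhat[:, j])
            z = Xhat[:, j] - Xhat[:, others] @ node.coef_
            w = np.zeros(k)
            w[j] = 1.0
            w[others] = -node.coef_
        zx = float(z @ Xhat[:, j])
        if abs(zx) < 1e-12 * n:
            beta_deb[j] = fit.beta[j]
            se[j] = np.inf
            continue
        beta_deb[j] = fit.beta[j] + float(z @ resid) / zx
        se[j] = sigma_eps * np.linalg.norm(z) / abs(zx)
        theta[j] = n * w / zx
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(np.isfinite(se) & (se > 0), beta_deb / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(zscore))
    return DesparsifiedResult(beta_debiased=beta_deb, se=se, p=p,
                              theta_hat=theta, sigma_eps=sigma_eps)


def call_causal(fit: LassoFit, desp: DesparsifiedResult, alpha: float = 0.05,
                exposure_ids=None) -> pd.DataFrame:
    """Causal verdict per exposure: nonzero Lasso coefficient AND p < alpha."""
    k = fit.beta.size
    ids = list(exposure_ids) if exposure_ids is not None else [f"x{i}" for i in range(k)]
    verdict = (fit.beta != 0) & (desp.p < alpha)
    return pd.DataFrame({
        "exposure_id": ids,
        "beta": fit.beta,
        "beta_debiased": desp.beta_debiased,
        "se": desp.se,
        "p": desp.p,
        "causal": verdict,
    })
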