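"""First-stage PLS2 regression of exposures on instruments.

Each component maximizes cov(G rho, X gamma) under unit-norm loadings:
rho is the leading eigenvector of G'XX'G (equivalently the leading left
singular vector of A = G'X, with theta the singular value), and
gamma = X'G rho / theta. The G-score u = G rho then deflates *both* blocks
by its OLS fit (G <- G - u sigma', X <- X - u tau'), and the coefficient
matrix is assembled as C = P (Sigma' P)^{-1} T'.

Deflating both blocks by the predictor-block score is the classical PLS2
recursion; it keeps successive scores mutually orthogonal, and at
r = rank(G) the fit coincides with the OLS projection of X onto col(G).

The deflated cross-product A is maintained by a rank-1 update
(A <- A - ||u||^2 sigma tau'), so each extra component costs O(NM), which
is what makes biobank-sized first stages practical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

__all__ = ["PLSFit", "fit_pls", "cross_validate_components", "pls_predict",
           "jackknife_snp_test"]

_RCOND = 1e-10


@dataclass
class PLSFit:
    r: int
    P: np.ndarray        # (M, r) SNP loadings, unit columns
    Gamma: np.ndarray    # (K, r) exposure loadings, unit columns
    U: np.ndarray        # (N, r) G-scores
    Sigma: np.ndarray    # (M, r) G regression loadings on scores
    T: np.ndarray        # (K, r) X regression loadings on scores
    theta: np.ndarray    # (r,) singular values of the deflated cross-products
    C: np.ndarray        # (M, K) coefficient matrix P (Sigma'P)^-1 T'
    snp_ids: list = field(default_factory=list)
    cv_mse: np.ndarray | None = None

    def coefficients(self, r: int | None = None) -> np.ndarray:
        """C truncated to the first ``r`` components."""
        if r is None or r == self.r:
            return self.C
        return _assemble_coef(self.P[:, :r], self.Sigma[:, :r], self.T[:, :r])


def _assemble_coef(P, Sigma, T):
    core = Sigma.T @ P                      # r x r
    return P @ np.linalg.pinv(core, rcond=_RCOND) @ T.T


def _sign_fix(rho):
    j = np.argmax(np.abs(rho))
    return rho if rho[j] >= 0 else -rho


def fit_pls(G: np.ndarray, X: np.ndarray, r: int, snp_ids=None) -> PLSFit:
    """Fit ``r`` PLS2 components of standardized X on standardized G.

    Stops early (with a warning) if the deflated cross-product vanishes
    before ``r`` components; raises if ``r`` exceeds min(M, K, N-1).
    """
    G = np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = G.shape
    k = X.shape[1]
    # components live in the instrument space: up to rank(G) of them exist
    # even when K is smaller (the cross-covariance is re-expressed after
    # each deflation), so only M and N-1 cap r
    r_max = min(m, n - 1)
    if not 1 <= r <= r_max:
        raise ValueError(f"r={r} outside attainable range [1, {r_max}]")
    Gd = G.copy()
    Xd = X.copy()
    A = Gd.T @ Xd
    theta0 = None
    P = np.empty((m, r))
    Gamma = np.empty((k, r))
    U = np.empty((n, r))
    Sigma = np.empty((m, r))
    T = np.empty((k, r))
    thetas = np.empty(r)
    got = 0
    for i in range(r):
        svd_u, svd_s, _ = np.linalg.svd(A, full_matrices=False)
        theta = svd_s[0]
        if theta0 is None:
            theta0 = theta
        if theta <= max(theta0, 1.0) * 1e-12:
            warnings.warn(f"cross-covariance exhausted after {got} components; "
                          f"r truncated from {r}", stacklevel=2)
            break
        rho = _sign_fix(svd_u[:, 0])
        gamma = (A.T @ rho) / theta
        u = Gd @ rho
        nu = float(u @ u)
        sigma = (Gd.T @ u) / nu
        tau = (Xd.T @ u) / nu
        P[:, i], Gamma[:, i], U[:, i] = rho, gamma, u
        Sigma[:, i], T[:, i], thetas[i] = sigma, tau, theta
        Gd -= np.outer(u, sigma)
        Xd -= np.outer(u, tau)
        A -= nu * np.outer(sigma, tau)
        got += 1
    P, Gamma, U = P[:, :got], Gamma[:, :got], U[:, :got]
    Sigma, T, thetas = Sigma[:, :got], T[:, :got], thetas[:got]
    C = _assemble_coef(P, Sigma, T)
    return PLSFit(r=got, P=P, Gamma=Gamma, U=U, Sigma=Sigma, T=T,
                  theta=thetas, C=C, snp_ids=list(snp_ids or []))


def cross_validate_components(G, X, folds: int = 10, max_r: int | None = None,
                              seed: int = 0):
    """Select the component count by K-fold CV on held-out exposure MSE.

    Returns (r_opt, cv_mse) where cv_mse[r-1] is the mean squared held-out
    prediction error using r components, averaged over folds and all
    exposure columns (unweighted). Ties break to the smallest r.
    """
    G = np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = G.shape
    k = X.shape[1]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one sample per fold")
    if max_r is None:
        max_r = min(k, m, int(np.floor(n * (folds - 1) / folds)) - 1)
    max_r = max(1, max_r)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(max_r)
    count = np.zeros(max_r)
    for train, test in kf.split(G):
        fit = fit_pls(G[train], X[train], r=max_r)
        for r in range(1, max_r + 1):
            C = fit.coefficients(min(r, fit.r))
            resid = X[test] - G[test] @ C
            sse[r - 1] += np.sum(resid ** 2)
            count[r - 1] += resid.size
    cv_mse = sse / count
    r_opt = int(np.argmin(cv_mse)) + 1
    return r_opt, cv_mse


def pls_predict(fit: PLSFit, G_new: np.ndarray, snp_ids=None) -> np.ndarray:
    """Fitted exposures G_new @ C for new genotype rows (same SNP order)."""
    G_new = np.atleast_2d(np.asarray(G_new, dtype=float))
    if G_new.shape[1] != fit.C.shape[0]:
        raise ValueError("SNP dimension mismatch")
    if snp_ids is not None and fit.snp_ids and list(snp_ids) != list(fit.snp_ids):
        raise ValueError("SNP identifier/order mismatch")
    return G_new @ fit.C


def jackknife_snp_test(G, X, r: int, max_n: int = 500, force: bool = False):
    """Leave-one-out jackknife t-test for each SNP-exposure coefficient.

    Refits the PLS at fixed ``r`` with each sample held out; the jackknife
    variance of C[m, k] over the N refits gives t = c / se on N-1 df.
    Entries with zero jackknife variance are flagged degenerate and assigned
    p = 0 (the coefficient is identical in every refit).

    Returns dict with arrays ``coef``, ``se``, ``t``, ``p``, ``degenerate``.
    """
    G = np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    n = G.shape[0]
    if n > max_n and not force:
        raise ValueError(
            f"N={n} leave-one-out refits exceed the cap {max_n}; subsample "
            "or pass force=True")
    full = fit_pls(G, X, r=r)
    mask = np.ones(n, dtype=bool)
    cs = np.empty((n,) + full.C.shape)
    for i in range(n):
        mask[i] = False
        cs[i] = fit_pls(G[mask], X[mask], r=min(r, G.shape[1], n - 2)).C
        mask[i] = True
    # deviations computed explicitly so an exactly constant coefficient
    # yields variance 0 rather than rounding residue
    var = (n - 1) / n * np.sum((cs - cs.mean(axis=0)) ** 2, axis=0)
    se = np.sqrt(var)
    degenerate = se <= 1e-12 * (np.abs(full.C) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.inf * np.sign(full.C), full.C / se)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 0.0, p)
    return {"coef": full.C, "se": se, "t": t, "p": p, "degenerate": degenerate}
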