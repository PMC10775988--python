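"""Pleiotropy and instrument-strength diagnostics.

Sargan over-identification test: regress the second-stage residual
eps = Y - Xhat beta on the full instrument matrix; S = N R^2 is chi-square
with M - K degrees of freedom under no horizontal pleiotropy. A p-value
below 0.05 flags the MR result as unreliable.

Instrument strength: the joint F-statistic per exposure,
F = R^2 (N - M - 1) / ((1 - R^2) M), and the Sanderson-Windmeijer
conditional F, which measures the strength of an exposure's instruments
conditional on the remaining exposures (rule of thumb: weak below 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SarganResult", "StrengthReport", "sargan_test", "f_statistic",
           "conditional_f", "strength_report"]


@dataclass
class SarganResult:
    S: float
    df: int
    p: float
    r2: float

    @property
    def unreliable(self) -> bool:
        return self.p < 0.05


@dataclass
class StrengthReport:
    exposure_ids: list
    f: np.ndarray
    f_sw: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"exposure_id": self.exposure_ids,
                             "F": self.f, "F_sw": self.f_sw})


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    """Centered R^2 of y on [intercept, design]."""
    X = np.column_stack([np.ones(len(y)), design])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return max(0.0, 1.0 - float(resid @ resid) / tss)


def sargan_test(G, Xhat, Y, beta) -> SarganResult:
    """S = N R^2 from the residual-on-instruments regression."""
    G = np.asarray(G, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, m = G.shape
    k = Xhat.shape[1]
    if m <= k:
        raise ValueError("Sargan undefined: need more instruments than exposures")
    eps = Y - Xhat @ np.asarray(beta, dtype=float)
    r2 = _r2(eps, G)
    S = n * r2
    df = m - k
    return SarganResult(S=S, df=df, p=float(stats.chi2.sf(S, df)), r2=r2)


def f_statistic(r2: float, n: int, m: int) -> float:
    """Joint instrument F from the explained variance of one exposure."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= m + 1:
        raise ValueError("need n > m + 1")
    return r2 * (n - m - 1) / ((1.0 - r2) * m)


def conditional_f(G, X, k_idx: int) -> float:
    """Sanderson-Windmeijer conditional F-statistic for exposure ``k_idx``.

    The target exposure is residualized on the instrument-predicted values
    of the other exposures, the residual is regressed on the full instrument
    set, and the F-statistic uses M - K + 1 numerator degrees of freedom.
    Falls back to the unconditional F when only one exposure is present.
    """
    G = np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = G.shape
    k = X.shape[1]
    xk = X[:, k_idx]
    if k < 2:
        return f_statistic(_r2(xk, G), n, m)
    if m <= k - 1:
        raise ValueError("need more instruments than conditioning exposures")
    others = np.delete(np.arange(k), k_idx)
    ones = np.ones((n, 1))
    design = np.column_stack([ones, G])
    coef, *_ = np.linalg.lstsq(design, X[:, others], rcond=None)
    x_others_hat = design @ coef
    d2 = np.column_stack([ones, x_others_hat])
    c2, *_ = np.linalg.lstsq(d2, xk, rcond=None)
    resid = xk - d2 @ c2
    r2 = _r2(resid, G)
    if n <= m + 1:
        raise ValueError("need n > m + 1")
    return r2 * (n - m - 1) / ((1.0 - r2) * (m - k + 1))


def strength_report(G, X, exposure_ids=None, pair_mask=None) -> StrengthReport:
    """Joint and conditional F for every exposure.

    ``pair_mask`` (M, K) restricts each exposure's joint F to its own
    associated instruments; the conditional F always uses the full set.
    """
    G = np.asarray(G, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = G.shape
    k = X.shape[1]
    ids = list(exposure_ids) if exposure_ids is not None else [f"x{i}" for i in range(k)]
    f = np.empty(k)
    fsw = np.empty(k)
    for j in range(k):
        cols = np.flatnonzero(pair_mask[:, j]) if pair_mask is not None else np.arange(m)
        if cols.size == 0:
            f[j] = np.nan
        else:
            f[j] = f_statistic(_r2(X[:, j], G[:, cols]), n, cols.size)
        fsw[j] = conditional_f(G, X, j)
    return StrengthReport(exposure_ids=ids, f=f, f_sw=fsw)
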