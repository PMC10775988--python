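"""Marginal SNP-exposure association scan and instrument selection.

With standardized variables the simple-regression slope of exposure k on
SNP m equals their sample correlation r; its test statistic is
t = r sqrt(N-2) / sqrt(1 - r^2) on N-2 degrees of freedom. Instruments are
the SNPs associated with at least one exposure below a marginal p-value
threshold (genome-wide significance 5e-8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GwasScan", "InstrumentSet", "marginal_gwas", "select_instruments"]


@dataclass
class GwasScan:
    """Per-(SNP, exposure) marginal effects.

    ``beta`` / ``z`` / ``p`` are (M, K) arrays aligned with snp_ids and
    exposure_ids; ``n`` is the GWAS sample size.
    """

    snp_ids: list
    exposure_ids: list
    beta: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        m, k = self.p.shape
        return pd.DataFrame({
            "snp_id": np.repeat(self.snp_ids, k),
            "exposure_id": np.tile(self.exposure_ids, m),
            "beta_marginal": self.beta.ravel(),
            "z": self.z.ravel(),
            "p": self.p.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n: int) -> "GwasScan":
        if df.duplicated(["snp_id", "exposure_id"]).any():
            raise ValueError("duplicate (snp_id, exposure_id) entries")
        wide = df.pivot(index="snp_id", columns="exposure_id", values="p")
        snp_ids, exposure_ids = list(wide.index), list(wide.columns)
        p = wide.to_numpy()
        if "z" in df.columns:
            z = df.pivot(index="snp_id", columns="exposure_id", values="z").to_numpy()
        else:
            z = stats.norm.isf(p / 2.0)
        if "beta_marginal" in df.columns:
            beta = df.pivot(index="snp_id", columns="exposure_id",
                            values="beta_marginal").to_numpy()
        else:
            beta = np.zeros_like(p)
        return cls(snp_ids=snp_ids, exposure_ids=exposure_ids,
                   beta=beta, z=z, p=p, n=n)


@dataclass
class InstrumentSet:
    """SNPs retained as instruments and the per-pair association mask."""

    snp_ids: list
    snp_index: np.ndarray          # indices into the originating scan / G
    pair_mask: np.ndarray          # (M_sel, K) bool, True where association retained
    threshold: float
    exposure_ids: list
    dropped_exposures: list        # exposures with no retained association

    @property
    def kept_exposure_index(self) -> np.ndarray:
        return np.flatnonzero(self.pair_mask.any(axis=0))


def marginal_gwas(data, df_mode: str = "t") -> GwasScan:
    """Simple-regression scan of every exposure on every SNP.

    Parameters
    ----------
    data : GenoPhenoData (standardized).
    df_mode : 't' (exact, N-2 df) or 'normal' for the large-sample mapping.
    """
    G, X = data.G, data.X
    n = G.shape[0]
    # slope of X_k on G_m = sample correlation for standardized columns
    r = (G.T @ X) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r * r, 0.0))
    if df_mode == "t":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    elif df_mode == "normal":
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p = np.where(np.isfinite(t), p, 0.0)
    return GwasScan(snp_ids=list(data.snp_ids), exposure_ids=list(data.exposure_ids),
                    beta=r, z=t, p=p, n=n)


def select_instruments(scan: GwasScan, threshold: float = 5e-8) -> InstrumentSet:
    """Retain SNPs with min-over-exposures p below ``threshold``.

    The pair mask is True exactly where p < threshold; exposures without a
    single retained pair are flagged for dropping from the MR stage.
    """
    if scan.p.size == 0:
        raise ValueError("empty scan")
    hit = scan.p < threshold
    keep = hit.any(axis=1)
    if not keep.any():
        raise ValueError("no instruments: no SNP passes the threshold")
    idx = np.flatnonzero(keep)
    mask = hit[idx]
    dropped = [e for j, e in enumerate(scan.exposure_ids) if not mask[:, j].any()]
    return InstrumentSet(
        snp_ids=[scan.snp_ids[i] for i in idx], snp_index=idx,
        pair_mask=mask, threshold=threshold,
        exposure_ids=list(scan.exposure_ids), dropped_exposures=dropped)
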