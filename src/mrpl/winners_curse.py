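"""Winner's-curse shrinkage of SNP-exposure z-scores.

Selecting instruments at a p-value threshold in the same cohort used for
the MR analysis inflates the selected associations. The correction
soft-thresholds the absolute z-score of every selected pair,

    |z_corr| = (|z| - gamma)_+ ,   gamma = c / (-log10(threshold) + log10(N)),

then re-applies the selection threshold to the corrected p-values
p_corr = 2(1 - Phi(|z_corr|)). Shrinkage is stronger for looser thresholds
and smaller GWAS sample sizes; c (default 20) tunes the overall strength.
Pairs whose corrected p-value no longer passes the threshold are dropped,
and with them any SNP or exposure left without a retained association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WcConfig", "WcResult", "p_to_z", "shrinkage_gamma", "wc_correct"]


@dataclass
class WcConfig:
    threshold: float = 5e-8
    n: int = 10_000
    c: float = 20.0

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.c < 0:
            raise ValueError("c must be non-negative")


@dataclass
class WcResult:
    gamma: float
    pairs: pd.DataFrame            # snp_id, exposure_id, z_raw, z_corrected, p_corrected, retained
    retained_snps: list
    retained_exposures: list
    snp_index: np.ndarray          # indices of retained SNPs in the input scan
    pair_mask: np.ndarray          # (n_retained_snps, K) retained associations


def p_to_z(p) -> np.ndarray | float:
    """Two-sided standard-normal quantile |z| = Phi^{-1}(1 - p/2).

    ``scipy``'s isf branch is accurate down to the smallest positive
    doubles, so p-values as extreme as 1e-320 map without overflow.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(p_arr / 2.0)
    return float(z) if np.isscalar(p) else z


def shrinkage_gamma(cfg: WcConfig) -> float:
    """gamma = c / (-log10(threshold) + log10(N)); positive, decreasing in N
    and in the strictness of the threshold."""
    denom = -np.log10(cfg.threshold) + np.log10(cfg.n)
    if denom <= 0:
        raise ValueError("non-positive shrinkage denominator")
    return cfg.c / denom


def wc_correct(scan, cfg: WcConfig, instruments=None) -> WcResult:
    """Shrink and re-select the instrument pairs of a GWAS scan.

    Parameters
    ----------
    scan : GwasScan (full matrix of marginal p-values).
    cfg : WcConfig.
    instruments : optional InstrumentSet from the raw selection; defaults to
        selecting at ``cfg.threshold`` first (the correction operates on
        pairs that already pass the raw threshold).
    """
    from .gwas import select_instruments

    if instruments is None:
        instruments = select_instruments(scan, cfg.threshold)
    gamma = shrinkage_gamma(cfg)
    idx = instruments.snp_index
    mask0 = instruments.pair_mask
    p_raw = scan.p[idx]
    # p -> |z| -> shrink -> corrected p, on the selected pairs only
    with np.errstate(invalid="ignore"):
        z_raw = np.where(mask0, stats.norm.isf(np.minimum(p_raw, 1.0) / 2.0), 0.0)
    z_corr = np.maximum(np.abs(z_raw) - gamma, 0.0)
    p_corr = np.where(mask0, 2.0 * stats.norm.sf(z_corr), 1.0)
    retained = mask0 & (p_corr < cfg.threshold)

    keep_snp = retained.any(axis=1)
    keep_exp = retained.any(axis=0)
    rows = np.nonzero(mask0)
    pairs = pd.DataFrame({
        "snp_id": [instruments.snp_ids[i] for i in rows[0]],
        "exposure_id": [scan.exposure_ids[j] for j in rows[1]],
        "z_raw": z_raw[rows],
        "z_corrected": z_corr[rows],
        "p_corrected": p_corr[rows],
        "retained": retained[rows],
    })
    if not keep_snp.any():
        warnings.warn("winner's-curse correction removed every instrument",
                      stacklevel=2)
        return WcResult(gamma=gamma, pairs=pairs, retained_snps=[],
                        retained_exposures=[],
                        snp_index=np.empty(0, dtype=int),
                        pair_mask=np.empty((0, scan.p.shape[1]), dtype=bool))
    return WcResult(
        gamma=gamma, pairs=pairs,
        retained_snps=[s for s, k in zip(instruments.snp_ids, keep_snp) if k],
        retained_exposures=[e for e, k in zip(scan.exposure_ids, keep_exp) if k],
        snp_index=idx[keep_snp],
        pair_mask=retained[keep_snp],
    )
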