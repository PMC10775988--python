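"""Aligned genotype / exposure / outcome containers and standardization.

All downstream stages assume columns scaled to zero mean and unit variance
(sample variance, N-1 denominator). Genotypes enter as dosages (0/1/2 or
real-valued) and are standardized in place; exposures may first be
residualized on covariates and then re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenoPhenoData",
    "standardize",
    "residualize",
    "load_geno_pheno",
]


def standardize(matrix: np.ndarray, names=None) -> np.ndarray:
    """Scale each column to mean 0, variance 1 (N-1 denominator).

    Parameters
    ----------
    matrix : (N, J) array
    names : optional sequence of column labels used in error messages.

    Raises
    ------
    ValueError
        If N < 2 or any column is constant.
    """
    X = np.asarray(matrix, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("standardize requires at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else str(bad[0])
        raise ValueError(f"constant column: {label}")
    out = (X - mean) / sd
    return out[:, 0] if one_d else out


def residualize(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS-residualize each column on [intercept, covariates], re-standardize.

    Raises if the covariate design (with intercept) is rank deficient, or if
    a column is exactly explained by the covariates (degenerate residual).
    """
    X = np.asarray(matrix, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    n = X.shape[0]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ coef
    # a column lying in the covariate span leaves only rounding noise
    degenerate = resid.std(axis=0) <= 1e-10 * (X.std(axis=0) + 1.0)
    if degenerate.any():
        j = int(np.flatnonzero(degenerate)[0])
        raise ValueError(f"column {j} is fully explained by the covariates")
    out = standardize(resid)
    return out[:, 0] if one_d else out


@dataclass
class GenoPhenoData:
    """Aligned, standardized genotype/exposure/outcome matrices.

    Attributes
    ----------
    G : (N, M) standardized genotype matrix
    X : (N, K) standardized exposure matrix
    Y : (N,) standardized outcome
    covariates : optional (N, Q) matrix (already used for residualization
        upstream; kept for bookkeeping)
    """

    G: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    snp_ids: list = field(default_factory=list)
    exposure_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.G.shape[0]
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise ValueError("G, X, Y must share the sample dimension")
        if self.covariates is not None and np.asarray(self.covariates).shape[0] != n:
            raise ValueError("covariates must share the sample dimension")
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(self.G.shape[1])]
        if not self.exposure_ids:
            self.exposure_ids = [f"x{i}" for i in range(self.X.shape[1])]
        if not self.sample_ids:
            self.sample_ids = list(range(n))
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if len(set(self.exposure_ids)) != len(self.exposure_ids):
            raise ValueError("exposure_ids must be unique")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_raw(cls, G, X, Y, snp_ids=None, exposure_ids=None, sample_ids=None,
                 covariates=None, adjust_outcome: bool = False):
        """Standardize raw inputs; optionally residualize X (and Y) on covariates."""
        if covariates is not None:
            X = residualize(X, covariates)
            if adjust_outcome:
                Y = residualize(Y, covariates)
            else:
                Y = standardize(Y)
        else:
            X = standardize(X)
            Y = standardize(Y)
        G = standardize(G, names=snp_ids)
        return cls(G=G, X=X, Y=Y, snp_ids=list(snp_ids or []),
                   exposure_ids=list(exposure_ids or []),
                   sample_ids=list(sample_ids or []), covariates=covariates)


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}; remove incomplete samples first")
    return df


def load_geno_pheno(genotype_path, exposure_path, outcome_path,
                    covariate_path=None, adjust_outcome: bool = False,
                    logger=None) -> GenoPhenoData:
    """Load delimited tables (rows = samples, first column = sample id),
    align samples by id intersection, and standardize.

    Sample alignment drops rows missing from any table; the dropped count
    is reported through ``logger`` when given.
    """
    g = _read_table(genotype_path)
    x = _read_table(exposure_path)
    y = _read_table(outcome_path)
    frames = [g, x, y]
    cov = None
    if covariate_path is not None:
        cov = _read_table(covariate_path)
        frames.append(cov)
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    n_dropped = max(len(f) for f in frames) - len(common)
    if logger is not None and n_dropped:
        logger.info("dropped %d samples without complete data", n_dropped)
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared across input tables")
    g, x, y = g.loc[common], x.loc[common], y.loc[common]
    cov_arr = cov.loc[common].to_numpy() if cov is not None else None
    return GenoPhenoData.from_raw(
        g.to_numpy(), x.to_numpy(), y.to_numpy()[:, 0],
        snp_ids=list(g.columns), exposure_ids=list(x.columns),
        sample_ids=list(common), covariates=cov_arr,
        adjust_outcome=adjust_outcome)
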