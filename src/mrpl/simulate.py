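"""Synthetic genotype/exposure/outcome generator and the benchmark grid.

The baseline generator draws m independent SNPs from Binomial(2, maf) and
standardizes them. For each of K exposures a fraction pi of SNPs is causal
with effects gamma ~ N(0, hg2/(pi m)), so the causal SNPs jointly explain
hg2 of the exposure's variance. Shared confounders induce the correlation
between exposures and confound the outcome:

    X_k = G gamma_k + sum_{i != k} alpha_{i,k} U_i + eps_k
    Y   = sum_k beta_k X_k + sum_k delta_k U_k + eps_y

with eps ~ N(0, sigma^2), sigma = 0.1, delta ~ U(0, 1), and confounder
variances Var(U_i) = (1 - hg2 - sigma^2) / sum_{k != i} alpha_{i,k}^2 so
that each exposure has approximately unit variance before its final
standardization. alpha is drawn once per (confounder, exposure) pair.

The default grid crosses hg2 in {0.2, 0.3, 0.4, 0.5}, confounder strength
alpha ~ U(0,5) or U(5,10), and six causal-effect laws (discrete
{-b, 0, b} or continuous U(-b, b), b in {0.1, 0.2, 0.3}) — 48 settings.

Two supplementary modes exist: correlated dosages from a Gaussian-copula
AR(1) block model (LD), and direct SNP effects on the outcome added to a
fraction of instrument-eligible SNPs (horizontal pleiotropy). Both are
parametric stand-ins exposing their knobs; the baseline grid does not use
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GenoPhenoData

__all__ = ["SimSetting", "SimReplicate", "setting_grid", "simulate_replicate",
           "simulate_ld", "simulate_pleiotropy"]

BETA_LAWS = (("discrete", 0.1), ("discrete", 0.2), ("discrete", 0.3),
             ("uniform", 0.1), ("uniform", 0.2), ("uniform", 0.3))


@dataclass(frozen=True)
class SimSetting:
    """One cell of the simulation grid."""

    hg2: float = 0.5
    alpha_ux: tuple = (0.0, 5.0)
    beta_law: tuple = ("discrete", 0.3)
    n: int = 10_000
    m: int = 5_000
    k: int = 20
    maf: float = 0.3
    pi: float = 0.05
    sigma: float = 0.1
    delta_uy: tuple = (0.0, 1.0)
    setting_id: int = -1

    def __post_init__(self):
        if self.hg2 + self.sigma ** 2 >= 1:
            raise ValueError("hg2 + sigma^2 must be below 1")

    def label(self) -> str:
        kind, b = self.beta_law
        beta = f"beta~{{-{b},0,{b}}}" if kind == "discrete" else f"beta~U(-{b},{b})"
        return (f"hg2={self.hg2} alpha~U{self.alpha_ux} {beta}")


def setting_grid(n: int = 10_000, m: int = 5_000, k: int = 20) -> list[SimSetting]:
    """The 48-setting grid, enumerated lexicographically by
    (hg2, alpha range, causal-effect law)."""
    grid = []
    i = 0
    for hg2 in (0.2, 0.3, 0.4, 0.5):
        for alpha in ((0.0, 5.0), (5.0, 10.0)):
            for law in BETA_LAWS:
                grid.append(SimSetting(hg2=hg2, alpha_ux=alpha, beta_law=law,
                                       n=n, m=m, k=k, setting_id=i))
                i += 1
    return grid


@dataclass
class SimReplicate:
    data: GenoPhenoData
    beta_true: np.ndarray          # causal effects on the standardized scale
    beta_raw: np.ndarray           # causal effects on the generative scale
    gamma_true: np.ndarray         # (m, k) SNP effects on exposures
    causal_mask: np.ndarray        # (m, k) bool
    confounders: np.ndarray        # (n, k)
    setting: SimSetting
    x_scale: np.ndarray = field(default=None)
    y_scale: float = 1.0
    pleiotropy_snps: np.ndarray | None = None


def _draw_dosages(rng, n, m, maf):
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    # monomorphic columns cannot be standardized; redraw them
    for _ in range(100):
        sd = G.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size == 0:
            break
        G[:, bad] = rng.binomial(2, maf, size=(n, bad.size))
    return G


def _draw_dosages_ld(rng, n, m, maf, block_size, rho):
    """Gaussian-copula dosages: AR(1) latent normals per block, thresholded
    at the Binomial allele-frequency quantile, summed over two haplotypes."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    cut = stats.norm.ppf(maf)
    G = np.empty((n, m))
    scale = np.sqrt(1.0 - rho ** 2)
    for start in range(0, m, block_size):
        width = min(block_size, m - start)
        dosage = np.zeros((n, width))
        for _hap in range(2):
            z = np.empty((n, width))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, width):
                z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(n)
            dosage += (z < cut).astype(float)
        G[:, start:start + width] = dosage
    for _ in range(100):
        sd = G.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size == 0:
            break
        G[:, bad] = rng.binomial(2, maf, size=(n, bad.size))
    return G


def _standardize_cols(A):
    return (A - A.mean(axis=0)) / A.std(axis=0, ddof=1)


def _simulate(setting: SimSetting, rng, geno_fn, frac_pleiotropic=0.0,
              pleiotropy_sd=0.0) -> SimReplicate:
    n, m, k = setting.n, setting.m, setting.k
    G = _standardize_cols(geno_fn(rng, n, m, setting.maf))

    causal = rng.random((m, k)) < setting.pi
    for _ in range(100):
        empty = np.flatnonzero(~causal.any(axis=0))
        if empty.size == 0:
            break
        causal[:, empty] = rng.random((m, empty.size)) < setting.pi
    gamma = np.zeros((m, k))
    eff_sd = np.sqrt(setting.hg2 / (setting.pi * m))
    gamma[causal] = rng.normal(0.0, eff_sd, size=int(causal.sum()))

    lo, hi = setting.alpha_ux
    alpha = rng.uniform(lo, hi, size=(k, k))      # alpha[i, j]: U_i -> X_j
    off_diag = ~np.eye(k, dtype=bool)
    conf_var = 1.0 - setting.hg2 - setting.sigma ** 2
    denom = np.where(off_diag, alpha ** 2, 0.0).sum(axis=1)
    u_sd = np.sqrt(conf_var / denom)
    U = rng.standard_normal((n, k)) * u_sd

    eps_x = rng.normal(0.0, setting.sigma, size=(n, k))
    X = G @ gamma + U @ np.where(off_diag, alpha, 0.0) + eps_x

    kind, b = setting.beta_law
    if kind == "discrete":
        beta_raw = rng.choice([-b, 0.0, b], size=k)
    elif kind == "uniform":
        beta_raw = rng.uniform(-b, b, size=k)
    else:
        raise ValueError(f"unknown causal-effect law {kind!r}")
    delta = rng.uniform(*setting.delta_uy, size=k)
    eps_y = rng.normal(0.0, setting.sigma, size=n)
    Y = X @ beta_raw + U @ delta + eps_y

    pleio_idx = None
    if frac_pleiotropic > 0:
        if not 0 <= frac_pleiotropic <= 1:
            raise ValueError("frac_pleiotropic must lie in [0, 1]")
        eligible = np.flatnonzero(causal.any(axis=1))
        chosen = eligible[rng.random(eligible.size) < frac_pleiotropic]
        if chosen.size:
            Y = Y + G[:, chosen] @ rng.normal(0.0, pleiotropy_sd, size=chosen.size)
        pleio_idx = chosen

    x_sd = X.std(axis=0, ddof=1)
    y_sd = Y.std(ddof=1)
    X_std = (X - X.mean(axis=0)) / x_sd
    Y_std = (Y - Y.mean()) / y_sd
    # causal effects on the all-standardized scale used for estimation
    beta_true = beta_raw * x_sd / y_sd

    data = GenoPhenoData(G=G, X=X_std, Y=Y_std)
    return SimReplicate(data=data, beta_true=beta_true, beta_raw=beta_raw,
                        gamma_true=gamma, causal_mask=causal, confounders=U,
                        setting=setting, x_scale=x_sd, y_scale=float(y_sd),
                        pleiotropy_snps=pleio_idx)


def simulate_replicate(setting: SimSetting, seed) -> SimReplicate:
    """One baseline replicate (independent SNPs, no pleiotropy)."""
    rng = np.random.default_rng(seed)
    return _simulate(setting, rng, _draw_dosages)


def simulate_ld(setting: SimSetting, seed, block_size: int = 10,
                rho: float = 0.5) -> SimReplicate:
    """Replicate with AR(1)-correlated dosages in blocks of ``block_size``."""
    rng = np.random.default_rng(seed)

    def geno(rng_, n, m, maf):
        return _draw_dosages_ld(rng_, n, m, maf, block_size, rho)

    return _simulate(setting, rng, geno)


def simulate_pleiotropy(setting: SimSetting, seed, frac_pleiotropic: float = 0.3,
                        effect_sd: float = 0.05) -> SimReplicate:
    """Replicate where a fraction of instrument-eligible SNPs also act on
    the outcome directly (violating exclusion restriction)."""
    rng = np.random.default_rng(seed)
    return _simulate(setting, rng, _draw_dosages,
                     frac_pleiotropic=frac_pleiotropic, pleiotropy_sd=effect_sd)
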