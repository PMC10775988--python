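"""MR-PL model and results objects.

``MRPL`` bundles the whole one-sample multivariable MR pipeline behind a
statsmodels-style interface: build the model from aligned individual-level
data, call :meth:`MRPL.fit`, and read estimates, de-sparsified p-values and
diagnostics off the returned :class:`MRPLResults`.

Pipeline per fit: marginal GWAS scan -> instrument selection at the
p-value threshold -> optional winner's-curse re-selection -> first-stage
PLS2 with CV-chosen component count -> second-stage Lasso with CV-chosen
penalty -> de-sparsified inference -> Sargan pleiotropy test and
instrument-strength report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenoPhenoData
from .diagnostics import SarganResult, StrengthReport, sargan_test, strength_report
from .gwas import GwasScan, InstrumentSet, marginal_gwas, select_instruments
from .lasso import DesparsifiedResult, LassoFit, call_causal, desparsify, lasso_fit
from .pls import PLSFit, cross_validate_components, fit_pls
from .winners_curse import WcConfig, WcResult, wc_correct

__all__ = ["MRPL", "MRPLResults"]


class MRPL:
    """One-sample multivariable MR of exposures X on outcome Y with
    genotype instruments G.

    Parameters
    ----------
    data : GenoPhenoData
        Aligned, standardized matrices.
    instrument_threshold : float
        Marginal p-value cutoff for instrument selection (default 5e-8).
    winners_curse : WcConfig | float | bool | None
        ``None``/``False`` disables the correction; ``True`` uses the
        recommended c = 20; a float sets c; a WcConfig is used as given
        (its threshold/n are overridden to match the scan).
    """

    def __init__(self, data: GenoPhenoData, instrument_threshold: float = 5e-8,
                 winners_curse=None):
        self.data = data
        self.instrument_threshold = float(instrument_threshold)
        if winners_curse is None or winners_curse is False:
            self.wc_config = None
        elif winners_curse is True:
            self.wc_config = WcConfig(threshold=self.instrument_threshold, n=data.n)
        elif isinstance(winners_curse, WcConfig):
            self.wc_config = WcConfig(threshold=self.instrument_threshold,
                                      n=data.n, c=winners_curse.c)
        else:
            self.wc_config = WcConfig(threshold=self.instrument_threshold,
                                      n=data.n, c=float(winners_curse))

    @classmethod
    def from_arrays(cls, Y, X, G, snp_ids=None, exposure_ids=None,
                    standardized: bool = False, covariates=None, **kw) -> "MRPL":
        if standardized:
            data = GenoPhenoData(G=G, X=X, Y=Y, snp_ids=list(snp_ids or []),
                                 exposure_ids=list(exposure_ids or []))
        else:
            data = GenoPhenoData.from_raw(G, X, Y, snp_ids=snp_ids,
                                          exposure_ids=exposure_ids,
                                          covariates=covariates)
        return cls(data, **kw)

    @classmethod
    def from_dataframes(cls, genotypes: pd.DataFrame, exposures: pd.DataFrame,
                        outcome: pd.Series, covariates: pd.DataFrame = None,
                        **kw) -> "MRPL":
        common = genotypes.index.intersection(exposures.index).intersection(
            outcome.index)
        if covariates is not None:
            common = common.intersection(covariates.index)
        cov = covariates.loc[common].to_numpy() if covariates is not None else None
        return cls.from_arrays(
            outcome.loc[common].to_numpy(), exposures.loc[common].to_numpy(),
            genotypes.loc[common].to_numpy(), snp_ids=list(genotypes.columns),
            exposure_ids=list(exposures.columns), covariates=cov, **kw)

    def fit(self, folds: int = 10, seed: int = 0, max_components: int | None = None,
            inference: bool = True, compute_sargan: bool = True,
            compute_strength: bool = False, alpha: float = 0.05,
            scan: GwasScan | None = None) -> "MRPLResults":
        data = self.data
        if scan is None:
            scan = marginal_gwas(data)
        raw_instruments = select_instruments(scan, self.instrument_threshold)
        wc_result = None
        if self.wc_config is not None:
            wc_result = wc_correct(scan, self.wc_config, raw_instruments)
            if wc_result.snp_index.size == 0:
                raise ValueError("winner's-curse correction removed every "
                                 "instrument; rerun without correction or "
                                 "relax the threshold")
            snp_index, pair_mask = wc_result.snp_index, wc_result.pair_mask
        else:
            snp_index, pair_mask = raw_instruments.snp_index, raw_instruments.pair_mask
        kept = np.flatnonzero(pair_mask.any(axis=0))
        G_sel = data.G[:, snp_index]
        X_kept = data.X[:, kept]
        r_opt, cv_curve = cross_validate_components(
            G_sel, X_kept, folds=folds, max_r=max_components, seed=seed)
        pls_fit = fit_pls(G_sel, X_kept, r=r_opt,
                          snp_ids=[data.snp_ids[i] for i in snp_index])
        pls_fit.cv_mse = cv_curve
        Xhat = G_sel @ pls_fit.C
        lfit = lasso_fit(Xhat, data.Y, folds=folds, seed=seed)
        desp = desparsify(Xhat, data.Y, lfit, folds=folds, seed=seed) if inference else None

        k_full = data.k
        beta = np.zeros(k_full)
        beta[kept] = lfit.beta
        beta_deb = np.full(k_full, np.nan)
        bse = np.full(k_full, np.nan)
        pvals = np.full(k_full, np.nan)
        if desp is not None:
            beta_deb[kept] = desp.beta_debiased
            bse[kept] = desp.se
            pvals[kept] = desp.p

        sargan = None
        if compute_sargan and G_sel.shape[1] > X_kept.shape[1]:
            sargan = sargan_test(G_sel, Xhat, data.Y, lfit.beta)
        strength = None
        if compute_strength:
            strength = strength_report(
                G_sel, X_kept,
                exposure_ids=[data.exposure_ids[i] for i in kept],
                pair_mask=pair_mask[:, kept])

        return MRPLResults(
            model=self, params=beta, params_debiased=beta_deb, bse=bse,
            pvalues=pvals, kept_exposures=kept, alpha=alpha,
            instruments=raw_instruments, wc_result=wc_result,
            snp_index=snp_index, pair_mask=pair_mask, pls=pls_fit,
            lasso=lfit, desparsified=desp, sargan=sargan, strength=strength,
            fitted_exposures=Xhat, seed=seed)


@dataclass
class MRPLResults:
    """Causal-effect estimates and diagnostics from an MR-PL fit.

    ``params`` holds the Lasso causal estimates on the standardized scale
    (exposures dropped during selection carry 0); ``pvalues`` are the
    de-sparsified Lasso p-values (NaN for dropped exposures).
    """

    model: MRPL
    params: np.ndarray
    params_debiased: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    kept_exposures: np.ndarray
    alpha: float
    instruments: InstrumentSet
    wc_result: WcResult | None
    snp_index: np.ndarray
    pair_mask: np.ndarray
    pls: PLSFit
    lasso: LassoFit
    desparsified: DesparsifiedResult | None
    sargan: SarganResult | None
    strength: StrengthReport | None
    fitted_exposures: np.ndarray
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def exposure_ids(self) -> list:
        return list(self.model.data.exposure_ids)

    @property
    def causal(self) -> np.ndarray:
        """Verdict per exposure: nonzero estimate AND p below alpha."""
        with np.errstate(invalid="ignore"):
            return (self.params != 0) & (self.pvalues < self.alpha)

    @property
    def n_instruments(self) -> int:
        return int(self.snp_index.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure_id": self.exposure_ids,
            "beta": self.params,
            "beta_debiased": self.params_debiased,
            "se": self.bse,
            "p": self.pvalues,
            "causal": self.causal,
        })

    def summary(self) -> str:
        data = self.model.data
        lines = [
            "MR-PL: one-sample multivariable Mendelian randomization",
            "=" * 56,
            f"samples: {data.n}    candidate SNPs: {data.m}    exposures: {data.k}",
            f"instruments retained: {self.n_instruments} "
            f"(threshold {self.model.instrument_threshold:g}"
            + (f", winner's-curse c={self.model.wc_config.c:g}, "
               f"gamma={self.wc_result.gamma:.4f}" if self.wc_result else "")
            + ")",
            f"PLS components: {self.pls.r}    "
            f"Lasso lambda: {self.lasso.lambda_opt:.4g}    "
            f"active exposures: {self.lasso.n_active}",
        ]
        if self.sargan is not None:
            flag = "  [unreliable: possible pleiotropy]" if self.sargan.unreliable else ""
            lines.append(f"Sargan S={self.sargan.S:.3f} (df={self.sargan.df}), "
                         f"p={self.sargan.p:.4g}{flag}")
        lines.append("-" * 56)
        lines.append(f"{'exposure':<16}{'beta':>10}{'p':>12}  causal")
        for i, eid in enumerate(self.exposure_ids):
            pv = self.pvalues[i]
            p_str = f"{pv:.3g}" if np.isfinite(pv) else "--"
            mark = "*" if self.causal[i] else ""
            lines.append(f"{str(eid):<16}{self.params[i]:>10.4f}{p_str:>12}  {mark}")
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """Plot the PLS component-count CV curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.pls.cv_mse
        ax.plot(np.arange(1, len(curve) + 1), curve, marker="o")
        ax.axvline(self.pls.r, ls="--", color="grey")
        ax.set_xlabel("PLS components")
        ax.set_ylabel("CV MSE of held-out exposures")
        return ax
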