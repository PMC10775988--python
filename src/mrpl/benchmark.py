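"""Replication driver and metric aggregation for the simulation benchmark.

Per replication the protocol mirrors a real one-sample MR analysis: a
marginal GWAS on the simulated cohort, instrument selection at the
p-value threshold, an optional winner's-curse re-selection, estimation by
each requested method, and the Sargan pleiotropy test. Metrics per
setting: MSE (mean squared estimation error over exposures and
replications), bias (mean absolute error), variance (across-replication
variance of the error), type-I error and power at the 5% nominal level,
and the percentage MSE decrease attributable to the winner's-curse
correction (delta-MSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparators import COMPARATORS, pls_penalty_variant
from .diagnostics import sargan_test, strength_report
from .gwas import marginal_gwas, select_instruments
from .lasso import desparsify, lasso_fit
from .pls import cross_validate_components, fit_pls
from .simulate import SimSetting, simulate_replicate
from .winners_curse import WcConfig, wc_correct

__all__ = ["ReplicationResult", "SimReport", "run_replication", "run_setting",
           "aggregate_metrics", "delta_mse", "tune_c"]

PLS_VARIANTS = {"pls_ridge": "ridge", "pls_elasticnet": "elasticnet",
                "pls_lars": "lars"}


@dataclass
class ReplicationResult:
    estimates: dict                 # method -> (K,) causal estimates
    rejections: dict                # method -> (K,) bool or None
    n_instruments: int
    kept_exposures: np.ndarray
    sargan_p: float | None = None
    f_sw: np.ndarray | None = None
    failed: bool = False


@dataclass
class SimReport:
    setting: SimSetting
    n_reps: int
    metrics: pd.DataFrame           # rows = methods; mse, bias, variance, type1, power
    mean_instruments: float

    def mse(self, method: str) -> float:
        return float(self.metrics.loc[method, "mse"])


def _estimate_once(G_sel, X_kept, Y, pair_mask_kept, methods, folds, seed,
                   inference, alpha):
    """Run every requested estimator on one instrument/exposure selection."""
    out_beta, out_rej = {}, {}
    pls_needed = "mrpl" in methods or any(m in PLS_VARIANTS for m in methods)
    mrpl_beta_kept = None
    Xhat = None
    if pls_needed:
        r_opt, _ = cross_validate_components(G_sel, X_kept, folds=folds, seed=seed)
        pfit = fit_pls(G_sel, X_kept, r=r_opt)
        Xhat = G_sel @ pfit.C
        if "mrpl" in methods:
            lfit = lasso_fit(Xhat, Y, folds=folds, seed=seed)
            mrpl_beta_kept = lfit.beta
            rej = None
            if inference:
                desp = desparsify(Xhat, Y, lfit, folds=folds, seed=seed)
                rej = (lfit.beta != 0) & (desp.p < alpha)
            out_beta["mrpl"] = lfit.beta
            out_rej["mrpl"] = rej
        for name, penalty in PLS_VARIANTS.items():
            if name in methods:
                res = pls_penalty_variant(Xhat, Y, penalty, folds=folds, seed=seed)
                out_beta[name] = res.beta
                out_rej[name] = None
    for name, func in COMPARATORS.items():
        if name in methods:
            res = func(G_sel, X_kept, Y, pair_mask_kept)
            out_beta[name] = res.beta
            with np.errstate(invalid="ignore"):
                out_rej[name] = (np.nan_to_num(res.p, nan=1.0) < alpha
                                 ) if res.p is not None else None
    return out_beta, out_rej, mrpl_beta_kept, Xhat


def run_replication(rep, methods=("mrpl",), wc_config: WcConfig | None = None,
                    threshold: float = 5e-8, folds: int = 10, seed: int = 0,
                    inference: bool = True, diagnostics: bool = False,
                    strength: bool = False, alpha: float = 0.05,
                    scan=None) -> ReplicationResult:
    """The per-replication protocol; returns full-K estimate vectors
    (exposures dropped during selection carry estimate 0)."""
    data = rep.data
    if scan is None:
        scan = marginal_gwas(data)
    try:
        instruments = select_instruments(scan, threshold)
    except ValueError:
        return ReplicationResult({}, {}, 0, np.empty(0, int), failed=True)
    if wc_config is not None:
        cfg = WcConfig(threshold=threshold, n=data.n, c=wc_config.c)
        wres = wc_correct(scan, cfg, instruments)
        if wres.snp_index.size == 0:
            return ReplicationResult({}, {}, 0, np.empty(0, int), failed=True)
        snp_index, pair_mask = wres.snp_index, wres.pair_mask
    else:
        snp_index, pair_mask = instruments.snp_index, instruments.pair_mask
    kept = np.flatnonzero(pair_mask.any(axis=0))
    G_sel = data.G[:, snp_index]
    X_kept = data.X[:, kept]
    beta_kept, rej_kept, mrpl_beta, Xhat = _estimate_once(
        G_sel, X_kept, data.Y, pair_mask[:, kept], methods, folds, seed,
        inference, alpha)

    k = data.k
    estimates, rejections = {}, {}
    for name, b in beta_kept.items():
        full = np.zeros(k)
        full[kept] = np.nan_to_num(b, nan=0.0)
        estimates[name] = full
        r = rej_kept[name]
        if r is None:
            rejections[name] = None
        else:
            fr = np.zeros(k, dtype=bool)
            fr[kept] = r
            rejections[name] = fr

    sargan_p = None
    if (diagnostics and mrpl_beta is not None and Xhat is not None
            and G_sel.shape[1] > X_kept.shape[1]):
        sargan_p = sargan_test(G_sel, Xhat, data.Y, mrpl_beta).p
    f_sw = None
    if strength:
        rep_strength = strength_report(G_sel, X_kept, pair_mask=pair_mask[:, kept])
        f_sw = rep_strength.f_sw
    return ReplicationResult(estimates=estimates, rejections=rejections,
                             n_instruments=int(snp_index.size),
                             kept_exposures=kept, sargan_p=sargan_p, f_sw=f_sw)


def aggregate_metrics(results: list[ReplicationResult],
                      beta_true: list[np.ndarray],
                      setting: SimSetting | None = None) -> SimReport:
    """Aggregate MSE / bias / variance / type-I / power over replications.

    Type-I and power are per-replication rates (fraction of true-null /
    true-nonnull exposures rejected) averaged over replications; methods
    without a rejection rule report estimation metrics only.
    """
    pairs = [(r, bt) for r, bt in zip(results, beta_true) if not r.failed]
    if len(pairs) < 2:
        raise ValueError("need at least 2 successful replications")
    methods = list(pairs[0][0].estimates)
    rows = []
    for method in methods:
        errs = np.stack([r.estimates[method] - bt for r, bt in pairs])
        mse = float(np.mean(errs ** 2))
        bias = float(np.mean(np.abs(errs)))
        variance = float(np.mean(np.var(errs, axis=0, ddof=1)))
        t1_rates, pow_rates = [], []
        for (r, bt) in pairs:
            rej = r.rejections.get(method)
            if rej is None:
                continue
            nulls = bt == 0
            if nulls.any():
                t1_rates.append(float(rej[nulls].mean()))
            if (~nulls).any():
                pow_rates.append(float(rej[~nulls].mean()))
        rows.append({
            "method": method, "mse": mse, "bias": bias, "variance": variance,
            "type1": float(np.mean(t1_rates)) if t1_rates else np.nan,
            "power": float(np.mean(pow_rates)) if pow_rates else np.nan,
        })
    metrics = pd.DataFrame(rows).set_index("method")
    return SimReport(setting=setting, n_reps=len(pairs), metrics=metrics,
                     mean_instruments=float(np.mean([r.n_instruments
                                                     for r, _ in pairs])))


def run_setting(setting: SimSetting, reps: int, master_seed: int = 0,
                methods=("mrpl",), wc_config: WcConfig | None = None,
                threshold: float = 5e-8, folds: int = 10,
                inference: bool = True, compare_wc: bool = False,
                strength: bool = False, simulate=simulate_replicate):
    """Run one grid cell. With ``compare_wc`` the same replicates (and the
    same GWAS scan) are analysed both with and without the winner's-curse
    correction; returns (report_without, report_with) in that case.

    Seeds: replicate t of setting s uses the stream spawned from
    (master_seed, s, t), so any cell is reproducible in isolation.
    """
    res_plain, res_wc, truths = [], [], []
    for t in range(reps):
        ss = np.random.SeedSequence(master_seed,
                                    spawn_key=(max(setting.setting_id, 0), t))
        rep = simulate(setting, np.random.default_rng(ss))
        fit_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        scan = marginal_gwas(rep.data)
        # metrics are on the generative scale: estimates from the
        # standardized data are compared to the drawn causal effects, the
        # outcome's standardization factor being part of the error
        truths.append(rep.beta_raw)
        if compare_wc or wc_config is None:
            res_plain.append(run_replication(
                rep, methods, None, threshold, folds, fit_seed, inference,
                strength=strength, scan=scan))
        if compare_wc or wc_config is not None:
            cfg = wc_config or WcConfig(threshold=threshold, n=setting.n)
            res_wc.append(run_replication(
                rep, methods, cfg, threshold, folds, fit_seed, inference,
                strength=strength, scan=scan))
    if compare_wc:
        return (aggregate_metrics(res_plain, truths, setting),
                aggregate_metrics(res_wc, truths, setting))
    picked = res_wc if wc_config is not None else res_plain
    return aggregate_metrics(picked, truths, setting)


def delta_mse(reports_nowc, reports_wc, method: str = "mrpl"):
    """Percentage MSE decrease per setting and its unweighted average.

    Accepts two parallel lists of SimReport (or two mappings id -> mse).
    Settings with zero uncorrected MSE are skipped.
    """
    if isinstance(reports_nowc, dict):
        items = [(sid, reports_nowc[sid], reports_wc[sid]) for sid in reports_nowc]
    else:
        items = [(r0.setting.setting_id if r0.setting else i,
                  r0.mse(method), r1.mse(method))
                 for i, (r0, r1) in enumerate(zip(reports_nowc, reports_wc))]
    per_setting = {}
    for sid, m0, m1 in items:
        if m0 == 0:
            continue
        per_setting[sid] = 100.0 * (m0 - m1) / m0
    avg = float(np.mean(list(per_setting.values()))) if per_setting else np.nan
    return per_setting, avg


def tune_c(c_grid, settings, threshold: float = 5e-8, reps: int = 20,
           master_seed: int = 0, methods=("mrpl",), folds: int = 10,
           inference: bool = False) -> pd.DataFrame:
    """Average delta-MSE over ``settings`` for each shrinkage constant c.

    Returns a DataFrame (c, delta_mse) sorted by c; the recommended c is
    the argmax, ties resolved to the smaller c.
    """
    rows = []
    for c in c_grid:
        nowc, wc = [], []
        for setting in settings:
            r0, r1 = run_setting(setting, reps, master_seed, methods,
                                 wc_config=WcConfig(threshold=threshold,
                                                    n=setting.n, c=c),
                                 threshold=threshold, folds=folds,
                                 inference=inference, compare_wc=True)
            nowc.append(r0)
            wc.append(r1)
        _, avg = delta_mse(nowc, wc)
        rows.append({"c": c, "delta_mse": avg})
    df = pd.DataFrame(rows)
    if len(df):
        df.attrs["recommended_c"] = float(
            df[df["delta_mse"] == df["delta_mse"].max()]["c"].min())
    return df
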