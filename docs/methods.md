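# Methods

## The model

`mrpl` estimates the causal effects of K correlated exposures
X = (X_1, …, X_K) on an outcome Y from individual-level data of a single
cohort, using M genetic variants G as instruments — one-sample
multivariable Mendelian randomization. The structural model is

    X = G C + E            (first stage: genetic prediction of exposures)
    Y = X̂ β + ε            (second stage: outcome on fitted exposures)

with all columns of G, X and Y standardized to mean 0, variance 1
(sample variance, N−1 denominator). β_k is the causal effect of exposure k
per standard deviation, holding the other exposures fixed. Valid inference
needs the usual instrumental-variable assumptions: each instrument is
associated with at least one exposure, independent of confounders, and
affects Y only through the modelled exposures; the Sargan test (below)
screens violations of the last assumption.

### First stage: PLS2

With hundreds of instruments and tens of mutually correlated exposures,
per-exposure OLS first stages overfit and ignore the cross-exposure
structure. The first stage is therefore partial least squares (PLS2).
Component i maximizes cov(Gρ, Xγ) under ‖ρ‖=‖γ‖=1: ρ⁽ⁱ⁾ is the leading
eigenvector of GᵀXXᵀG (computed as the leading left singular vector of
A = GᵀX, with singular value θ), γ⁽ⁱ⁾ = XᵀGρ⁽ⁱ⁾/θ. The G-score
û = Gρ⁽ⁱ⁾ then deflates both blocks by its OLS fit,
σ⁽ⁱ⁾ = Gᵀû/‖û‖², τ⁽ⁱ⁾ = Xᵀû/‖û‖², G ← G − ûσ⁽ⁱ⁾ᵀ, X ← X − ûτ⁽ⁱ⁾ᵀ.
After r components the coefficient matrix is Ĉ = P(ΣᵀP)⁻¹Tᵀ (columns of
P, Σ, T are the ρ, σ, τ vectors; the r×r core is inverted with a
pseudo-inverse, rcond 1e-10). Deflating with the predictor-block score
keeps successive scores exactly orthogonal, and at r = rank(G) the fit
coincides with the OLS projection of X onto col(G) — both are tested.

Implementation note: after the rank-1 deflation, the cross-product obeys
A ← A − ‖û‖²στᵀ, so each additional component costs O(NM) rather than
O(NMK); this is what makes 10-fold cross-validation over component counts
affordable at N = 10⁴, M ≈ 10³.

r is chosen by 10-fold CV on held-out exposure MSE (unweighted over the K
columns), searched up to min(K, M, N·9/10 − 1) — exposures rarely support
more useful components than K — with ties broken to the smallest r.
Loadings are sign-fixed (largest-magnitude entry positive); predictions
are invariant to the sign convention.

A leave-one-out jackknife on the PLS coefficients gives per-(SNP,
exposure) t-tests: the coefficient is refit N times with one sample held
out (r fixed at the full-data optimum), the jackknife variance is
((N−1)/N)·Σᵢ(ĉ₋ᵢ − c̄)², and t = ĉ/ŝe on N−1 df. Entries whose
leave-one-out coefficients are identical (variance 0 up to rounding) are
flagged degenerate. Because this is O(N) refits, N is capped (default
500) unless forced.

### Second stage: Lasso with de-sparsified inference

β̂ minimizes ‖Y − X̂β‖² + λ‖β‖₁, the penalty searched over 100 log-spaced
values with exponents on [−2, 10] and chosen by 10-fold CV; ties prefer
the larger λ (sparser model). No intercept is fitted and the X̂ columns
are not re-standardized inside the solver (their variance is ≤ 1 by
construction; rescaling would change the objective). The coordinate
descent solver works in the mean-loss parameterization (α = λ/2N); the
final solution is refit at tolerance 1e-10 so the reported coefficients
satisfy the KKT conditions of the un-normalized objective to ~1e-6.

P-values come from the de-sparsified (debiased) Lasso. For each j a
nodewise Lasso of X̂_j on X̂_{−j} (penalty CV-selected per column on the
same fold stream) gives the residual direction Z_j; then

    b_j = β̂_j + Z_jᵀ(Y − X̂β̂)/(Z_jᵀX̂_j),
    se_j = σ̂_ε ‖Z_j‖ / |Z_jᵀX̂_j|,    p_j = 2(1 − Φ(|b_j|/se_j)),

with σ̂_ε = ‖Y − X̂β̂‖/√(N − ŝ), ŝ the active-set size. With K = 1 the
construction degenerates to simple-regression inference. An exposure is
called causal when β̂_k ≠ 0 AND p_k < 0.05 — both the sparsity event and
the test must agree.

### Winner's-curse correction

Selecting instruments at a p-value threshold in the same cohort used for
estimation inflates the selected associations. The correction
soft-thresholds each selected pair's |z| by

    γ = c / (−log₁₀(threshold) + log₁₀(N)),   c = 20 by default,

recomputes p from the shrunk z under the standard normal, and re-applies
the selection threshold; SNPs and exposures left without a retained pair
are dropped before the first stage. γ is decreasing in N and increasing
for looser thresholds, which is the behaviour the correction is designed
to have; the retained set equals raw selection at the implied stricter
cutoff z(threshold) + γ (a tested identity). Only p-values are needed, so
the correction also runs in summary-statistics-only mode. c = 20 is the
recommended default; robustness at neighbouring c (15, 25) should be
checked in applications, and `tune_c` reproduces the ΔMSE-based selection
of c in simulation.

### Diagnostics

* Sargan over-identification test: ε̂ = Y − X̂β̂ (β̂ the full second-stage
  vector, zeros included) regressed on all instruments with intercept;
  S = N·R² ~ χ²(M − K) under no horizontal pleiotropy; p < 0.05 flags the
  fit as unreliable. Centered R²; requires M > K.
* Joint instrument strength per exposure: F = R²(N−M−1)/((1−R²)M) with R²
  the variance of the exposure explained by its own associated
  instruments.
* Sanderson–Windmeijer conditional F: the exposure is residualized on the
  instrument-predicted values of the other exposures, the residual is
  regressed on the full instrument set, and the F-statistic uses M−K+1
  numerator df. Values below ~10 indicate conditional weakness; in this
  design (many correlated exposures, polygenic instruments) the pooled
  mean sits near 4–6 even in ideal simulations, so the rule of thumb is
  of limited use here.

### Comparator estimators

Multi-2SLS (joint first and second stages, Eq-form
[XᵀP_G X]⁻¹XᵀP_G Y), Uni-2SLS (per exposure, own instruments only),
PRS-2SLS (unweighted mean allele score as a single instrument), and an
MV-IWAS-like estimator (exposure-specific first stages, joint second
stage). Their p-values are conventional 2SLS t-tests whose error variance
uses the structural residual Y − Xβ̂ with the original exposures — the
naive usage being benchmarked, not a corrected one. Ridge, elastic-net
(mixing parameter CV-selected over 0.1…0.9) and LARS variants replace the
second-stage Lasso for estimation-only comparisons. A published
joint-selection framework that transforms exposures into synthetic
composites is intentionally not re-implemented; the estimator registry
accepts external adapters.

## The synthetic cohort generator

Baseline conditions (the study conditions, not tuning knobs): N = 10,000
samples, m = 5,000 SNPs drawn i.i.d. Binomial(2, 0.3) and standardized,
K = 20 exposures, causal-SNP probability π = 0.05 per exposure, SNP
effects γ ~ N(0, hg²/(πm)) so the causal SNPs explain hg² of each
exposure's variance, residual sd σ = 0.1. K shared confounders:
α_{i,k} ~ U(0,5) or U(5,10) once per (confounder, exposure) pair,
Var(U_i) = (1 − hg² − σ²)/Σ_{k≠i}α_{i,k}², giving exposures approximate
unit variance before standardization (mean within [0.9, 1.1]; individual
columns spread roughly [0.7, 1.5] at K = 20 because the α-weight sums
fluctuate) and mean pairwise exposure correlations
≈ (K−2)/(K−1)·E[α]²/E[α²]·(1−hg²−σ²), spanning ~0.35 to ~0.72 across the
grid. Outcome: Y = Σβ_k X_k + Σδ_k U_k + ε, δ ~ U(0,1), then Y is
standardized. The grid crosses hg² ∈ {0.2, 0.3, 0.4, 0.5}, the two α
ranges, and six causal-effect laws ({−b,0,b} or U(−b,b), b ∈ {0.1, 0.2,
0.3}) — 48 settings, enumerated lexicographically.

Exposure columns that draw zero causal SNPs are re-drawn (vanishingly
rare at π·m = 250); monomorphic genotype columns likewise.

Two supplementary modes are parametric constructions exposing their
knobs, not reconstructions of any specific published recipe: correlated
dosages via a Gaussian copula (AR(1) latent blocks thresholded at the
allele-frequency quantile, two haplotype draws summed — the implied
dosage correlation has a closed-form orthant-probability oracle used in
tests), and horizontal pleiotropy via direct N(0, sd²) SNP effects on Y
for a fraction of instrument-eligible SNPs.

What the generator does not emulate: linkage disequilibrium from real
haplotypes, allele-frequency spectra, non-Gaussian confounding, binary or
ascertained outcomes, population structure. Passing benchmarks here show
the estimator behaves as designed under its own assumptions; they do not
certify behaviour on real cohort data.

## Benchmark protocol and metrics

Each replication mimics a real analysis end to end: marginal GWAS on the
simulated cohort (slope = correlation for standardized data; two-sided
t-test, N−2 df), instrument selection at p < 5e-8 (SNPs associated with
at least one exposure), optional winner's-curse re-selection, estimation
by each method, diagnostics. Per-(setting, replication) random streams
are spawned from a master seed so any cell reproduces in isolation.

Metrics compare the estimates — obtained from fully standardized data —
against the causal effects on the generative scale, with no rescaling:
the outcome's standardization factor is deliberately part of the error.
This convention is what makes "hard" settings hard: with weak effects and
strong exposure correlation, Var(Y) strays far from 1 and every estimate
is off by the factor 1/sd(Y), which dominates the MSE. (The
scale-consistent truth, β·sd(X_k)/sd(Y), is kept on each replicate as
`beta_true` for users who want scale-adjusted errors.) MSE is the mean
squared error over exposures and replications; bias the mean absolute
error; variance the across-replication variance of the error; type-I
error and power are per-replication rates at the 5% level averaged over
replications, a rejection being the causal verdict for MR-PL and p < 0.05
for the 2SLS-family methods. ΔMSE is the percentage MSE decrease from the
winner's-curse correction, per setting and averaged unweighted.

## Desk-scale presets and known limitations

Down-scaled runs use n = 2,000, m = 1,000 with reduced replications.
This scaling preserves each causal SNP's selection non-centrality exactly
(N·hg²/(πm) is invariant), hence the *fraction* of SNPs selected, but not
the absolute number of instruments per exposure. Consequences measured on
the full 48-setting scaled grid: the winner's-curse correction improves
MSE in a majority of settings (29/48; median ΔMSE +2.6%) but the
unweighted average is dominated by a few cells where the correction
strips a desk-scale instrument set from ~66 to ~14 SNPs — an artifact
impossible at m = 5,000, where the same settings go e.g. 1054→544. The
average-ΔMSE benefit should therefore only be expected at the full
generative size; the desk-scale benchmark demonstrates the direction as a
majority property.

The two MSE anchor settings are run at full N and m with few
replications (8 easy / 12–16 hard). The hard anchor's per-replication MSE
is heavy-tailed — 1/sd(Y) is sometimes ~1.3 and sometimes ~4 — so its
mean converges slowly; the replication counts were chosen from a
pre-registered tail analysis of the scale-factor distribution, not from
observed pass/fail outcomes.

Numerical choices collected: variance uses N−1 everywhere; GWAS p-values
use the exact t mapping while the winner's-curse z-conversion uses the
standard normal (both exposed); PLS stops early with a warning if the
cross-covariance is exhausted; λ and nodewise-penalty ties prefer
sparsity; degenerate inputs (constant columns, covariate-explained
columns, exposures without instruments, M ≤ K for Sargan) raise or drop
with explicit messages. The jackknife refits at fixed r rather than
re-selecting r per fold (r-selection noise would otherwise dominate the
coefficient variance).

Open design points resolved here: whether outcomes are covariate-adjusted
like the exposures is caller-selectable (`adjust_outcome`); Sargan uses
all K second-stage exposures in its df; the nodewise penalty is the
CV-minimum (not a one-standard-error rule); the elastic-net mixing grid
is 0.1…0.9.
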