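# Methods

This note documents the statistical models, defaults and numerical choices
behind `lungmeth`, and what the synthetic-data conditions do and do not show
about real methylation studies.

## Scales and data model

Methylation enters as beta values β = methylated/(methylated+unmethylated) in
the open interval (0,1) and is analysed on the M-value scale
M = log₂(β/(1−β)), which stabilises variance near the boundaries. Exact 0/1
values (possible in toy inputs) are clamped to [10⁻⁶, 1−10⁻⁶] with a logged
warning; strict mode raises instead. Missing entries propagate through the
transform and are handled per CpG by complete-case analysis downstream. QC
drops CpGs above a missingness ceiling (default 10%) or below a variance
floor (sd < 10⁻⁶); the filter is idempotent and order-preserving.

Annotation positions are 1-based inclusive in TSV; BED exports are 0-based
half-open.

## Robust per-CpG regression

Each scan fits, per CpG, `outcome ~ intercept + covariates + M` by
M-estimation: iteratively reweighted least squares with the Tukey bisquare ψ
at tuning constant c = 4.685 (≈95% efficiency under Gaussian errors),
residual scale fixed at 1.4826 × MAD of the initial least-squares residuals,
at most 50 iterations, convergence when the largest coefficient change falls
below 10⁻⁸. Non-convergence is flagged on the record, never silent. The
estimator reduces exactly to least squares when all robust weights are one
(e.g. noiseless data). CpGs with fewer than `n_covariates + 10` complete
cases are skipped and counted.

**Standard errors and p-values.** Coefficient covariance is the Huber
sandwich A⁻¹BA⁻¹ with bread A = Σψ′(r/s)xxᵀ/s and meat
B = Σψ(r/s)²xxᵀ/(1−h)², where h are the weighted leverages (an HC3-style
correction), times a small-sample factor n/(n−p). P-values are two-sided
from a t reference with per-coefficient Satterthwaite effective degrees of
freedom computed from the sandwich weights (df_j = (Σa)²/Σa² with
a_i = [(A⁻¹x_i)_j]²). Rationale: genome-like M-value predictors are skewed,
the sandwich variance estimate is then noisy (few effective df), and a plain
normal reference inflates the extreme tail several-fold at p ≈ 10⁻⁵ — the
regime Benjamini–Hochberg probes in a 5,000-CpG scan. The t reference nests
the normal approximation: for well-behaved designs the effective df
approaches n and the two coincide. We verified calibration directly: under
the global null, empirical FDR of the BH 0.05 threshold over 200 scans of
5,000 CpGs stays within two Monte-Carlo standard errors of 0.05.

The whole scan is vectorised: the covariate block of the design is shared
across CpGs and only the CpG column differs, so IRLS runs as batched matrix
algebra with an active set (converged CpGs drop out of later iterations).
A cross-check test compares single fits against statsmodels' RLM with the
same ψ and fixed MAD scale (coefficients agree to ~10⁻⁷).

Sex-chromosome CpGs are analysed only within sex strata when an annotation
is provided; autosomes appear in all strata. FDR is Benjamini–Hochberg,
computed within one outcome × stratum × cohort scan.

## Meta-analysis and retention

Fixed-effects inverse-variance pooling: w_k = 1/SE_k², pooled effect
Σw_k b_k/Σw_k, SE 1/√Σw_k, two-sided normal p on the pooled z. A CpG enters
the meta-analysis when its per-cohort p < 0.05 (the discovery threshold) in
at least one cohort; a designated-discovery-cohort mode restricts the entry
criterion to named cohorts. Pooling always uses every cohort in which the
CpG was measured. Direction strings follow the METAL convention over the
declared cohort order: `+`, `-`, `0` (exactly zero effect — treated as
disagreement and logged), `?` (not measured). Cochran's Q is emitted for
information only and never filters.

Two retention tiers at FDR < 0.05: **all_studies** (no missing symbol, all
signs agree) and **two_of_three** (at least two agreeing non-missing signs;
a disagreeing or missing remainder is tolerated). The first tier is a subset
of the second by construction. The tolerance of a disagreeing third sign in
the weaker tier is a deliberate reading of "consistent in at least two of
the three studies".

Candidate regions use a distance rule, not a kernel smoother: per
chromosome, position-sorted retained CpGs are merged while consecutive gaps
stay ≤ 1,000 bp, and merged runs with ≥ 4 CpGs are reported. The 1 kb
default mirrors common DMR bandwidths.

## Sex-divergent DMPs

From the male and female stratified meta-analyses, a CpG is divergent when
the pooled effects have opposite (nonzero) signs, FDR < 0.05 in at least one
sex, and at least two studies agree with the pooled sign within each sex
separately. Pooled effects exactly zero are excluded and logged. No formal
sex × CpG interaction test is used for this filter (an interaction scan
exists in the PRS module but plays no role here).

## PRS robustness

The PRS-adjusted scan appends a standardised (mean 0, SD 1) score to the
covariates; samples without a score are dropped and the reduced n is carried
on each record. "Coefficient remained unchanged" is quantified as relative
change |Δb|/|b| ≤ 10% **and** FDR < 0.05 in the adjusted scan — the 10% is a
package default, declared as an assumption, configurable. Base effects below
10⁻⁶ in magnitude switch to an absolute-change criterion scaled by the
scan-median |effect|. The interaction model is
`outcome ~ covariates + PRS + M + M×PRS`, reporting the product term.

## Stratified Gaussian graphical models

Input nodes (by default the sex-divergent CpG set; any list is accepted) are
residualised against covariates per CpG, then a graphical lasso is fit per
sex stratum on the correlation matrix along 10 log-spaced penalties from
λ_max (the largest absolute off-diagonal correlation) down to 0.25 λ_max.
The path floor keeps the selected model inside the sparsistent regime for
the planted structures the package simulates.

**Selection.** Default is EBIC with γ = 0.5: consistent for sparse graphs,
near-empty on independent noise (0 edges in 20/20 null runs at n = 2000,
p = 20), chain edge-recovery F1 0.86–1.0 at partial correlation 0.4. StARS
is available (20 subsamples of ⌊0.8 n⌋, instability threshold 0.1, seeded
subsampling) but is not the default: at an 0.8 subsample ratio the
subsampled fits are highly concordant, so small spurious edge sets keep the
total instability below the 0.1 threshold and the selected null graph
carries several edges. A fixed-λ mode supports exact-inference checks
(λ→0, n≫p reproduces the inverted empirical covariance within 0.02).

Edges are nonzero off-diagonals of the selected precision matrix Θ, reported
as partial correlations ρ_ij = −Θ_ij/√(Θ_ii Θ_jj). Hub scores are the
principal eigenvector of the |partial correlation| weight matrix, taken
elementwise absolute and scaled so the maximum is 1 (for a symmetric matrix
HITS hub/authority and eigenvector centrality coincide). Disconnected
components are normalised globally; isolated nodes score 0; an edgeless
network scores all zeros. Differential hubs are nodes with
|hub_f − hub_m| > 0.20.

## Epigenetic age

Clocks are linear on beta values only: age = intercept + Σcoef_i β_i, with
coefficients supplied by the user (no published clock is bundled, and
transformed-age clocks are out of scope). Missing clock CpGs are imputed at
the cohort mean beta (or raise under strict policy); coverage below 50%
always raises. Age acceleration is the residual of predicted on
chronological age — uncorrelated with chronological age by construction;
constant chronological age falls back to centring. The association model
`outcome ~ acceleration + covariates` is ordinary least squares. In
simulation mode the pipeline constructs a synthetic clock from the cohort's
own data purely so the stage runs end to end; it has no biological meaning.

## The synthetic-data generator

The generator emulates the three-cohort early-life design: two childhood
cohorts and one cord-blood birth cohort with default sizes 788/703/572.
Per-CpG beta values follow Beta(μκ, (1−μ)κ) with concentration κ = 50 and a
bimodal mean mixture (40% in 0.05–0.15, 40% in 0.85–0.95, 20% in 0.30–0.70),
mimicking the genome-wide bimodality of array data. Covariates: sex (42%
female), age ~ N(10.5, 2) years (birth cohort: gestational age ~ N(39.2,
1.5) weeks and age 0), height linear in age plus noise, smoke exposure
Bernoulli(0.3) (birth: 0.05), and six cell-type proportions from a
blood-like Dirichlet. Outcomes are linear: baseline + per-outcome-scaled
covariate signal + Σ effect_c × centred M_c + Gaussian noise, with planted
effects drawn N(effect_mean, effect_sd) on the M scale (default mean 0.5)
and the birth cohort attenuated ×0.5 to emulate weaker cord-blood signal.
Sex-divergent CpGs flip sign exactly between sexes (female +e, male −e), so
their pooled combined-sex effect is 0 by design.

Multi-cohort generation shares a configurable fraction of causal CpGs across
cohorts with a common sign (magnitudes redrawn per cohort); the rest are
cohort-private and disjoint. Part of the shared causal budget (30%, at least
one run when the budget allows) is planted as contiguous runs of 4–6 CpGs
inside annotation spacing clusters — the annotation places CpGs in clusters
of 8 consecutive ids spaced 50–300 bp within and 2–20 kb between — giving
the ≥4-CpG region rule a recoverable truth. Divergent CpGs are drawn from
the scattered (non-run) shared causal set so planted regions keep a coherent
direction. Network data are exact zero-mean Gaussians from unit-diagonal
precision matrices (chain, star, or random-sparse structures; positive
definiteness is checked, which bounds star strength by 1/√(p−1)). PRS scores
are built as ρ·z(outcome) + √(1−ρ²)·noise and re-standardised.

Every generator is a pure function of its configuration and seed;
regeneration is bit-identical.

**What the simulations do not capture:** probe-level measurement error and
batch structure, correlation between neighbouring CpGs (region members are
causally coherent but statistically independent), methylation–covariate
dependence (so covariate adjustment is exercised but confounding is not),
population stratification, and real LD between PRS and methylation. Passing
recovery tests therefore demonstrates correctness of the inference chain
under its stated model, not robustness to those real-data pathologies.

## Problem sizes and benchmarks

Simulated scans use thousands of CpGs (2,000–5,000) rather than the ~450k of
a real array — the per-CpG model is identical and independent across CpGs,
so this scales the multiple-testing burden, not the per-test behaviour. The
benchmark suite (`lungmeth.evaluation`, driven by `scripts/acceptance.py`
and the acceptance tests) fixes: pooling vs the hand formula on 1,000 random
problems; the null three-study consistency rate over 3×10⁶ triples against
2×0.025³; empirical FDR over 200 null scans of 5,000 CpGs at n = 300;
robust-vs-OLS win rate over 200 replicates at n = 500 with 10% contamination
at 20–50σ; pooled-effect bias and all-studies sensitivity (vs a closed-form
OLS oracle pushed through the same meta logic) averaged over six independent
three-cohort draws at study sizes; chain-GGM F1 and null sparsity; planted
differential-hub recovery over 50 replicates; sex-divergence recovery at
n = 2000/stratum; and byte-identical re-runs of the full pipeline. Single
study draws share one outcome realisation across all causal CpGs, which
correlates their estimation errors — hence the bias benchmark averages
several draws.

## Known limitations

* The robust scan assumes outcome-on-methylation linearity and covariate
  additivity; no mixed models, surrogate variables or genomic control.
* Fixed-effects pooling only; Cochran's Q is descriptive. Heterogeneous
  true effects across cohorts will be averaged, not modelled.
* The region rule is a distance merge, intentionally simpler than
  kernel-based DMR callers; region p-values are not computed.
* The "coefficient unchanged" tolerance (10%) and the hub-difference
  threshold semantics (eigenvector centrality scaled to max 1) are package
  conventions where the field reports no formula.
* Networks are estimated on FDR-selected nodes; post-selection uncertainty
  in the graph is not propagated.
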