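# Methods

## Scope and model

`tnftime` analyzes a two-condition (control / TNF-treated) bulk RNA-seq
time course with matched samples at every time point for every replicate
pool, stratified by sex. Counts are modeled as negative binomial,
`Var = μ + α·μ²`, with a per-sample size factor entering the mean as a
log offset. The analysis grid is the 11 comparison time points
0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72 h.

## Normalization

Size factors use the median-of-ratios estimator: reference genes are rows
with no zero count; each gene's geometric mean across samples defines the
per-sample ratios, and the sample's factor is the median ratio. Factors
are defined only up to a common constant; no rescaling is applied. If no
all-positive gene exists, an explicit `pseudo_reference=True` flag
switches to geometric means over positive entries only. TPM divides
counts by gene length in kilobases and rescales each sample to 10⁶; when
genes have been filtered, TPM is renormalized over the retained set (this
is deliberate and documented rather than hidden). Annotated gene length
is taken as input; whether it is effective or annotated transcript length
is the caller's choice and does not affect any within-gene comparison.

QC uses classical (Torgerson) multidimensional scaling: squared Euclidean
inter-sample distances are double-centered and eigendecomposed;
coordinates are eigenvectors scaled by the square roots of their
eigenvalues. Negative eigenvalues beyond `1e-8` of the spectral radius
trigger a non-Euclidean-input warning.

## Dispersion estimation

Per-gene dispersions come from a method-of-moments estimator pooled over
condition × time cells with ≥ 2 replicates:

    α̂ = Σ_cells (s² − μ̂·c₁) / Σ_cells (μ̂² − s²/n)

computed on size-factor-normalized counts, where `c₁` is the cell mean of
1/size-factor (the Poisson component of a normalized count's variance is
μ/sf, not μ) and the `s²/n` term removes the upward bias of the squared
sample mean. With 3 replicates per cell the raw gene-wise estimate is
noisy (≈ 44 residual df over the 22 cells of one sex), and plugging noisy
dispersions into a likelihood-ratio test is anti-conservative — measured
type-I error ≈ 0.10–0.13 at nominal 0.05 on all-null simulations, while
oracle dispersions give 0.054. Estimates are therefore moderated toward
the across-gene median with weight `prior_df / (prior_df + resid_df)`;
the prior weight defaults to 40 df, chosen by null-simulation calibration
before the acceptance checks were frozen. `moderation_prior_df=0`
recovers raw gene-wise values.

## Likelihood-ratio test

For each gene, full (`~ treatment + time + treatment:time`) and reduced
(`~ treatment + time`) NB GLMs with log link and log size-factor offset
are fitted by IRLS (statsmodels `GLM`; dispersions below 1e-8 use the
Poisson family). Time is a factor, so the interaction has T − 1 = 10 df.
The statistic 2(ℓ_full − ℓ_reduced) is referenced to
`F(df, resid_df + prior_df)` via `stat/df` rather than to χ²(df): the F
reference absorbs the dispersion estimator's finite degrees of freedom in
the spirit of quasi-likelihood F-tests and restores nominal type-I error
(0.04–0.065 across null simulations, with uniform p-values). A
chi-square path remains available (`denom_df=None`). Genes whose IRLS
fails to converge are flagged, get `p = NA`, and are excluded downstream
with a log message. Genes with total counts < 10 across all samples are
excluded before fitting.

Per-time-point fold changes are `log2((treated mean + 0.5) / (control
mean + 0.5))` over pool means of normalized counts; the 0.5 pseudocount
guards zeros. DEG calls combine the single time-series adjusted p-value
(BH step-up, < 0.05) with the per-time fold-change gate (|log₂FC| > 1);
the paper-level tool reports only a single test per gene, so the per-time
significance gate is deliberately the time-series padj, an interpretation
documented here and isolated in `call_degs`.

Sexes are analyzed separately throughout the DE and classification stages
and merged afterwards, excluding baseline sex differences from the
treatment contrast.

## Regulation classification

Labels are assigned by a fixed precedence so that every gene receives
exactly one label:

1. `excluded_low_expression` — max condition × time mean TPM < 1
   (strictly; a max of exactly 1.0 is retained).
2. `not_regulated` — no DEG flag at any time point.
3. `excluded_inconsistent_direction` — both up and down flags occur.
4. `excluded_not_sequential` — no ≥ 2 consecutive same-sign DEG flags.
5. `excluded_control_variable` — the CV pattern fails: requires control
   CV < 0.3 **and** treated CV > 0.3 (strict inequalities; an undefined
   CV from a non-positive mean fails). Both the drifting-control and the
   stable-treated failure collapse into this one label, with both CVs
   recorded as evidence — the delay-versus-inhibition subtypes of a
   drifting control are not algorithmically separable from profile data.
6. `excluded_low_peak_fc` — for up-candidates, max over time of
   log2(treated_t / treated_0.5h) ≤ 0.7; for down-candidates, max
   |log₂FC| versus time-matched control ≤ 0.7. The asymmetry (treated
   baseline for up, control for down) is deliberate and kept.
7. `upregulated` / `downregulated` otherwise, by DEG sign.

CVs use the sample (n−1) standard deviation over per-time-point means,
computed mean-then-CV (pools are averaged within each time point first).
Merging sexes is set algebra on the two label vectors
(both / female_only / male_only / neither) with an explicit conflict flag
for opposite-direction calls.

## Coexpression network

Genes enter the network when total counts ≥ 10 and the CV of normalized
counts across all samples exceeds 0.2 (the filter removes low-variation
genes; correlations are computed on log₂(normalized + 1)). Adjacency is
signed hybrid, `a = max(cor, 0)^β`. Soft-threshold selection computes,
per candidate β, the connectivity distribution's scale-free fit: k is
binned into 10 equal-width bins, log₁₀ frequency is regressed on log₁₀
mean-k per bin, and the fit index is R² signed negatively when the slope
is positive; the smallest β with fit ≥ 0.8 wins, falling back to 12 with
a warning. The TOM is

    TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with connectivity excluding the diagonal and TOM_ii = 1; the unsigned
formula is applied to the already non-negative signed-hybrid adjacency.
Modules come from average-linkage (UPGMA) clustering of 1 − TOM followed
by the tree variant of dynamic cut: a static cut at absolute height 0.99
(TOM dissimilarity of unrelated genes concentrates near 1, so a fixed
height, not a quantile of merge heights, separates real branches from
noise) and a minimum branch size of 30; modules are labeled 1..M by
decreasing size, unassigned genes 0. Eigengenes are the first right
singular vector of the z-scored module expression (unit norm,
sign-oriented to correlate positively with members on average), with the
fraction of variance explained reported. kME is the Pearson correlation
of each gene with each eigengene, p-values from the t statistic with
n − 2 df; the "featured" flag requires kME > 0.80 and p < 0.05 against
the gene's own module. Hubs maximize intramodular connectivity, ties
broken to the lexicographically first gene id. Module merging by
eigengene correlation and block-wise decomposition are out of scope; the
implementation targets single-block problems of desk scale (≤ a few
thousand genes).

## Enrichment

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for a query of n genes against a set with K members inside the
N-gene universe, BH-adjusted across terms. The universe is the analyzed
background (genes surviving the expression filter), not the genome. Gene
sets come from GMT files; sets with fewer than 5 universe members are
skipped by default. Only over-representation is tested.

## Sex comparisons

Baseline sex DE fits, per time point, a control-samples-only NB GLM on a
sex factor (dispersions pooled over sex × time cells; the same F
reference as above) and BH-adjusts within the time point; a gene is
baseline sex-DE when |log₂FC| > 1 and padj < 0.05 at **every** time
point. The concordance check computes pool-matched treated/control log₂
ratios (pseudocount 0.5) and flags a gene as sex-specific when some pool
of one sex exceeds |log₂FC| > 1 while every sample of the other sex stays
below 0.1375 (fold change 1.1); the check is exactly symmetric under
swapping sex labels. The per-sample ratio is pool-level by design — the
replicate structure of "samples" is otherwise underdetermined.

## Synthetic data generator

The generator emulates the study design: 2 conditions × 11 time points ×
3 pools per sex, matched control/treated samples per pool and time.
Temporal archetypes are piecewise-logistic — an onset sigmoid (midpoint
between onset and peak, width (peak − onset)/8) times an optional
resolution sigmoid — normalized so the treated-minus-control difference
equals `peak_log2fc` exactly at `peak_h`. Defaults: early-transient
(onset 1 h, peak 6 h, resolved by 48 h), early-sustained (1 h/8 h,
sustained), delayed (onset 12 h, peak 24 h, held through 72 h),
down-sustained (2 h/12 h), down-resolving (2 h/8 h/48 h), a
control-drift archetype in which both conditions drift identically, and a
delayed-drift confounder in which treatment lags the control's drift by
24 h — the class a regulation classifier must exclude as control-driven.
Baseline log₂ TPM is uniform in [3, 7]; library sizes are log-uniform in
[3×10⁵, 10⁶] to exercise size-factor estimation (depths are otherwise
unreported for the emulated design); gene lengths log-uniform in
[500, 5000] bp; dispersion defaults to 0.05 with log-normal jitter
(σ = 0.3), typical of pooled bulk RNA-seq. Expected counts are
library-size × the length-weighted relative abundance implied by the
log₂ TPM curves; counts are NB draws with the per-gene dispersion.

Coexpression blocks are carved out of null genes and share a per-sample
latent factor added on the log₂ scale; the loading is derived from the
target within-block correlation (default 0.7) against the NB noise floor
√α/ln 2, so realized pairwise correlations attenuate to ≈ 0.55–0.6. An
optional knob plants a constant between-sex baseline shift on a chosen
number of genes; by default the sexes are generated statistically
identical. Pools are independent NB replicates — within-pool donor
variance of a pooled design is not recoverable and is not modeled. The
generator does not emulate read-level artifacts, UMIs, batch effects
beyond pool identity, library-composition biases beyond the planted
responses, or count outliers; passing tests therefore demonstrate
correctness of the statistical machinery under the NB model, not
robustness to artifacts real data may carry.

## Benchmark problem sizes

The recovery benchmark uses 2000 genes (10% early-induced split between
transient and sustained, 10% delayed, 5% + 5% down-regulated, 10%
delayed-drift confounders, 60% null) at peak |log₂FC| = 2 and dispersion
0.05 — large enough for stable rates while keeping a full two-sex
pipeline run in tens of seconds. Calibration uses 1000 all-null genes in
one sex; module recovery uses 600 genes with planted blocks of
150/120/80/10 at β = 6; the sex-concordance property uses 20 independent
300-gene datasets. All randomness flows from a single seed via
`numpy.random.default_rng`.

## Known limitations

- Dispersion moderation shrinks toward a single central value, not a
  mean-dependent trend; strongly mean-dependent dispersion would be
  mis-moderated (the trend hook exists but is off).
- The LRT's F reference treats the dispersion df as
  `resid_df + prior_df`, an approximation validated by simulation rather
  than derived exactly.
- Wald tests per coefficient, LFC shrinkage, outlier replacement and
  independent filtering are deliberately out of scope.
- The tree-cut variant is the static-height tree method; the hybrid
  PAM-assisted variant is not implemented (the interface leaves room).
- Classification thresholds are strict inequalities at every boundary;
  values exactly at a threshold fail the criterion.
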