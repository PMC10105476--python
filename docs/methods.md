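# Methods

## Scope and data model

`epireg` analyzes feature × sample numeric matrices: mRNA log-expression
(log2(x+1) of a normalized unit), miRNA log-expression, and methylation
beta values in (0,1). All exchange formats are plain text (TSV, GMT,
JSON). The package performs no downloads and no platform-specific
normalization; preprocessing is limited to a missingness filter (features
with a missing fraction strictly above 20% dropped), feature-median
imputation of the remaining gaps, and the log2(x+1) transform. The
conversion between expression units (e.g. FPKM to TPM) is out of scope
because it needs gene lengths; the transform contract applies to whatever
normalized unit is supplied.

## Regulatory screen

For a candidate pair (regulator, gene), the Pearson correlation r is
computed on pairwise-complete samples (n_eff recorded). The test
statistic is the variance-stabilized Fisher transform, z = atanh(r), with
standardized score z·√(n_eff−3), approximately N(0,1) under r = 0. A pair
is significant-negative when z·√(n_eff−3) < z_crit (default −1.96,
strict) and r < 0. This is the unique reading of a "−1.96 on the Fisher-Z
scale" criterion that yields a valid one-sided α ≈ 0.025 test for
negative correlation; the threshold and the negative-only gate are
configurable (a two-sided option exists for the methylation screen).

Guard rails: pairs with n_eff < 30 (configurable), zero variance on
either side, or |r| = 1 (atanh diverges) are flagged invalid and can
never be significant. Gene-level aggregation is "any significant pair",
with the minimum-z_std pair reported as the gene's representative — the
least-assumption rule, monotone under adding pairs.

CpG–gene pairing follows the annotation table verbatim (probe → gene,
island relation, genomic position class); no distance-based promoter
calling is attempted. miRNA–gene candidates are the strict three-way
intersection of the supplied target lists, restricted to measured
features. Region frequencies compare the island-relation and
position-class composition of significant probes against all probes.

## Aberrance profiles

Per gene, the lower/upper quantiles (default quartiles,
linear-interpolation convention) are computed **across samples**; a gene
is aberrantly high in a sample when strictly above Q3, low when strictly
below Q1. Per-sample frequencies are counts over the measured genes of
the set. Thresholding per gene (rather than ranking within each sample)
is deliberate: within-sample ranking would force identical 25%/25%
fractions in every sample and make the cross-sample co-regulation
correlation degenerate; the per-gene reading is the only one under which
that statistic is informative. Profiles are invariant to monotone
per-gene transforms; constant genes contribute to neither tail.

## Integrative clustering

The regulated expression blocks are per-feature standardized (constant
features dropped), stacked, and modeled as a Gaussian latent factor
model x_j = W z_j + e_j with z_j ~ N(0, I_q), per-feature noise
variances, and q = k−1 factors for k clusters (so the "4 clusters"
model has 3 latent dimensions). Fitting is MAP-EM with a per-feature
noise-scaled Gaussian prior on the loadings (ridge strength 1e-3): the
M-step solves w_i = a_i (G + λI)⁻¹ per feature and the tracked
log-posterior objective is monotone non-decreasing every iteration —
asserted in tests. Initialization is the SVD of the stacked data, so a
fit is fully deterministic; the only seeded randomness is the k-means
restart schedule (50 restarts) applied to the posterior factor scores
E[Z|X]. Factor signs are canonicalized (largest-|loading| component
positive) so that labels are invariant to sample-column permutation.
Cluster labels are relabeled deterministically by descending cluster
size, ties by ascending mean of the first factor.

This deterministic EM formulation deliberately replaces Bayesian
integrative clustering by MCMC (iClusterBayes-style spike-and-slab
sampling): the scientific contract — a joint latent space over omics
blocks with the cluster number chosen by BIC — is preserved, while fits
become reproducible and desk-scale. Posterior feature-relevance
probabilities are therefore not produced.

Model selection: BIC = −2·loglik + p_eff·ln(n·p_total) with p_eff =
p_total·q + p_total (loadings + noise variances); the effective sample
size n·p_total (total observations) is the default, with n-only exposed
in config. A deviance ratio 1 − RSS(model)/RSS(null) is reported per k as
a secondary diagnostic. The argmin-BIC model is returned with the full
traces.

## Signatures, NTP, concordance

Signatures are one-vs-rest Welch t-tests per gene on log-scale
expression with BH adjustment within each contrast. A gene qualifies
for a subtype when FDR < 0.05 and log2FC > 0; a gene qualifying in
several subtypes is assigned only where its log2FC is maximal, so
templates are mutually disjoint. Lists are ordered by descending log2FC
and truncated to the top 500. Welch t + BH stands in for moderated-t
ranking; with ≥ tens of samples per cluster the moderation effect on a
log2FC-ordered top-500 list is minor. The FDR gate is configurable
(fdr_max = 1 disables it).

Nearest template prediction standardizes expression per gene, represents
each subtype as the indicator vector of its measured markers, and assigns
each sample to the template with minimal cosine distance (ties → smallest
subtype index). Significance is by gene resampling: n_perm size-matched
random gene subsets drawn from all measured genes; p = (1 + #{d_random ≤
d_observed})/(n_perm+1), BH across samples. Because p is computed for the
*predicted* (argmin) template, multi-template p-values are
anti-conservative by at most a factor k; with a single template they are
uniform under the null, which is how calibration is tested.

Cross-cohort concordance is a one-directional subclass-mapping screen:
entry (i, j) measures enrichment of cohort A's subtype-i signature at the
top of cohort B's subtype-j-vs-rest t ranking using a weighted
Kolmogorov–Smirnov running sum (weights |t|), with p-values from n_perm
permutations of B's labels and BH over the full k_A × k_B matrix. The
decision rule "matched iff raw and adjusted p < 0.05" is preserved. The
full bidirectional Fisher-combined subclass mapping is intentionally not
reimplemented; the screen is used only as a concordance check.

## ssGSEA

Per sample, genes are ranked by expression (average ranks on ties) and
the list walked from most to least expressed. The in-set cumulative uses
weights rank^α normalized by the in-set weight total; the out-of-set
cumulative is uniform; the enrichment score is the **sum** of their
differences over all positions (not the maximum). α defaults to 0.25
with optional global (max−min) normalization of the whole score matrix,
both configurable; α = 0 reduces to the classic unweighted KS running
sum. Scores are rank-based, hence invariant to monotone per-sample
transforms. Sets with fewer than two measured genes (or covering every
measured gene) are skipped with a warning. Tests pin the implementation
to an independent brute-force walk to 1e-12 on all toys ≤ 20 genes.
Immune/stromal scores are simply ssGSEA scores of user-supplied gene
sets; purity transforms and external deconvolution methods are consumed
as score tables, not reimplemented.

## Drug screen

AUC matrices (cell line or sample × drug; lower = more sensitive) are
filtered (drugs with missingness strictly above 20% removed) and imputed
by k-nearest-neighbor cell lines: distances are Euclidean over per-drug
z-scored, mutually observed drugs; each gap takes the unweighted mean of
the drug's value in the k = 5 nearest lines that observed it (next
nearest used when a neighbor lacks the drug; column mean as last resort).
Observed entries are never altered and the operation is idempotent.

Tumor sensitivity is predicted per drug by ridge regression on cell-line
expression over the shared genes, each matrix z-scored per gene within
its own dataset (a minimal cross-platform homogenization; empirical-Bayes
batch correction is deliberately not applied). The penalty is chosen per
drug by 10-fold cross-validated MSE over a grid, since drugs differ in
signal strength.

A drug is subtype-specific for s iff log2(m_t/m_s) > 0.05 for every
other subtype t, with m_s the mean predicted AUC in s — the
generalization of the reference rule stated for one subtype to all
subtypes; by construction at most one subtype can win per drug. The rule
is applied to per-sample predicted AUCs (the only reading consistent
with per-sample prediction).

## Survival and association statistics

Kaplan–Meier product-limit curves per group with the k-group log-rank
test (lifelines); groups with zero events are kept in curves but warned
about for the test. Categorical associations use chi-square, or Fisher's
exact for 2×2 tables with any expected cell ≤ 5. Subtype score
comparisons use Kruskal–Wallis with BH over gene sets.

## Synthetic cohorts: what they emulate, and what not

`SimConfig` defaults encode the standard study conditions used by the
test-suite: n = 200 samples; 2000 genes; 300 planted CpG–gene and 300
miRNA–gene pairs at target r = −0.5 among independent null pairs; four
subtypes with prevalences (0.30, 0.23, 0.15, 0.32) — the cluster-size
imbalance typical of real cohorts — each shifting 150 genes by 1.5
within-gene SD; exponential survival with hazards (0.05, 0.08, 0.10,
0.15) per month and exponential censoring at rate 0.05; a 50-drug panel
with 3 planted drugs per subtype at a 0.2 log2 AUC effect, 5% log2
replicate noise and 10% missingness; three target lists of all true
pairs plus 200 per-list decoys (three-way decoy overlap 0 by default, so
intersection logic can be tested separately from correlation logic).

Construction details that matter:

- Methylation is simulated on the logit scale and squashed by the
  inverse logit, keeping betas in (0,1). Regulation acts on the logit
  scale, where the planted correlation is exact; on the beta scale the
  mild sigmoid nonlinearity attenuates |r| by ~1%.
- The regulator of a planted pair is generated from the
  population-standardized gene value, whose moments include the
  subtype-shift mixture; the pooled correlation therefore equals
  target_r exactly even though planted genes are also differentially
  expressed. At n = 200 the empirical mean r shows small-sample
  attenuation of ~0.02.
- DE genes are drawn from the regulated gene pools (half METcor, half
  MIRcor per subtype) so the screened blocks carry the subtype signal
  the clustering stage consumes.
- A shared per-sample dysregulation factor (log-normal, variance
  normalized so E[f²] = 1) inflates the noise of regulated genes in both
  blocks, producing co-regulated aberrance burdens at r ≈ 0.6 — the
  scale reported for real tumor cohorts — without touching the pair
  correlation calibration (default coupling 0.12; 0 disables it).
- The drug panel is indexed by the cohort samples so the specificity
  rule can be exercised directly; a separate subtype-shifted expression
  matrix for the profiled lines supports the ridge-transfer path.
- One integer seed; all stage generators derive child seeds
  deterministically, so outputs are bit-identical under a fixed seed.

Not emulated: realistic 450K probe densities and probe-level artifacts,
copy-number/mutation structure, batch effects between cohorts, non-
exponential hazards, and dose–response curve fitting (AUCs are inputs).
Passing tests therefore demonstrate correctness of the statistical
machinery under a faithful but idealized generative model, not
robustness to platform noise.

## Problem sizes and numerical choices

The test-suite and the acceptance script run at the sizes above; the
multi-seed checks use 20 seeds in the test-suite and 5 in the acceptance
script (the script favors a broad sweep of every stage in one run).
Numerical guards: EM noise variances floored at 1e-8; relative
log-posterior tolerance 1e-6 with a 200-iteration cap (non-convergence
returns the best iterate, flagged); quantile convention "linear"
throughout; strict inequalities at every stated boundary (20%
missingness, −1.96, 0.05 log2 ratio, Q1/Q3); ties broken toward the
smallest subtype index everywhere.
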