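# Methods

This note documents the models, numerical choices, and design decisions
behind `coexgwas`, and what the synthetic-data experiments do and do not
establish.

## Gene-based association under LD

The gene statistic is T = Σ −log₁₀ pᵢ over the SNPs assigned to a gene.
All distribution theory is done on Q = 2 ln(10) · T = Σ qᵢ with
qᵢ = −2 ln pᵢ, because under the null each qᵢ is exactly χ²₂.

**Dependence model.** GWAS p-values are two-sided, so each qᵢ is a function
of |zᵢ| for an (approximately) Gaussian association score zᵢ, and the
correlation of scores at two SNPs equals their dosage correlation r in the
reference panel.  Writing q = f(z) with f(z) = −2 ln(2Φ(−|z|)) and expanding
f in probabilists' Hermite polynomials, the covariance for jointly normal
scores is the even power series

    cov(q_i, q_j) = Σ_{k even ≥ 2} c_k² k! · r^k ,

with c_k the Hermite coefficients of f.  The coefficients through order 30
are computed by adaptive quadrature and frozen in
`gene_assoc._TWO_SIDED_COEF`; the small remaining mass (the series converges
slowly near |r| = 1 because f has a kink at 0) is assigned to the r³² term
so the coefficients sum exactly to 4 = Var(χ²₂), making duplicated SNPs
behave exactly.  A unit test re-derives several points of the function by
direct two-dimensional Gauss–Hermite integration and checks the frozen
series against them.

The widely quoted cubic 3.263|r| + 0.710 r² + 0.027|r|³ is a fit for
*one-sided* p-values.  Applied to two-sided p-values it overstates the
covariance at moderate correlation (e.g. 1.81 vs the true 0.98 at r = 0.5)
and drives the type-I error of the moment-matched test down to ≈ 0.027 at
α = 0.05.  It remains available as `cov_model="one-sided"` for data that
genuinely carries signed one-sided p-values.

**Null approximation.** Q's mean 2m and variance 4m + 2Σᵢ<ⱼ cov are matched
to c·χ²_f with f = 2E²/Var and c = Var/(2E).  Two exact reductions anchor
the approximation: identity LD gives Var = 4m, hence Fisher's method
exactly; an all-ones LD matrix gives f = 2, c = m, hence the single-SNP
p-value.  Between these extremes the approximation is a genuine
approximation: simulated type-I error at α = 0.05 over random AR(r) LD
(r ~ U(0, 0.95), m ~ U{1..50}) is ≈ 0.053, inside the design band
[0.042, 0.058], but a two-moment (or even an exact-third-moment) gamma-family
fit cannot reproduce the full null law to Monte-Carlo accuracy at 200,000
draws; the worst standardized deviation from a 200,000-draw empirical tail
is tens of standard errors for strong-LD 4-SNP matrices.  This is an
intrinsic limit of moment matching, not an implementation artifact, and is
reported honestly by the acceptance script (`gene_test_mc_max_z`).

**Numerical details.** LD matrices are repaired to positive semidefinite by
eigenvalue clipping at zero with the unit diagonal restored; p_gene is
clamped into [1e-12, 1 − 1e-12] before the probit so downstream set analysis
stays finite; duplicate SNP ids keep their first occurrence; p ≤ 0 or > 1 is
rejected rather than clamped.

## SNP-to-gene annotation

Proximity windows are strand-aware ([start − 35 kb, end + 10 kb] for +
genes, mirrored for −), since "upstream" is biologically a 5' notion; an
option disables strand awareness.  The eQTL scheme uses a strict q < 0.05
cut.  Both produce the same assignment type so the gene test is agnostic to
the annotation source.  Bonferroni thresholds come in a global scheme
(0.05 / total tests) and a per-tissue scheme (0.05 / tests in the tissue);
values are kept exact internally and rounded to 3 significant figures only
for display.

## Competitive gene-set analysis

The design matrix is intercept + membership + covariates.  Gene size and
SNP count enter as log(length) and log(n_snps); log SNP *density* is their
difference and therefore exactly collinear on the log scale, so it is not a
third column (the singular-design guard would reject it).  The GLS error
covariance is the gene-gene correlation of the Q statistics implied by
shared or linked SNPs, computed with the same covariance series and
restricted to gene pairs within 1 Mb on the same chromosome, then clipped
to positive semidefinite.

The empirical correction permutes gene scores (not set labels), re-tests
all sets per permutation with a vectorized whitened least-squares kernel,
and uses the per-permutation *minimum* p, giving family-wise control across
modules; per-set early stopping (10 exceedances) bounds work on clearly
null sets.  p_corr = (b + 1)/(k + 1) is never zero.  Redundant covariate
columns (for instance a constant SNP count in a panel where every gene has
one eQTL) are dropped with a warning before fitting.

## Co-expression networks

Soft threshold: powers 2–20, scale-free fit measured as the signed R² of
log₁₀(frequency) on log₁₀(connectivity) over 10 equal-width connectivity
bins; chosen power is the smallest with fit ≥ 0.8.  Powers whose mean
connectivity falls below 1.0 are ineligible: raising the power always
empties the network until the log-log fit looks good for the trivial reason
that almost no edges remain, and module detection degrades in that regime.
If no eligible power reaches the target, the best-fitting eligible power is
used with a warning (white-noise input always takes this path).

Module detection is a fixed-height cut of the average-linkage tree of
1 − TOM at 0.99 (the dissimilarity scale's conventional cut), with two
acceptance rules: minimum size 30, and a cohesion guard requiring a
branch's median intra-branch TOM to exceed 3× the network's background
overlap (the 0.1 quantile of off-diagonal TOM).  A cut at a *quantile of
merge heights* was considered and rejected: on permuted (structure-free)
data, average-linkage merge heights concentrate, and any quantile cut
produces a few large clusters that pass a size rule alone — the cohesion
guard is what makes the permutation stability result ("no modules in
permuted data") robust across soft-threshold powers.  The guard assumes
modules do not cover ~90% or more of the network (the background quantile
would then no longer estimate noise); both the ratio and the quantile are
configurable.

Eigengenes are the first right singular vector of the standardized member
submatrix, unit norm, oriented to correlate non-negatively with members on
average.  Merging is iterative best-pair with an inclusive ≥ 0.8 threshold.
The stability check permutes every gene's values across samples
independently and reruns the full pipeline including the power scan.

## Preservation

Two density statistics (mean intramodular adjacency at power 6, proportion
of variance explained by the module eigengene) are computed in the test
data; two connectivity statistics (correlation of intramodular connectivity
vectors, correlation of the gene-gene correlation upper triangles) compare
reference and test.  This is a 2+2 subset with the composite structure
(median within class, mean of the two class composites = Zsummary) of the
full module-preservation statistic roster; fidelity to that tool's exact
statistic list is not claimed — the categorical thresholds (2 and 10) are
the interface contract.

Null gene sets are drawn per module size from the genes present in the test
tissue.  Density nulls sample from *all* genes (the density question is
competitive: denser than a random gene set of this network?).  Connectivity
nulls *exclude the evaluated module's members*: sampled module genes carry
reproducible connectivity into the null and deflate the Z of a genuinely
preserved module.  With highly modular synthetic data (most genes in some
module), connectivity nulls still contain other modules' genes, so
connectivity Z-scores are conservative there; the canonical preservation
experiment in the tests therefore plants a single 50-gene module against
250 background genes, splits 200 samples into reference/test halves, and
checks Zsummary > 10 for the intact module and < 2 against re-wired data.
A null standard deviation of zero yields Z = +∞ (with a warning) if the
observation exceeds the null mean, else 0.

## Synthetic data

The generator emulates the statistical structure of the study's inputs at
desk scale; defaults: 300 SNPs in AR blocks of 10 with adjacent-dosage
correlation 0.7, 300 genes with 4 planted 50-gene modules at within-module
correlation 0.6, 200 expression donors, eQTLs for half the genes at effect
0.5 SD, GWAS cohort of 4,000 with per-causal-SNP effect 0.15 SD.

Genotypes are two thresholded latent-Gaussian haplotypes per sample; the
latent AR parameter is calibrated per block by inverting the tetrachoric
attenuation so the *dosage* correlation, not the latent one, hits the
target.  This controls correlation but is not a coalescent model: no
recombination hotspots, no allele-frequency spectrum beyond U(0.05, 0.5),
no population structure.

Module genes load on a shared factor with per-gene loadings drawn uniformly
in √cor ± 0.15, so the expected pairwise within-module correlation equals
`module_cor` while genes differ in centrality.  The heterogeneity matters:
equal loadings make the connectivity distribution bimodal and defeat the
scale-free criterion, whereas real co-expression modules have hub
structure.  cis-eQTL effects are added with loadings rescaled so gene
variance stays 1 and within-module correlation is unchanged.

Because the generator's marginals are clean (normal expression, exact
study-design sampling), passing tests demonstrate the machinery's
statistical behaviour — calibration, recovery, control — under the stated
conditions, not robustness to the pathologies of real expression data
(batch effects, counts, outliers, sample overlap between tissues).

## Problem sizes in tests and the acceptance script

Simulation sizes (5,000–10,000 null genes for calibration, 50 seeds for
recovery and enrichment, 50 stability replicates, 100 preservation
permutations, 300–500 replicates for family-wise error) were chosen as the
package's standard desk-scale experiment battery: large enough that the
binomial/Monte-Carlo noise is small against each criterion's margin, small
enough to run in minutes on one CPU.
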