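# Methods

## The model

Gene expression is modeled as a sparse linear function of cis genotypes,

    y = X beta + eps,    X = [X_e, X_ne],

with `X_e` the "essential" variants — those overlapping at least one of four
epigenomic annotation tracks (H3K27ac, H3K4me3, DNase hypersensitivity,
CTCF) — and `X_ne` the rest.  Genotypes and expression are standardized
(variance 1), so effect sizes are on the correlation scale throughout.

The weights are estimated by an elastic net whose penalty is *partitioned*
by annotation: for shrinkage parameter `lambda >= 0` and mitigation factor
`phi in (0, 1]`, the per-sample loss is

    f(beta) = beta' G beta - 2 beta' r
              + (lambda/4) sum_j m_j beta_j^2
              + (lambda/2) sum_j m_j |beta_j|,

with `m_j = phi` for essential variants and 1 otherwise.  A mitigation
factor below one softens both penalty components on annotated variants, so
putatively functional variants are preferentially retained.  The L2 and L1
coefficients are fixed at `lambda/4` and `lambda/2`; there is no free
elastic-net mixing parameter.

Only summary statistics are needed to evaluate this loss:

* `G` — the LD (correlation) matrix of the candidate variants, estimated
  from a reference panel of matched ancestry and shrunk toward the identity,
  `G <- (1 - eps) G + eps I` with `ridge_eps = 0.05` by default.  The ridge
  guarantees a positive-definite Gram with out-of-sample LD and bounds the
  coordinate-descent curvature away from zero.
* `r` — the vector of marginal variant-expression correlations, recovered
  from marginal eQTL z-scores as `r_j = z_j / sqrt(z_j^2 + n_j - 2)`.  This
  inversion is exact for the t-statistic of a simple linear regression and
  makes the input scale-free: files reporting betas on any unit are reduced
  to z first.  Per-variant sample sizes may differ (meta-analyzed eQTL
  resources are heterogeneous); the model's training N is the median
  variant N.

The loss is written per sample (divided by N), so `lambda` is comparable
across genes and cohorts; the sum-scale equivalent is `lambda_sum =
N * lambda`.

## Optimization

Cyclic coordinate descent with the closed-form single-coordinate update

    beta_j <- S(rho_j, lambda m_j / 4) / (G_jj + lambda m_j / 4),

where `S` is the soft-threshold and `rho_j = r_j - sum_{k != j} G_jk
beta_k`.  Variants are visited in genomic-position order; convergence is
declared when the largest coefficient change in a sweep drops below `tol`
(default 1e-8).  The inner loop is compiled with numba.  The zero vector is
optimal exactly when `lambda >= lambda_max = max_j 4 |r_j| / m_j`, which
anchors all penalty grids.  The solver is verified against an independent
projected convex solver (positive/negative split plus L-BFGS-B) to 1e-6 on
exact in-sample Gram matrices.

## Tuning

Three tuning parameters: the window `w` (which candidate variants enter),
the mitigation `phi`, and the shrinkage `lambda`.

**Candidate windows.**  Linear windows are flanks around the gene body
(default grid 100 kb / 250 kb / 500 kb / 1 Mb in the CLI; configurable).
3D-genome windows are derived per gene: for TADs and contact domains, the
union of intervals containing the TSS; for chromatin loops and
promoter-capture Hi-C, both anchors of every pair with one anchor touching
the promoter (TSS ± 2 kb; configurable — no canonical value exists).  Empty
windows are skipped with a log entry.  Cell types lacking annotation borrow
it from the transcriptionally nearest annotated cell type (Spearman
correlation of log1p TPM profiles; an optional eQTL-effect feature block can
be averaged in, off by default).

**Shrinkage via pseudo-variable selection (PVS).**  Pseudo variables share
the LD of the measured variants but are null by construction, so any
shrinkage level that lets a pseudo variable into the model is too weak.
Their summary statistics are drawn directly on the per-sample scale,

    r_pi ~ N(0, G / N),

(with var(Y) = 1; Cholesky with an eigenvalue-clipping fallback), and the
augmented system with block-diagonal Gram `[[G, 0], [0, G]]` and stacked
`(r, r_pi)` is solved along an ascending 50-point log-spaced grid on
`[0.01 lambda_max, lambda_max]` (the augmented lambda_max, so the all-zero
endpoint always exists).  `lambda_hat` is the smallest grid value at which
every pseudo coefficient is exactly zero; pseudo variables are never
mitigated.  Ten replicates are drawn and their `lambda_hat` averaged.  One
pseudo variable per measured variant is used — the natural choice that
doubles the Gram.

The scale of the pseudo draw is the one self-consistent with the per-sample
loss: under the null the measured `r` has covariance `G / N` as well, so the
pseudo maximum estimates exactly the noise level the shrinkage must beat.
(The sum-scale alternative `N(0, Sigma)` differs only by relabeling lambda.)

**(phi, w) via summary-statistics cross-validation.**  The observed `X'y` is
the sum of N per-individual contributions `X_i y_i ~ N(X'y / N, Sigma)`.
N − 1 contributions are simulated, the N-th is the residual (so the sum is
conserved exactly, to float precision), and a seeded balanced partition
assigns them to 5 folds.  Each fold's held-out statistics validate the model
trained on the remainder.  The validated loss is the *penalized* objective
evaluated at `lambda_hat(phi, w)` — quadratic term from the held-out fold
plus the mitigation-aware penalty at the fitted coefficients.  Including the
penalty makes the zero model the reference (loss 0) and prevents borderline
noise fits from winning the grid search.  The `mse` strategy instead lets
lambda join the grid search and scores by the unpenalized quadratic loss
(held-out MSE up to a constant).

Ties are broken toward the smaller window, then the larger phi, then the
larger lambda — the more parsimonious model in each direction.

**Model emission.**  After selection, a final fit on the full `r` at the
chosen triple produces the weights.  A gene yields *no model* when the final
solution is all-zero or when the best cross-validated loss is not below 0,
i.e. when no candidate validates better than predicting nothing.  This
mirrors the practice of retaining only significantly predictive models and
is what keeps null genes (h2 = 0) from emitting spurious single-variant
models.

## Downstream analyses

**TWAS.**  The gene-trait statistic is the weighted-burden form
`Z = w' z / sqrt(w' G w)` over the model variants found in the GWAS after
allele harmonization (sign flips for swapped alleles; strand-ambiguous A/T
and C/G variants dropped by default).  Results with under 50% of absolute
weight mass covered are flagged low-coverage.  Significant genes are grouped
into loci iteratively: the smallest-p unassigned gene is the sentinel of a
1 Mb window (gene midpoint ± 500 kb; the total width is configurable since
"a 1 Mb window surrounding" is ambiguous between ±500 kb and ±1 Mb), and a
locus is *known* when a same-trait catalog hit lies within 1 Mb (inclusive)
of the sentinel.  The mean sentinel chi-square over known loci estimates the
noncentrality and is reported as an empirical power metric.

**Cross-cell-type heterogeneity.**  For TWAS z-scores `U` of one gene in K
cell types, `H = sum_k (U_k - Ubar)^2 = U' C U` with C the centering matrix.
The null covariance of `U` is the LD quadratic-form kernel
`beta_k1' Sigma beta_k2` over the union variant set (zeros where a cell type
does not use a variant), normalized to a correlation matrix `Phi` so that
z-scores have unit null variance (the raw kernel is available behind a
flag).  Under the null `H ~ sum_k lambda_k chi2_1` with eigenvalues of
`C Phi C'`; tiny negative eigenvalues (relative magnitude below 1e-10) are
clipped to zero, materially negative ones are an error.  Tail probabilities
use Ruben's central chi-square mixture series, which carries a rigorous
truncation bound (the remaining mixture mass) and reproduces the
chi-square closed form at machine precision; near-singular spectra fall back
to Imhof's characteristic-function inversion, then to a Satterthwaite-Welch
moment match.  The method used is recorded per result.  Genes tested per the
blood/cell-type convention use a Bonferroni threshold of 0.05 over the
number tested (0.05/1222 = 4.1e-5 in the motivating analysis).

**Cell-type enrichment and signatures.**  Expression processing: drop genes
unexpressed in every cell type, rescale each cell type to one million TPM,
and define the specificity score as the row-normalized share, so scores sum
to one per gene.  Cell-type-specific gene sets are either the top decile of
specificity (nearest-rank; threshold ties all included) or genes whose TPM
exceeds the across-cell-type mean plus one sample SD (strict inequality;
with two cell types no gene can qualify).  Enrichment of TWAS hits regresses
gene-level chi-squares on set membership with HC1-robust standard errors,
one-sided for positive enrichment; the reference weighted-regression
framework is not fully specified by its source, so this robust OLS is a
deliberate, transparent reimplementation, with a label-permutation p-value
available as a fallback.  Drug signatures are the Bonferroni-significant
genes split by sign of z, ranked by |z|; a signature is usable only with at
least 10 genes on each side.

**Leave-cohort-out subtraction.**  To keep training and testing cohorts
independent when the training meta-analysis contains the test cohort,
fixed-effect inverse-variance weights are inverted exactly:
`beta_out = (w_m b_m - w_c b_c) / (w_m - w_c)`, `se_out = (w_m - w_c)^{-1/2}`
with `w = se^{-2}`.  This is the exact inverse of re-meta-analysis (round
trips at 1e-13) and errors out when the cohort is not a precision subset of
the meta-analysis.

## Synthetic data

The generator emulates every input with known truth.  Genotypes are two
latent-Gaussian AR(1) haplotypes thresholded at the MAF quantile
(MAF ~ U(0.05, 0.5)); the latent autocorrelation `ld_rho = 0.5` by default,
restarting every 200 variants to mimic LD blocks.  On the dosage scale the
AR(1) correlation attenuates (latent 0.9 realizes ≈ 0.53 adjacent dosage
correlation, a value pinned in the tests).  Causal variants (default 5) are
drawn from the essential set with probability 0.9 and scaled so the genetic
variance matches `h2_cis = 0.3`; expression is standardized and marginal
summary statistics are exact simple-regression t-statistics, so the reader's
z-to-r inversion recovers the sample correlations bit-for-bit.  The default
cohort sizes are 500 reference individuals, 1,000 eQTL samples, and 50,000
GWAS samples.  GWAS z-scores follow a mediation model,
`z = sqrt(n_gwas) * alpha_med * G beta + MVN(0, G)` with `alpha_med = 0.1`.
Multi-cell-type truth shares each causal variant across all K = 3 cell types
with probability 0.7, else assigns it privately.  Annotation tracks are
BED intervals covering essential variants ± 250 bp, distributed cyclically
over the four track names, plus one promoter-to-causal-cluster loop so 3D
windows are exercisable.

What the generator does *not* emulate: realistic recombination maps or
demography, dosage uncertainty, expression batch structure, trans effects,
and cross-cohort LD mismatch beyond the ridge.  Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
generative model, not performance on real cohorts.

## Numerical choices and test problem sizes

* Coordinate descent: tol 1e-8 (1e-12 in oracle comparisons), genomic-order
  sweeps, warm starts along ascending penalty grids.
* LD ridge 0.05; PSD fallbacks clip eigenvalues at zero.
* BED intervals are 0-based half-open, variant positions 1-based; the
  conversion happens once at the overlap boundary and is tested at the
  fence posts.
* Weight files store full float precision via `repr`; round trips are
  bit-exact.
* The test and acceptance workloads use 50-variant genes, 20–50 genes per
  experiment, 2,000 draws for calibration checks and 1e5 draws for
  Monte-Carlo oracles — sizes chosen so the whole suite runs in a few
  minutes on one CPU while keeping Monte-Carlo error well below the asserted
  tolerances.

## Known limitations

* Cis only; no trans-eQTL component.
* Single LD panel; no multi-ancestry combination or fine-mapping posterior
  probabilities — the association layer is a standard single-panel
  weighted-burden test.
* The enrichment regression is a stand-in for an unspecified weighted
  scheme; permutation p-values are offered where its small-sample behavior
  matters.
* No liftover, imputation-quality weighting, or dosage handling in readers.
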