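# Methods

`ifomics` implements the statistical core of a multi-omics study design in
which an intermittent-fasting intervention in diabetic mice is read out
through three molecular blocks — a small hippocampal gene signature, gut
microbial counts, and microbial metabolites — plus metabolic phenotypes.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic generator does and does not
emulate.

## The synthetic study generator

All tests and the acceptance script run on simulated data with the shapes
of the target design: two groups of 10 and 11 mice, 36 genes, 26
metabolites (23 plasma-metabolite-like and 3 SCFA-like columns), and 50
taxa of which 17 respond to treatment.

The generative model is a single shared latent factor

    u_i = mu_{g(i)} + eps_i,    eps_i ~ N(0, 1),

with `mu_IF - mu_control = group_effect` (default **4.0** latent-SD
units).  Continuous blocks are `baseline + loading * u_i + N(0, noise_sd)`
on the informative features (default `loading = 2`, `noise_sd = 1`);
metabolite values are exponentiated so intensities stay positive.  Taxon
log-abundances are `baseline + gamma_t * u_i + noise` with alternating
signs of `gamma` over the informative taxa (treatment reshapes the
community rather than uniformly inflating it), pushed through a softmax
and drawn multinomially with log-normal library sizes (mean 35,000,
sigma 0.1), so counts are compositional and the default rarefaction depth
of 28,257 retains almost every sample.

Why `group_effect = 4`: the shared latent factor bounds what any
classifier can do — averaging many informative features recovers `u`
almost exactly, so the Bayes accuracy is `Phi(group_effect / 2)`
regardless of how many features load on it.  The design this package
emulates has strongly separable groups (per-block predictive accuracies in
the 90–100% range), which requires a latent separation of roughly 3.3 SD
or more; 4.0 SD (Bayes accuracy ~98%) reproduces that regime.  With
`group_effect = 2` the ceiling is ~84% no matter the loading, which is a
useful *moderate-effect* setting but not the default study condition.

A nuisance timepoint covariate alternates within each group (balanced, so
it is nearly orthogonal to treatment) and shifts every block through
per-feature random coefficients scaled by `time_shift = 0.5`.  Phenotypes
(glucose mg/dL, insulin mU/L, bodyweight g) decrease with `u`, emulating
metabolic improvement under treatment.

What the generator does **not** emulate: sequencing-read error, taxonomy,
batch or injection-order drift, zero-inflation beyond what the
logistic-normal/multinomial induces, repeated measures within mouse, and
library-size confounding with treatment.  Passing tests therefore
demonstrate correctness of the statistical machinery and its calibration
under this generative model, not performance on real sequencing data.

The planted truth (informative indices, latent values) is stored in a
`truth` sub-record that only tests and the acceptance script read;
analysis stages never touch it.

## Preprocessing

* **CSS** (cumulative sum scaling): per sample the scaling factor is the
  sum of counts at or below the chosen quantile (default 0.5) of that
  sample's *positive* counts, times a fixed scale (default 1000).  The
  adaptive-quantile variant is deliberately out of scope; the quantile is
  a parameter.
* **Rarefaction**: multivariate-hypergeometric subsampling without
  replacement to a fixed depth (default 28,257); samples below depth are
  dropped with a warning rather than failing the run.
* **CLR**: `log(x + pc) - mean_k log(x_k + pc)` per sample, pseudocount
  default 1.  On counts and on relative abundances this differs only
  through the pseudocount, since per-sample centering removes the
  library-size constant.
* **Autoscaling** uses the sample standard deviation (ddof = 1), so a
  column `[1, 2, 3]` maps to `[-1, 0, 1]`; zero-variance features are
  dropped with a warning by default.  Parameters are stored and can be
  applied to held-out samples.
* **Expression filter**: keep a gene iff strictly more than `threshold`
  (default 1, FPKM-like units) in at least `min_samples` (default 10)
  samples.
* **BH-FDR** goes through `statsmodels.stats.multitest`; an independent
  brute-force step-up oracle checks it in the test suite.
* Scalar formulas: HOMA-IR = insulin[mU/L] x glucose[mg/dL] x 0.05551 /
  22.5 (the 0.05551 converts glucose to mmol/L), and relative expression
  by `2^-ddCT`.

## PLS-DA and repeated double cross-validation

The classifier is PLS2 on a centered one-hot class matrix, fitted by
NIPALS with training-only centering/scaling.  For two classes the
indicator matrix has rank 1 and the inner loop converges in a single pass;
weight vectors are unit-norm with the deterministic sign convention that
the largest-|value| coordinate is positive (this makes the DIABLO
reduction an exact equality, not an equality up to sign).  Convergence
tolerance is 1e-9 with up to 500 iterations — tight enough that the
single-block sGCCA fixed point and the NIPALS fixed point agree to 1e-8.

rdCV: per repetition a stratified outer split (default 7 folds) holds out
each sample once; per outer fold an inner CV (default 6 folds) over
1..`max_components` (default 3) picks the component count minimizing
*balanced* misclassification (ties favor fewer components, protecting the
10-vs-11 imbalance); the tuned model predicts the outer test fold.  The
default 200 repetitions mirror the study protocol; class "probabilities"
are assignment frequencies over repetitions and accuracy is correctly
predicted samples over total samples under the frequency-argmax consensus.
Prediction uses the maximum predicted-indicator column; probabilities for
single fits are a softmax-free normalization of the shifted indicator row.

The permutation gate shuffles labels and refits a reduced-cost rdCV
(1 repetition per permutation by default; the full-cost mode is a
parameter); empirical p = (1 + #{perm >= obs}) / (1 + n), with a one-sided
t comparison of the observed accuracy against the permuted distribution
reported alongside.  The null-uniformity check in the test suite runs the
observed model at one repetition too, because exact uniformity of the
permutation p requires observed and permuted statistics to be computed at
identical cost; it uses 5 outer / 5 inner folds and 2 components as its
problem size so 200 null datasets x 100 fits stay inside a desk-scale run.

## Multi-block sparse discriminant integration

One latent variate per block per component, maximizing the design-weighted
sum of score covariances (response included at fixed weight 1).  The
design matrix defaults to the *full* design — every off-diagonal weight 1;
the ambiguous phrasing of a "random use" of the full design in the source
protocol is read as plain use of the full design.  Block-coordinate
ascent: each weight update is the design-weighted covariance direction,
hard-thresholded to exactly `keepX` nonzero entries (ties broken toward
the smaller feature index) and renormalized.  Each update is the exact
maximizer under the cardinality constraint, so the objective is
non-decreasing — asserted at every iteration of every fit.  Initialization
is each block's dominant singular vector, so fits are deterministic with
no seed.  Blocks are deflated by their own component; the response is not
deflated.

With a single block and full keepX the update collapses to the NIPALS
fixed point, so the model reduces exactly to PLS-DA — this reduction and
the exact-sparsity guarantee are acceptance-tested.

`keepX` tuning is a coordinate-wise search over blocks in input order with
cross-validated misclassification (default tenfold), ties toward the
smaller value.  On small studies the selection is high-variance; the test
suite asserts modal recovery over repeated draws rather than per-run
correctness.  Prediction is a per-block regression of the class indicator
on that block's scores with majority vote across blocks, ties broken by
the averaged indicator.  Reported model views: block-by-block Pearson
correlations of first-component scores, cross-block feature links at
|r| >= 0.7 by default (the cutoff is a choice, not a reproduction of the
source figure), and clustered-image-map row/column orders from complete-
linkage Euclidean clustering.

## Microbiome statistics

* **PCoA** eigendecomposes the Gower-centered `-D^2/2` matrix; negative
  eigenvalues are reported and excluded from coordinates — no
  Cailliez/Lingoes correction, by design (transparency over silent
  adjustment).
* **PERMANOVA** uses the pseudo-F from among/within sums of squared
  distances, whole-sample label permutations, and the +1-corrected p.  An
  `exhaustive` mode enumerates all label permutations for small n, which
  the acceptance suite compares against a hand enumeration of the distinct
  splits.
* **Partial CAP / db-RDA** embeds the distances via PCoA (positive axes),
  regresses out the conditioned nuisance design, then projects the
  residuals onto the conditioned constraint space.  Inertia fractions are
  of total positive-axis inertia and the constrained + conditioned +
  residual decomposition sums to 1 within 1e-8.  Per-term fractions are
  sequential in column order; significance is Freedman–Lane permutation of
  reduced-model residuals (raw-label permutation by flag).  Factors are
  dummy-encoded against the first level.
* **ANCOM**: all pairwise log-ratio location tests (rank-sum for two
  groups, Kruskal–Wallis otherwise; pseudocount 1), BH-adjusted *within
  each focal taxon* at alpha = 0.05; W counts rejections and a taxon is
  flagged at W >= 0.7 (m - 1).  These defaults follow the method's common
  configuration; the original study does not print its variant, so
  detected-set membership is not claimed to reproduce it.
* **CLR–phenotype correlations**: Pearson r with two-sided t-based p, BH
  across all (taxon, phenotype) pairs.

Bray–Curtis is bounded in [0, 1], symmetric and hollow; the triangle
inequality can fail and is not asserted.

## Co-expression modules and hub genes

Signed adjacency `((1 + r)/2)^beta` (unsigned `|r|^beta` by flag);
soft-threshold selection takes the smallest power whose sign-adjusted
log-log degree-distribution R^2 reaches 0.8, else the argmax.  The
topological overlap matrix follows the standard shared-neighbor formula
and is checked against a triple-loop oracle to 1e-12.  Modules come from
average-linkage clustering of 1 - TOM with a *static* branch cut (default
height 0.25, minimum size 30; the pipeline default lowers the minimum size
to 5 because the simulated gene block has only 36 genes).  Dynamic tree
cutting and module merging are out of scope.  Module eigengenes are the
first principal component of the module's standardized expression,
sign-oriented to correlate positively with the module mean; kME is the
gene–eigengene correlation.  Hub genes satisfy all three thresholds
simultaneously — kME > 0.8, |trait r| > 0.85, BH-q < 0.01 (trait coded
0/1 for treatment) — and edge export keeps weights strictly above 0.4.

## Pipeline, reproducibility and problem sizes

Stage order follows the analysis design: per-block predictive validation
precedes integration.  Per-stage seeds derive from the global seed by
CRC32 hashing of the stage name, so adding a stage never shifts another
stage's randomness; the manifest records config, seeds, versions and
SHA-256 checksums of every artifact, and two runs with the same config and
seed are byte-identical.  The OTU block enters integration as CLR-
transformed (CSS-relative by flag), recorded in the manifest.

Desk-scale defaults (20 rdCV repetitions, 50 permutations, 199 PERMANOVA
permutations) keep a full run around a few seconds; the protocol-scale
profile (200 repetitions, 1000 permutations, keepX 10, one component,
tenfold tuning) is accepted and tagged "protocol" in the manifest.  The test
suite and `scripts/acceptance.py` use 20-repetition rdCV, 99-permutation
gates, 999-permutation PERMANOVA and 20-seed Monte-Carlo sweeps as their
problem sizes.

## Known limitations

* ANCOM is O(m^2) pairwise tests — fine for tens to hundreds of taxa, not
  thousands.
* The co-expression layer materializes dense gene-by-gene matrices; it is
  intended for signatures of tens to low thousands of genes.
* Permutation p-values are discrete (resolution 1/(n+1)); null-uniformity
  holds up to that discreteness.
* CAP inertia ignores negative-eigenvalue axes, so fractions are of the
  Euclidean-embeddable part of the variation.
* `tune_keepx` does a single coordinate pass; it does not explore
  interactions between blocks' cardinalities.
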