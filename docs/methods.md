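# Methods

## Model

`microgp` performs exact Gaussian-process regression of a numeric host
phenotype on microbial community profiles. The latent function has a
zero-mean GP prior with a kernel built from pairwise community
dissimilarities, and observations add i.i.d. Gaussian noise with variance
σ_n². For a training kernel matrix `K` and `K_y = K + σ_n² I`, the predictive
distribution at a test sample is Gaussian with

    μ*  = k*ᵀ K_y⁻¹ y,
    σ*² = k** + σ_n² − k*ᵀ K_y⁻¹ k*,

and hyperparameters maximize the log marginal likelihood

    log p(y) = −½ yᵀ K_y⁻¹ y − ½ log|K_y| − (n/2) log 2π.

All solves go through Cholesky factorization and triangular back-substitution;
explicit inverses appear only in the test-suite oracles.

### Dissimilarity kernels

Each β-diversity index d (Jaccard, Bray–Curtis, unweighted UniFrac, weighted
UniFrac; all bounded in [0, 1]) yields one covariance component

    k_c(x, x′) = σ_c² exp(−d(x, x′)² / (2 l_c²)),

and the multiple kernel is the elementwise sum of the four components, each
with its own (l_c, σ_c). Unweighted UniFrac is implemented in two denominator
conventions: `all_branches` (every branch of the tree; the default) and
`union_branches` (only branches present in at least one community; the
canonical UniFrac normalization). `all_branches ≤ union_branches` holds for
every pair, since the two share a numerator and the all-branch denominator is
never smaller. Which convention a published analysis used is often
unstated, so both are exposed and recorded in the distance-matrix metadata.

Per-branch abundances A_j are cumulative: the summed relative abundance of
all leaves descending through branch j. The tree is stored with a
per-edge boolean descendant-leaf incidence matrix so a sample's full branch
profile is one matrix–vector product.

### Assumptions

- Targets are exchangeable given the community profile; noise is homoscedastic
  Gaussian.
- Community dissimilarity is a sufficient summary of between-sample structure;
  taxa enter only through the chosen β-diversity indices.
- Distances are computed once on the full sample collection (train and test
  jointly) and sliced per split. Pairwise dissimilarities involve no targets,
  so this leaks no label information; it does make the procedure mildly
  transductive (test *inputs* are seen before training), which mirrors the
  standard workflow for dissimilarity-based analyses.

## Positive-semidefiniteness repair

The four dissimilarities are not Euclidean-embeddable in general, so the
exponentiated kernels can be indefinite (smallest eigenvalues of order
−0.1 σ² are routine on sparse tables). Two repair modes exist:

- **jitter** (default): add λI with λ = max(0, tol − λ_min), escalating
  tenfold until Cholesky succeeds; tol defaults to 1e-8.
- **clip**: eigendecompose and floor eigenvalues at tol.

For a *fitted model*, jitter-mode λ is computed from the kernel on the full
sample set and the repaired matrix is sliced. Two alternatives were measured
and rejected on the well-specified synthetic pipeline: repairing only the
train block with test variances floored biases 90%-interval coverage down to
≈ 0.78 (the training side absorbs λ as extra noise the test side never sees),
and computing λ from the train block but lifting the test diagonal still
permits negative variances because a principal submatrix can be less
indefinite than the full matrix. With full-matrix jitter the effective kernel
K_full + λI is PSD, so predictive variances are non-negative by construction
and measured 90% coverage is ≈ 0.90. During hyperparameter optimization, the
repair runs on the train block only (the test samples play no role in the
likelihood); the applied correction is recorded in the model history and a
loud warning fires if it exceeds 1% of the mean kernel diagonal. Rectangular
cross-covariance blocks are never modified — jitter touches diagonals only,
so slicing the repaired full matrix and slicing the raw cross block agree
exactly. A floor of σ_n²·10⁻⁶ (standardized scale) remains as a guard against
rounding; with full-matrix jitter it is not reached in practice.

## Training

- **Standardization.** Targets are centered and scaled to unit variance for
  fitting (a zero-mean prior on raw ages or clinical scores would be badly
  misspecified); predictions are returned on the original scale with the
  variance Jacobian s_y² applied.
- **Optimizer.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), full batch,
  200 epochs, learning rate 0.1. Gradients are analytic:
  ∂ log p/∂θ = ½ tr((ααᵀ − K_y⁻¹) ∂K/∂θ) with α = K_y⁻¹ y.
- **Positivity.** l_c, σ_c, σ_n are reparameterized through softplus; Adam
  runs on the unconstrained scale.
- **Initialization.** l_c = median off-diagonal training distance per
  component; σ_c² = var(y)/n_components; σ_n² = 0.1 var(y) (all on the
  standardized scale, hence unit-invariant).
- **Best-iterate retention.** The iterate with the highest marginal
  likelihood is kept, guarding against late-epoch divergence. A non-finite
  likelihood triggers one retry at half the step size, then an abort with the
  recent likelihood trace.
- Training is deterministic: the initialization is closed-form and the
  optimization is full-batch, so the `seed` argument only tags provenance.

## Evaluation

- **NLL**: mean negative Gaussian log predictive density (natural log) of
  held-out targets; **RMSE** of the predictive means. Both on the original
  target scale.
- **Calibration/ECE**: 19 confidence levels 0.05, …, 0.95; central intervals
  μ* ± z₍(1+p)/2₎ σ*; ECE is the unweighted mean absolute gap between nominal
  level and empirical coverage. Coverage is non-decreasing in the level by
  construction.
- **Confidence/oracle curves/AUCO**: test points are removed one at a time by
  descending predictive variance (confidence) or descending absolute error
  (oracle), ties broken by ascending sample index (stable sort), from 0 to
  ⌊0.9N⌋ removed; each curve records survivor RMSE. AUCO is the signed
  trapezoidal area of (confidence − oracle) over the removal-fraction axis;
  the curves themselves are reported so any negative stretches are auditable.
  At least 10 test points are required.
- **Repeated splits**: deterministic shuffles seeded `base_seed + split`;
  ⌊n/2⌋ train, remainder test (odd n puts the extra sample in test); metrics
  aggregated as mean ± SEM with SEM = sd(ddof=1)/√n_splits. Per-split records
  and a manifest of every resolved parameter (splits, fractions, epochs,
  learning rate, kernel components) are persisted with the report.

## Synthetic data

The generator states a world with the pathologies of 16S amplicon data, not
any particular cohort:

- **Trees**: sequential random-join rooted binary topologies; branch lengths
  i.i.d. exponential with mean 1 (2n − 2 edges for n leaves).
- **Counts**: per-sample log-normal taxon intensities whose correlation decays
  with patristic distance as exp(−patristic/τ), τ = tree height / 2;
  independent Bernoulli thinning with default expected zero fraction 0.7
  (typical of prevalence-filtered gut 16S tables); multinomial sampling at a
  fixed depth of 10,000 reads. Samples that lose every taxon are redrawn (at
  most 100 attempts).
- **Targets**: f ~ N(0, K) with K the dissimilarity kernel on the simulated
  distance matrix (default: weighted UniFrac, l = 0.5 — mid-range for
  distances bounded in [0, 1] — σ = 1, σ_n = 0.3, i.e. ≈ 9% noise variance),
  plus i.i.d. Gaussian noise. The truth kernel is itself jitter-repaired
  before sampling; the correction is recorded with the generating parameters.

Random streams are split per generator via `SeedSequence` spawn keys, so
changing one stage's draws does not perturb the others.

What a green synthetic test does **not** establish: the generator produces no
sequencing error, no batch or compositional bias beyond closure, no
phenotype-driven taxon shifts (targets are drawn *from* the dissimilarity
kernel, so the model class is well specified by construction), and sample
sizes are hundreds, not thousands. Calibration and recovery results on this
world are statements about the implementation's correctness, not about
expected performance on real cohorts.

## Numerical choices and degenerate inputs

- Distance matrices must be symmetric within 1e-12 with zero diagonal;
  β-diversity entries are validated to [0, 1].
- Presence means strictly positive abundance at full floating precision — no
  pseudocounts or detection thresholds.
- Both-empty community pairs are rejected (0/0); duplicated samples yield
  zero distances and are handled by the jitter, not deduplicated.
- The prevalence filter drops a taxon iff its positive-sample count is
  strictly below min_prevalence × n_samples ("fewer than"), and is
  idempotent; relative-abundance rows must sum to 1 within 1e-9.
- Unrooted Newick inputs (basal multifurcation) are midpoint-rooted with a
  warning; UniFrac values depend on the root, so the re-rooting is surfaced,
  never silent.
- Constant training targets and fewer than 3 training samples are rejected.

## Known limitations

- Exact GP: O(n³) time and O(n²) memory; intended for the hundreds-to-
  low-thousands sample range. No sparse/inducing-point variants.
- Gaussian likelihood only; no classification, no heteroscedastic noise.
- Kernel indefiniteness is repaired, not avoided; with very sparse tables the
  jitter can reach a few percent of the kernel scale (it is logged and
  warned about). A PSD-by-construction alternative (e.g. embedding distances
  first) is out of scope.
- The multiple kernel sums the four components; learned convex weights and
  generalized/variance-adjusted UniFrac are not implemented.
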