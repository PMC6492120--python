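# Methods

## Model and procedure

The pipeline treats an ecogeographic morphometric study as four linked
analyses over three inputs: a specimen-level trait table (strictly positive
linear measurements in mm, with species, sex, age class, provenance and
locality coordinates), species-level environmental tables, and a rooted
phylogeny with branch lengths proportional to time.

**Blocks.** Morphological measurements are natural-log transformed;
between-species analyses use species means computed as the arithmetic mean
of the female mean and the male mean per trait (robust to unbalanced sex
ratios — the pooled mean would weight the commoner sex). Environmental
variables are divided by their standard deviation so measurement scale
cannot dominate; the morphology block is deliberately *not* rescaled, so a
common allometric size factor can surface in the first latent variable.
Within-species analyses first remove sex differences by centering every
specimen on its (species, sex) mean; the output is the deviation
(specimen − mean), whose sign convention is immaterial to all downstream
covariance/SVD analyses.

**2B-PLS.** With centered blocks X̃ (n×p) and Ỹ (n×q), the SVD of
R = X̃ᵀỸ/(n−1) gives K = min(p, q, n−1) pairs of unit loading vectors with
successively maximal score covariance d_k; loadings within a block are
orthogonal, effect sizes are d_k²/Σd_i², and r_k is the Pearson
correlation of paired scores. SVD sign indeterminacy is fixed by flipping
each u_k so its largest-magnitude entry is positive (v_k follows jointly).

**Phylogenetic correction.** Brownian motion on the tree implies species
covariance C[i,j] = root-to-MRCA path length. All phylogenetic variants
GLS-whiten by the lower Cholesky factor L of C: X̃ = L⁻¹(X − 1âᵀ), with
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X the GLS root estimate. Whitened ordinary
cross-products equal GLS cross-products exactly, so one code path serves
both cases and an equal-branch star tree reproduces the ordinary analysis
to machine precision (the suite's master equivalence test). A diagonal
jitter of 1e-10·trace(C)/n is added only if the factorization fails.
Covariances use denominator n−1 in both branches so the equivalence is
exact. Only the Brownian-motion model is supported (no OU or branch-length
transforms).

**Reduced-rank regression for clines.** Each trait is regressed on
intercept + latitude + longitude (OLS, or GLS with weight C⁻¹). The SVD of
the p×2 coefficient matrix B gives maximal gradient slopes d_k
(trait log-units per degree), unit geographic directions w_k, and
morphological loadings u_k: for any unit trait combination u the
fitted-surface gradient norm ‖Bᵀu‖ is at most d_1, attained at u_1.
Coordinates are used in raw decimal degrees — the slopes are then
interpretable per degree — with no map projection and no cos-latitude
correction of longitude; over continental extents this makes east–west
degrees shorter than north–south ones, a known anisotropy left to the
user's judgment. Score correlations r_k are computed with the same
transform applied to both the trait and the coordinate block (plain
centering without a tree, GLS whitening with one), so r_k is a correlation
in a single consistent inner-product space; for a star tree the two
choices coincide.

**Permutation tests.** Cross-block association is tested by permuting rows
of the (whitened) second block; both d_1 and |r_1| are available as test
statistics since the convention differs between studies. p = (#{permuted ≥
observed} + 1)/(n_perm + 1); when n! ≤ n_perm all permutations are
enumerated and the p-value is exact. Permuting after the GLS transform
preserves exchangeability of the whitened residuals.

**Isolation by distance.** Geographic distances are great-circle
(haversine) on a sphere of radius 6371.0088 km — the spherical error
(< 0.5%) is immaterial for permutation inference on distances — and
phenotypic distances are Euclidean (raw or log measurements). The Mantel
statistic is the Pearson correlation of upper-triangle entries; the null
permutes rows and columns of one matrix jointly; the p-value is one-sided
for positive association, since isolation by distance is a directional
hypothesis. Specimens sharing a locality keep distance 0 (no jitter).

**EM imputation.** Missing measurements (specimen damage) are completed
under a multivariate normal model: the E-step replaces each row's missing
cells by their conditional expectation given the row's observed cells and
accumulates the conditional-covariance correction; the M-step re-estimates
mean and covariance by maximum likelihood (denominator n) from the
completed data plus corrections. Iteration stops when the largest absolute
change in any imputed value falls below tol = 1e-6 (max_iter = 100;
non-convergence is reported, not raised). Because within-species samples
often have more traits than specimens, a ridge of 1e-6 × mean diagonal is
added to the covariance whenever p ≥ n or the matrix is numerically rank
deficient. Observed cells are never altered. Imputation is intended for
sex-centered within-species data; between-species means require complete
sex-trait cells instead.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure at the scale of the motivating study
system (a 12-species primate clade by default):

- **Tree:** pure-birth (Yule) process, depth normalized to 1 — the
  simplest ultrametric stand-in for a time-calibrated molecular phylogeny.
- **Species blocks:** one matrix-normal draw with row covariance C (from
  the tree) and column covariance Σ, where Σ_XX = σ²I, Σ_YY = σ²I and
  Σ_XY = c·u*v*ᵀ plants a rank-1 morphology–environment coupling
  (PSD iff c ≤ σ²; the error message states the bound). Sampling goes
  through Cholesky factors of C and Σ — exact under Brownian motion.
- **Specimens:** species mean + additive sex effect (males) + linear cline
  β·(lat, lon) along a designated trait direction + isotropic individual
  noise, all composed on the log scale and stored as exp() values, so the
  table carries strictly positive mm-like measurements while the analyses'
  log transform recovers exact additivity. Localities are uniform in a
  Southeast-Asian-like bounding box (lat −15…35, lon 70…130). Default
  individual noise SD is 0.1 log units (≈ 10% of a measurement) and
  missingness is 5% — typical of museum series. Missingness is MCAR only,
  matching EM's ignorability assumption (MAR/MNAR are out of scope).
- **Isolation by distance:** a Gaussian random field over localities with
  exponential covariance exp(−d/1500 km) in geodesic distance, scaled by
  `ibd_strength`, added to independent noise of SD 1. The "strong effect"
  used in power experiments sets the field SD to twice the noise SD.

What passing these tests shows is that each estimator recovers exactly the
structure its model assumes, at realistic sizes. What they cannot show:
robustness to non-Brownian evolution, measurement error, non-MCAR
missingness, unmodeled spatial sampling bias, or correlated environmental
noise — real museum data may violate any of these.

## Validation experiments and problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance tests
run the same experiments through `ecomorph.validation`:

- SVD maximality against 10,000 random unit loading pairs (PLS, 6×3 vs 6×2
  blocks) and 10,000 random unit directions (RRR, n=11, p=5).
- Star-phylogeny equivalence across all PLS/RRR outputs at n=10.
- Planted-coupling recovery at n=32 species, p=6, q=4, c=0.9σ², 200
  replicates, analysed with the matched phylogenetic correction. At these
  conditions the task is genuinely near the information limit: the largest
  noise singular value of a p×q sample cross-covariance, ≈ σ²(√p+√q)/√n ≈
  0.79, is comparable to the planted signal 0.9, so the median |cos(u_1,
  u*)| concentrates near 0.89–0.90 and varies by ±0.01 across seed
  batches. The imbalanced-tree comparison (32-tip ladder tree) shows the
  value of the correction: corrected recovery ≈ 0.90 vs ≈ 0.74 for the
  ordinary analysis on the same data.
- Cline recovery from specimens with β = (0.3, 0.1) log-units per degree
  at individual SD 0.1 (200 replicates; noise-free slope equals ‖β‖ to
  machine precision).
- Permutation calibration with 500 null replicates at 199 permutations
  each (n=16 blocks for PLS; m=12 localities for Mantel), and Mantel power
  under strong planted IBD at m=40 with 200 replicates. These sizes keep
  each experiment in seconds while leaving the binomial error on a
  rejection rate near 0.05 at about ±0.01.
- EM-vs-mean imputation on 200 MVN replicates (n=200, p=5, equicorrelation
  0.8, 10% MCAR; rows that would lose every cell keep one observed cell,
  respecting EM's precondition).

## Design choices where the design was open

- Sex centering outputs deviations (value − mean) rather than
  (mean − value); the two differ only in sign, which no downstream
  covariance or SVD analysis can see.
- Species means average sex means on the log scale (log first, then means)
  since all between-species analyses are log-scale.
- The canonical species order is the pruned tree's deterministic
  post-order tip sequence, making every downstream matrix reproducible.
- Results serialize to JSON at full double precision; round-trips are
  bit-stable, which the suite asserts.
- The within-species permutation test exposes both d_1 and |r_1|
  statistics; neither is privileged.

## Known limitations

Brownian motion only; no measurement-error model; no raster/climate
extraction (environmental values are consumed as tables); no map
projection; single-tree inference (no uncertainty over the phylogeny);
EM assumes multivariate normality of within-species deviations.
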