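# ecomorph

Multivariate ecogeographic analysis of craniodental morphometrics, for
comparative biologists asking how climate, habitat, and geography shape
morphology across a clade — and how much of that association is mediated
by shared phylogenetic history. The pipeline was designed around the
classic study system of macaque craniodental evolution (linear measurements
in mm from museum specimens, species-level climate/ecology tables, a
time-calibrated molecular phylogeny), but every stage is generic.

## Methods at the core

- **Two-block partial least squares (2B-PLS).** For an environment block
  Y (n×q, unit-variance scaled) and a log-scale morphology block X (n×p,
  centered but not rescaled), the SVD of the cross-covariance
  R = X̃ᵀỸ/(n−1) = U D Vᵀ yields paired unit loading vectors (u_k, v_k)
  whose latent-variable scores have successively maximal covariance d_k.
  The fraction d_k²/Σd_i² is the share of squared covariance on dimension
  k; r_k is the correlation of paired scores.
- **Phylogenetic correction.** Under Brownian motion on a tree with branch
  lengths proportional to time, species covary as C[i,j] = shared
  root-to-MRCA path length. GLS-whitening both blocks by the Cholesky
  factor of C (X̃ = L⁻¹(X − 1âᵀ), â the GLS root state) turns every
  phylogenetic cross-product into an ordinary one; with an equal-branch
  star phylogeny the corrected and ordinary analyses coincide exactly.
- **Reduced-rank regression (RRR) for spatial clines.** Each trait is
  regressed on latitude and longitude; the SVD of the p×2 coefficient
  matrix B = U D Wᵀ gives the steepest multivariate clines: d_k are
  maximal slopes (trait log-units per degree), w_k unit geographic
  directions, u_k morphological loadings. Unlike 2B-PLS on (X, coordinates),
  the answer is not dragged toward the long axis of the sampled range.
- **Mantel tests of isolation by distance.** Pearson correlation of
  great-circle (haversine, R = 6371.0088 km) and Euclidean phenotypic
  distance matrices, with a one-sided permutation null (default 10,000
  permutations).
- **Preprocessing.** Natural-log transform; species means as the arithmetic
  mean of female and male means; within-species sex removal by
  (species, sex) centering; EM imputation of missing measurements under a
  multivariate-normal model with ridge regularization.
- **Synthetic data with planted truth.** Yule trees (depth 1), matrix-normal
  Brownian motion with a planted rank-1 cross-block covariance
  Σ_XY = c·u*v*ᵀ, specimen tables with sex effects, linear clines and MCAR
  missingness, and Gaussian-random-field isolation-by-distance structure —
  so every estimator can be checked against known ground truth.

## Worked example

```python
import numpy as np
import ecomorph as em

# a 12-species clade with planted morphology–environment coupling
cfg = em.SimConfig(n_species=12, p=6, q=4, coupling_strength=0.9, seed=3)
tree = em.simulate_yule_tree(cfg.n_species, cfg.seed)
Sigma = em.build_joint_covariance(cfg)
X, Y = em.simulate_species_traits_bm(tree, Sigma, seed=5, p=cfg.p)

C = em.tree_to_covariance(tree)
res = em.fit_2bpls(X, em.scale_unit_variance(Y), C)
print(np.round(100 * res.effect, 1), np.round(res.r, 2))
```

prints

```
[54.  26.5 17.3  2.2] [0.67 0.72 0.7  0.25]
```

— after phylogenetic correction, latent-variable pair 1 carries 54% of
the squared covariance between blocks and its paired scores correlate at
0.67; the remaining pairs carry successively less, as expected when a
single planted axis couples the blocks. The same session's spatial run,

```python
G = np.random.default_rng(0).uniform(-10, 10, (12, 2))
rr = em.fit_rrr(X, G, C)
print(np.round(rr.d, 3))
```

prints `[0.053 0.044]`: maximal cline slopes in trait log-units per degree
along the two orthogonal geographic gradient directions (small here, since
no cline was planted).

A `typer` CLI mirrors the library (`ecomorph simulate|preprocess-cmd|pls|rrr|mantel`,
each driven by a YAML config plus `--seed`).

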