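"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the three inputs of an ecogeographic morphometric
study: a time-scaled phylogeny (pure-birth tree, depth normalized to 1),
species-mean trait blocks evolving under Brownian motion with an optional
planted rank-1 cross-block covariance between a "morphology" and an
"environment" block, and specimen-level tables (species mean + additive sex
effect + individual noise + optional linear spatial cline), with MCAR
missingness. A separate helper plants isolation-by-distance structure as a
Gaussian random field over localities with exponential covariance in
geodesic distance. Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import PhyloTree, SpecimenTable, ValidationError
from .phylo import tree_to_covariance


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the motivating study system: a macaque-like
    clade of 12 species, a handful of log-scale craniodental traits coupled
    to a few climate variables, several specimens of both sexes per species
    from localities in a Southeast-Asian-like bounding box, and mild MCAR
    missingness from specimen damage.
    """

    n_species: int = 12
    p: int = 6
    q: int = 4
    coupling_rank: int = 1
    coupling_strength: float = 0.9   # c, in units of bm_rate
    coupling_u: np.ndarray | None = None   # unit p-vector u*
    coupling_v: np.ndarray | None = None   # unit q-vector v*
    bm_rate: float = 1.0             # σ², per unit tree depth
    specimens_per_species: int = 6
    sex_effect: np.ndarray | None = None   # additive male-minus-female shift
    individual_sd: float = 0.1
    missing_rate: float = 0.05
    cline_slope: tuple[float, float] = (0.0, 0.0)  # β per degree (lat, lon)
    cline_direction: np.ndarray | None = None      # unit trait direction
    ibd_strength: float = 0.0
    bbox: tuple[float, float, float, float] = (-15.0, 35.0, 70.0, 130.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValidationError("n_species must be >= 3")
        if self.coupling_rank not in (0, 1):
            raise ValidationError("coupling_rank must be 0 or 1")
        for name in ("coupling_strength", "bm_rate", "individual_sd",
                     "ibd_strength"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.coupling_u is None:
            self.coupling_u = np.ones(self.p) / np.sqrt(self.p)
        if self.coupling_v is None:
            self.coupling_v = np.ones(self.q) / np.sqrt(self.q)
        self.coupling_u = np.asarray(self.coupling_u, dtype=float)
        self.coupling_v = np.asarray(self.coupling_v, dtype=float)
        if self.coupling_rank == 1:
            for vec, dim, nm in ((self.coupling_u, self.p, "u*"),
                                 (self.coupling_v, self.q, "v*")):
                if vec.shape != (dim,):
                    raise ValidationError(f"{nm} has wrong dimension")
                if abs(np.linalg.norm(vec) - 1) > 1e-8:
                    raise ValidationError(f"{nm} must have unit norm")
        if self.sex_effect is None:
            self.sex_effect = np.zeros(self.p)
        self.sex_effect = np.asarray(self.sex_effect, dtype=float)
        if self.cline_direction is None:
            self.cline_direction = self.coupling_u
        self.cline_direction = np.asarray(self.cline_direction, dtype=float)


def simulate_yule_tree(n_tips: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree, ultrametric, total depth normalized to 1.

    Lineages split at rate 1 per lineage; after the (n−1)-th split the
    process runs one more exponential waiting time so tips do not end at a
    split. All root-to-tip path lengths are exactly equal.
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root._birth = 0.0
    kids = [dendropy.Node(), dendropy.Node()]
    for k in kids:
        root.add_child(k)
    active = list(kids)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node._birth = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, leaf in enumerate(active):
        leaf._birth = t_end
    # assign edge lengths (normalized) and tip labels in traversal order
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        node.edge.length = (node._birth - node.parent_node._birth) / t_end
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    return PhyloTree(tree)


def build_joint_covariance(cfg: SimConfig) -> np.ndarray:
    """Joint (p+q)×(p+q) trait covariance with planted cross-block coupling.

    Σ_XX = σ²I_p, Σ_YY = σ²I_q, Σ_XY = c·u*v*ᵀ (zero if coupling_rank=0).
    The matrix is positive semidefinite iff c ≤ σ².
    """
    p, q = cfg.p, cfg.q
    s2 = cfg.bm_rate
    c = cfg.coupling_strength * s2 if cfg.coupling_rank == 1 else 0.0
    if c > s2 + 1e-12:
        raise ValidationError(
            f"coupling c={c:g} makes the joint covariance non-PSD; "
            f"maximal admissible c is {s2:g} (= bm_rate)"
        )
    S = np.zeros((p + q, p + q))
    S[:p, :p] = s2 * np.eye(p)
    S[p:, p:] = s2 * np.eye(q)
    if c > 0:
        S[:p, p:] = c * np.outer(cfg.coupling_u, cfg.coupling_v)
        S[p:, :p] = S[:p, p:].T
    w = np.linalg.eigvalsh(S)
    if w.min() < -1e-9 * max(1.0, w.max()):
        raise ValidationError("joint covariance failed the PSD check")
    return S


def simulate_species_traits_bm(
    tree: PhyloTree,
    Sigma: np.ndarray,
    seed: int,
    p: int | None = None,
) -> tuple[np.ndarray, np.ndarray] | np.ndarray:
    """Species trait values under Brownian motion on the tree.

    Draws one matrix-normal sample with row covariance C (the BM tree
    covariance) and column covariance ``Sigma``, via Cholesky factors of
    both (with tiny diagonal jitter when a factor is semidefinite). The
    root state is 0. If ``p`` is given the columns are split into a
    morphology block X (first p) and an environment block Y (rest).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    C = tree_to_covariance(tree).C
    n, m = C.shape[0], Sigma.shape[0]
    if n < 3:
        raise ValidationError("tree must have >= 3 tips")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, m))
    Lc = _psd_cholesky(C)
    Ls = _psd_cholesky(Sigma)
    M = Lc @ Z @ Ls.T
    if p is None:
        return M
    if not 0 < p < m + 1:
        raise ValidationError("block dimension p out of range")
    return M[:, :p], M[:, p:]


def _psd_cholesky(A: np.ndarray) -> np.ndarray:
    if np.allclose(A, 0):
        return np.zeros_like(A)
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(1.0, np.trace(A) / A.shape[0])
        return np.linalg.cholesky(A + jitter * np.eye(A.shape[0]))


def simulate_specimens(
    species_means: np.ndarray,
    cfg: SimConfig,
    species: list[str] | None = None,
) -> SpecimenTable:
    """Specimen-level table from species means.

    ``species_means`` and all effects live on the natural-log scale (the
    scale Brownian motion simulates and all analyses use); stored
    measurements are their exponentials, i.e. strictly positive mm values
    as in a real museum table. Each specimen is its species mean, plus the
    additive sex effect for males, plus a linear cline contribution
    β·(lat, lon) along the configured trait direction, plus isotropic
    Gaussian individual noise — all additive on the log scale. Localities
    are uniform in the bounding box; sexes alternate so both are
    represented in every species. Cells are then deleted completely at
    random at ``missing_rate``.
    """
    if cfg.specimens_per_species < 1:
        raise ValidationError("specimens_per_species must be >= 1")
    mu = np.asarray(species_means, dtype=float)
    n_sp, p = mu.shape
    if species is None:
        species = [f"t{i + 1}" for i in range(n_sp)]
    rng = np.random.default_rng(cfg.seed)
    lat0, lat1, lon0, lon1 = cfg.bbox
    rows = []
    values = []
    k = cfg.specimens_per_species
    beta = np.asarray(cfg.cline_slope, dtype=float)
    for s in range(n_sp):
        for j in range(k):
            sex = "male" if j % 2 == 0 else "female"
            lat = rng.uniform(lat0, lat1)
            lon = rng.uniform(lon0, lon1)
            val = mu[s].copy()
            if sex == "male":
                val = val + cfg.sex_effect
            val = val + (beta[0] * lat + beta[1] * lon) * cfg.cline_direction
            val = val + rng.normal(0.0, cfg.individual_sd, size=p)
            rows.append(
                dict(
                    specimen_id=f"{species[s]}_{j + 1}",
                    species=species[s],
                    sex=sex,
                    age_class="adult",
                    provenance="wild",
                    latitude=lat,
                    longitude=lon,
                )
            )
            values.append(val)
    V = np.exp(np.array(values))
    if cfg.missing_rate > 0:
        mask = rng.random(V.shape) < cfg.missing_rate
        V[mask] = np.nan
    trait_names = [f"m{i + 1}" for i in range(p)]
    df = pd.DataFrame(rows)
    df[trait_names] = V
    return SpecimenTable(df, trait_names)


def simulate_ibd_field(
    m: int,
    p: int,
    ibd_strength: float,
    seed: int,
    bbox: tuple[float, float, float, float] = (-15.0, 35.0, 70.0, 130.0),
    range_km: float = 1500.0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Localities plus traits with planted isolation-by-distance structure.

    Phenotypic drift is simulated as a Gaussian random field over localities
    with exponential covariance exp(−d/range_km) in geodesic distance,
    scaled by ``ibd_strength``, plus independent noise of SD ``noise_sd``.
    ibd_strength=0 yields spatially unstructured traits (the null).

    Returns (coords m×2, traits m×p).
    """
    from .mantel_ibd import geodesic_distance_matrix

    rng = np.random.default_rng(seed)
    lat0, lat1, lon0, lon1 = bbox
    coords = np.column_stack(
        [rng.uniform(lat0, lat1, m), rng.uniform(lon0, lon1, m)]
    )
    X = rng.normal(0.0, noise_sd, size=(m, p))
    if ibd_strength > 0:
        D = geodesic_distance_matrix(coords)
        K = (ibd_strength ** 2) * np.exp(-D / range_km)
        L = _psd_cholesky(K + 1e-10 * np.eye(m))
        X = X + L @ rng.standard_normal((m, p))
    return coords, X
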