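"""Multivariate spatial clines by reduced-rank regression.

Each trait is regressed on latitude and longitude (with intercept), by OLS
or by PGLS under a Brownian-motion tree covariance. The SVD of the
resulting p×2 matrix B of partial regression coefficients, B = U D Wᵀ,
yields the directions of steepest multivariate cline: the singular values
are the maximal slopes of the fitted trait surface over geography (trait
log-units per degree), the left singular vectors are morphological
loadings, and the right singular vectors are unit geographic gradient
directions. Unlike 2B-PLS on (traits, coordinates) — which chases the
direction of largest geographic spread of the sampled localities — this
maximizes the regression slope, so an elongated habitat range does not
dominate the answer.

Coordinates are used in raw decimal degrees, with no map projection and no
standardization, so slopes remain interpretable per degree.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np

from .core_io import RrrResult, ValidationError
from .phylo import PhyloCov, _chol_with_jitter
from scipy.linalg import solve_triangular


def _design(G: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(G.shape[0]), G])


def _whiten_pair(
    X: np.ndarray, G: np.ndarray, C: PhyloCov | np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (X*, Z*) with the GLS transform applied (Z includes intercept)."""
    Z = _design(G)
    if C is None:
        return X, Z
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    L = _chol_with_jitter(Cm)
    return (
        solve_triangular(L, X, lower=True),
        solve_triangular(L, Z, lower=True),
    )


def pgls_coefficients(
    X: np.ndarray,
    G: np.ndarray,
    C: PhyloCov | np.ndarray | None = None,
) -> np.ndarray:
    """p×2 matrix of partial regression coefficients on (latitude, longitude).

    Each trait is fitted as intercept + latitude + longitude, by OLS when
    ``C`` is None and by GLS with weight C⁻¹ otherwise (identical results
    for C = I). Row k holds (∂trait_k/∂lat, ∂trait_k/∂lon).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < 4:
        raise ValidationError("need n >= 4 for a 3-parameter fit")
    if X.shape[0] != n:
        raise ValidationError("X and G row counts differ")
    Xs, Zs = _whiten_pair(X, G, C)
    # rank check on the (lat, lon) part: collinear coordinates are useless
    if np.linalg.matrix_rank(Zs - Zs.mean(axis=0, keepdims=True)) < 2:
        raise ValidationError("latitude and longitude are collinear")
    ZtZ = Zs.T @ Zs
    try:
        coefs = np.linalg.solve(ZtZ, Zs.T @ Xs)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular normal equations") from exc
    return coefs[1:, :].T  # drop intercept; rows = traits


def fit_rrr(
    X: np.ndarray,
    G: np.ndarray,
    C: PhyloCov | np.ndarray | None = None,
) -> RrrResult:
    """Reduced-rank regression of the trait block on geography.

    SVD of B = pgls_coefficients(X, G, C) gives the two cline dimensions.
    For any unit trait combination u, the fitted-surface gradient norm
    ‖Bᵀu‖ is at most d_1, attained at u_1. Scores are projections of the
    centered (or GLS-whitened, in the phylogenetic case) blocks onto the
    corresponding loadings; r_k is the correlation of paired scores and
    effect_k = d_k²/(d_1²+d_2²).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    G = np.asarray(G, dtype=float)
    B = pgls_coefficients(X, G, C)
    K = min(B.shape[0], 2)
    if np.allclose(B, 0):
        warnings.warn("zero coefficient matrix; loadings set to canonical basis")
        p = B.shape[0]
        u = np.eye(p)[:, :K]
        w = np.eye(2)[:, :K]
        d = np.zeros(K)
    else:
        U, s, Wt = np.linalg.svd(B, full_matrices=False)
        u, w, d = U[:, :K], Wt.T[:, :K], s[:K]
        for k in range(u.shape[1]):
            j = int(np.argmax(np.abs(u[:, k])))
            if u[j, k] < 0:
                u[:, k] = -u[:, k]
                w[:, k] = -w[:, k]
    # score space: same transform for both blocks so r_k is a correlation
    # in one consistent inner product (centering when C is None, GLS
    # whitening otherwise; identical for a star tree)
    if C is None:
        Xs = X - X.mean(axis=0, keepdims=True)
        Gs = G - G.mean(axis=0, keepdims=True)
    else:
        from .phylo import gls_whiten

        Xs = gls_whiten(X, C)
        Gs = gls_whiten(G, C)
    sx = Xs @ u
    sg = Gs @ w
    r = np.array(
        [
            0.0 if sx[:, k].std() == 0 or sg[:, k].std() == 0
            else float(np.corrcoef(sx[:, k], sg[:, k])[0, 1])
            for k in range(K)
        ]
    )
    tot = float(d @ d)
    effect = d**2 / tot if tot > 0 else np.full(K, np.nan)
    return RrrResult(
        B=B, d=d, u=u, w=w, scores_x=sx, scores_g=sg, r=r, effect=effect,
        phylogenetic=C is not None,
    )


def rrr_permutation_test(
    X: np.ndarray,
    G: np.ndarray,
    C: PhyloCov | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    statistic: str = "d1",
) -> float:
    """Permutation p-value for the leading cline.

    Rows of the (whitened) geographic block are permuted against the trait
    block; the statistic is d_1 or |r_1|. Mirrors the PLS permutation
    scheme, including exact enumeration when n! ≤ n_perm.
    """
    if statistic not in ("d1", "r1"):
        raise ValidationError("statistic must be 'd1' or 'r1'")
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    n = G.shape[0]

    def stat(perm: np.ndarray | None) -> float:
        Gp = G if perm is None else G[perm]
        res = fit_rrr(X, Gp, C)
        return float(res.d[0]) if statistic == "d1" else abs(float(res.r[0]))

    obs = stat(None)
    if math.factorial(n) <= n_perm:
        warnings.warn("small n; using exact enumeration")
        vals = [stat(np.array(pm)) for pm in permutations(range(n))]
        return float(np.mean(np.asarray(vals) >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    count = sum(stat(rng.permutation(n)) >= obs for _ in range(n_perm))
    return (count + 1) / (n_perm + 1)
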