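"""Two-block partial least squares, ordinary and phylogenetic.

2B-PLS decomposes the cross-covariance matrix between two variable blocks
(here: environment and morphology) into successive pairs of unit axes with
maximal score covariance, via the SVD R = U D Vᵀ of R = X̃ᵀỸ/(n−1). The
singular values d_k are the score covariances; d_k²/Σd_i² is the fraction
of squared covariance carried by latent-variable pair k. The phylogenetic
variant first GLS-whitens both blocks by the Brownian-motion tree
covariance, after which the ordinary algebra applies unchanged; with an
equal-branch star phylogeny the two variants coincide exactly.

Convention: the morphological block is centered but not rescaled (so an
allometric size factor survives in LV 1); only the environmental block is
scaled to unit variance, upstream in preprocessing.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np

from .core_io import PlsResult, ValidationError
from .phylo import PhyloCov, gls_whiten


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def _prepare(X: np.ndarray, C: PhyloCov | np.ndarray | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if C is None:
        return _center(X)
    return gls_whiten(X, C)


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each u_k so its largest-|loading| entry is positive; v follows."""
    for k in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_2bpls(
    X: np.ndarray,
    Y: np.ndarray,
    C: PhyloCov | np.ndarray | None = None,
) -> PlsResult:
    """Fit two-block PLS between blocks X (n×p) and Y (n×q).

    With ``C`` given, both blocks are GLS-whitened first (phylogenetic
    2B-PLS); raw-centered score projections are then also reported for
    plotting alongside the whitened scores used for r_k. Extracts
    K = min(p, q, n−1) dimensions. The covariance of the paired LV-1 scores
    equals d_1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValidationError("X and Y must have the same number of rows")
    if C is not None:
        Cn = C.n if isinstance(C, PhyloCov) else C.shape[0]
        if Cn != n:
            raise ValidationError("phylogenetic covariance order mismatch")
    if n < 3:
        raise ValidationError("need n >= 3")
    Xt = _prepare(X, C)
    Yt = _prepare(Y, C)
    R = Xt.T @ Yt / (n - 1)
    K = min(p, q, n - 1)
    if np.allclose(R, 0):
        warnings.warn("zero cross-covariance; loadings set to canonical basis")
        u = np.eye(p)[:, :K]
        v = np.eye(q)[:, :K]
        d = np.zeros(K)
    else:
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        u, v, d = U[:, :K], Vt.T[:, :K], s[:K]
        u, v = _fix_signs(u, v)
    sx = Xt @ u
    sy = Yt @ v
    r = np.array([_safe_corr(sx[:, k], sy[:, k]) for k in range(K)])
    tot = float(d @ d)
    effect = d**2 / tot if tot > 0 else np.full(K, np.nan)
    res = PlsResult(
        u=u, v=v, d=d, scores_x=sx, scores_y=sy, r=r, effect=effect,
        phylogenetic=C is not None,
    )
    if C is not None:
        res.scores_x_raw = _center(X) @ u
        res.scores_y_raw = _center(Y) @ v
    return res


def pls_effect_sizes(result: PlsResult) -> np.ndarray:
    """Fractions d_k²/Σd_i² of squared covariance per dimension (sum to 1)."""
    tot = float(result.d @ result.d)
    if tot == 0:
        raise ValidationError("all singular values are zero; effects undefined")
    return result.d**2 / tot


def _pls_stat(Xt: np.ndarray, Yt: np.ndarray, statistic: str) -> float:
    R = Xt.T @ Yt / (Xt.shape[0] - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    if statistic == "d1":
        return float(s[0])
    sx = Xt @ U[:, 0]
    sy = Yt @ Vt[0, :]
    return abs(_safe_corr(sx, sy))


def pls_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    C: PhyloCov | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    statistic: str = "d1",
) -> float:
    """Permutation p-value for cross-block association.

    Rows of the (whitened, if phylogenetic) Y block are permuted uniformly
    at random; permuting after the GLS transform preserves the
    exchangeability argument. p = (#{permuted ≥ observed} + 1)/(n_perm + 1).
    When n! ≤ n_perm all n! permutations are enumerated instead and the
    p-value is the exact fraction.
    """
    if statistic not in ("d1", "r1"):
        raise ValidationError("statistic must be 'd1' or 'r1'")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    Xt = _prepare(np.asarray(X, float), C)
    Yt = _prepare(np.asarray(Y, float), C)
    n = Xt.shape[0]
    obs = _pls_stat(Xt, Yt, statistic)
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"n={n} too small for {n_perm} distinct permutations; "
            "using exact enumeration"
        )
        stats = [
            _pls_stat(Xt, Yt[list(perm)], statistic)
            for perm in permutations(range(n))
        ]
        return float(np.mean(np.asarray(stats) >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pls_stat(Xt, Yt[perm], statistic) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
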