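"""Brownian-motion covariance from a time-scaled tree and GLS machinery.

Under a Brownian-motion model of trait evolution on a rooted tree with
branch lengths proportional to time, the between-species covariance of any
trait is proportional to the matrix C with C[i,j] = shared path length from
the root to the most recent common ancestor of tips i and j (and diagonal
equal to root-to-tip depth). Whitening data by the inverse Cholesky factor
of C turns every phylogenetic (PGLS) cross-product into an ordinary one,
which is how the phylogenetic variants of two-block PLS and reduced-rank
regression are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .core_io import PhyloTree, ValidationError


@dataclass
class PhyloCov:
    """Species-by-species Brownian-motion covariance matrix."""

    C: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        n = len(self.species)
        if C.shape != (n, n):
            raise ValidationError("C shape does not match species list")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValidationError("C must be symmetric")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValidationError("C must be positive semidefinite")
        self.C = C

    @property
    def n(self) -> int:
        return len(self.species)


def tree_to_covariance(
    tree: PhyloTree, species_order: Sequence[str] | None = None
) -> PhyloCov:
    """Brownian-motion covariance C from a time-scaled tree.

    C[i,j] is the summed branch length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip depths.
    Rows/columns follow ``species_order`` (default: canonical tip order).
    """
    order = list(species_order) if species_order is not None else tree.tip_labels
    missing = set(order) - set(tree.tip_labels)
    if missing:
        raise ValidationError(f"species not in tree: {sorted(missing)}")
    t = tree.tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    # leaf sets per node via one post-order sweep; C[i,j] = depth of MRCA,
    # assigned from the deepest node containing both tips
    idx = {lab: k for k, lab in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))
    for node in t.postorder_node_iter():
        if node.is_leaf():
            node._tip_idx = (
                [idx[node.taxon.label]] if node.taxon.label in idx else []
            )
            if node.taxon.label in idx:
                C[node._tip_idx[0], node._tip_idx[0]] = node.root_distance
            continue
        kids = node.child_nodes()
        merged: list[int] = []
        depth = node.root_distance or 0.0
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]._tip_idx:
                    for j in kids[b]._tip_idx:
                        C[i, j] = C[j, i] = depth
        for k in kids:
            merged.extend(k._tip_idx)
            del k._tip_idx
        node._tip_idx = merged
    del t.seed_node._tip_idx
    return PhyloCov(C, order)


def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, adding diagonal jitter 1e-10·trace(C)/n if needed."""
    try:
        return cholesky(C, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    jitter = 1e-10 * np.trace(C) / C.shape[0]
    try:
        return cholesky(C + jitter * np.eye(C.shape[0]), lower=True)
    except Exception as exc:
        raise ValidationError("phylogenetic covariance is singular") from exc


def phylogenetic_mean(X: np.ndarray, C: PhyloCov | np.ndarray) -> np.ndarray:
    """GLS estimate of the root state: a = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹X.

    Reduces to the arithmetic column mean for C proportional to I.
    """
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Cm.shape[0]:
        X = X.T
    L = _chol_with_jitter(Cm)
    ones = np.ones((Cm.shape[0], 1))
    Ci1 = cho_solve((L, True), ones)
    CiX = cho_solve((L, True), X)
    return (ones.T @ CiX).ravel() / float((ones.T @ Ci1).item())


def gls_whiten(X: np.ndarray, C: PhyloCov | np.ndarray) -> np.ndarray:
    """GLS-whiten: X̃ = L⁻¹(X − 1aᵀ) with LLᵀ = C, a the phylogenetic mean.

    Ordinary cross-products of whitened blocks equal the GLS cross-products
    of the raw blocks, so downstream SVD-based analyses need no further
    phylogenetic bookkeeping.
    """
    Cm = C.C if isinstance(C, PhyloCov) else np.asarray(C, dtype=float)
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X.T).T if squeeze else X
    a = phylogenetic_mean(X, Cm)
    L = _chol_with_jitter(Cm)
    Xt = solve_triangular(L, X - a[None, :], lower=True)
    return Xt.ravel() if squeeze else Xt


def star_covariance(labels: Sequence[str], depth: float = 1.0) -> PhyloCov:
    """Covariance of an equal-branch star phylogeny: depth·I.

    Under this C every phylogenetic operation coincides with its ordinary
    counterpart — the master equivalence used throughout the test suite.
    """
    n = len(labels)
    return PhyloCov(depth * np.eye(n), list(labels))
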