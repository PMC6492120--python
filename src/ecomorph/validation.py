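"""End-to-end validation experiments on synthetic data.

Each function runs one self-contained experiment — planted-signal
recovery, permutation-test calibration, imputation accuracy, SVD
maximality — at a fixed problem size, returning the measured quantity.
They are used both by the test suite and by the reproduction script, so
the numbers a reader sees are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from . import (
    SimConfig,
    build_joint_covariance,
    em_impute,
    fit_2bpls,
    fit_rrr,
    geodesic_distance_matrix,
    mantel_test,
    phenotype_distance_matrix,
    pls_permutation_test,
    simulate_ibd_field,
    simulate_species_traits_bm,
    simulate_specimens,
    simulate_yule_tree,
    tree_to_covariance,
)


def pls_maximality_gap(seed: int, n_pairs: int = 10_000) -> dict:
    """d_1 minus the best score covariance over random unit loading pairs
    (nonnegative iff the SVD attains the maximum), plus the deviation of the
    returned pair from d_1 (≈ 0)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((6, 3))
    Y = rng.standard_normal((6, 2))
    res = fit_2bpls(X, Y)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = X.shape[0]
    U = rng.standard_normal((n_pairs, 3))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    V = rng.standard_normal((n_pairs, 2))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    covs = np.abs(np.einsum("ki,ik->k", U @ Xc.T, Yc @ V.T)) / (n - 1)
    attained = abs((Xc @ res.u[:, 0]) @ (Yc @ res.v[:, 0])) / (n - 1)
    return {
        "gap": float(res.d[0] - covs.max()),
        "attained_dev": float(abs(attained - res.d[0])),
        "n": n_pairs,
    }


def rrr_maximality_gap(seed: int, n_dirs: int = 10_000) -> dict:
    """d_1 minus max ‖Bᵀu‖ over random unit u, and |‖Bᵀu_1‖ − d_1|."""
    rng = np.random.default_rng(seed)
    n, p = 11, 5
    G = np.column_stack([rng.uniform(-10, 10, n), rng.uniform(-10, 10, n)])
    X = G @ rng.standard_normal((2, p)) + 0.3 * rng.standard_normal((n, p))
    res = fit_rrr(X, G)
    U = rng.standard_normal((n_dirs, p))
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    norms = np.linalg.norm(U @ res.B, axis=1)
    return {
        "gap": float(res.d[0] - norms.max()),
        "attained_dev": float(
            abs(np.linalg.norm(res.B.T @ res.u[:, 0]) - res.d[0])
        ),
        "n": n_dirs,
    }


def star_tree_equivalence(seed: int) -> dict:
    """Max absolute difference between phylogenetic and ordinary fits under
    an equal-branch star phylogeny, across all PLS and RRR outputs."""
    from .phylo import star_covariance

    rng = np.random.default_rng(seed)
    n = 10
    X = rng.standard_normal((n, 4))
    Y = rng.standard_normal((n, 3))
    G = np.column_stack([rng.uniform(-10, 10, n), rng.uniform(-10, 10, n)])
    star = star_covariance([f"s{i}" for i in range(n)])
    po, pp = fit_2bpls(X, Y), fit_2bpls(X, Y, star)
    ro, rp = fit_rrr(X, G), fit_rrr(X, G, star)
    diffs = [
        np.abs(po.d - pp.d).max(),
        np.abs(po.u - pp.u).max(),
        np.abs(po.v - pp.v).max(),
        np.abs(po.scores_x - pp.scores_x).max(),
        np.abs(po.scores_y - pp.scores_y).max(),
        np.abs(po.r - pp.r).max(),
        np.abs(po.effect - pp.effect).max(),
        np.abs(ro.B - rp.B).max(),
        np.abs(ro.d - rp.d).max(),
        np.abs(ro.u - rp.u).max(),
        np.abs(ro.w - rp.w).max(),
        np.abs(ro.scores_x - rp.scores_x).max(),
        np.abs(ro.scores_g - rp.scores_g).max(),
    ]
    return {"max_abs_diff": float(max(diffs)), "n": n}


def pls_planted_recovery(seed: int, n_rep: int = 200) -> dict:
    """Median |cos(u_1, u*)| for planted rank-1 coupling (n=32, p=6, q=4,
    c=0.9σ²) analysed with the matched phylogenetic correction."""
    n, p, q = 32, 6, 4
    cfg = SimConfig(n_species=n, p=p, q=q, coupling_strength=0.9, seed=seed)
    S = build_joint_covariance(cfg)
    u_star = cfg.coupling_u
    coss = []
    for r in range(n_rep):
        tree = simulate_yule_tree(n, seed + r)
        C = tree_to_covariance(tree)
        X, Y = simulate_species_traits_bm(tree, S, seed + 100_000 + r, p=p)
        res = fit_2bpls(X, Y, C)
        coss.append(abs(res.u[:, 0] @ u_star))
    return {"median_abs_cos": float(np.median(coss)), "n": n_rep}


def pls_recovery_imbalanced_tree(seed: int, n_rep: int = 200) -> dict:
    """Planted-coupling recovery on a maximally imbalanced (ladder) tree:
    median |cos| for the phylogenetic and the ordinary analysis."""
    n, p, q = 32, 6, 4
    s = np.linspace(0, 1, n)
    core = f"(t{n-1}:{1-s[n-2]:.8f},t{n}:{1-s[n-2]:.8f})"
    for k in range(n - 3, -1, -1):
        core = f"(t{k+1}:{1-s[k]:.8f},{core}:{s[k+1]-s[k]:.8f})"
    from .core_io import parse_newick

    tree = parse_newick(core + ";")
    C = tree_to_covariance(tree)
    cfg = SimConfig(n_species=n, p=p, q=q, coupling_strength=0.9, seed=seed)
    S = build_joint_covariance(cfg)
    u_star = cfg.coupling_u
    cos_p, cos_o = [], []
    for r in range(n_rep):
        X, Y = simulate_species_traits_bm(tree, S, seed + r, p=p)
        cos_p.append(abs(fit_2bpls(X, Y, C).u[:, 0] @ u_star))
        cos_o.append(abs(fit_2bpls(X, Y).u[:, 0] @ u_star))
    return {
        "median_abs_cos_phylo": float(np.median(cos_p)),
        "median_abs_cos_ordinary": float(np.median(cos_o)),
        "n": n_rep,
    }


def rrr_cline_recovery(seed: int, n_rep: int = 200) -> dict:
    """Median |cos| between the leading geographic direction and the planted
    cline β/‖β‖ on noisy specimens, plus the noise-free slope error."""
    beta = np.array([0.3, 0.1])
    bhat = beta / np.linalg.norm(beta)
    coss = []
    for r in range(n_rep):
        cfg = SimConfig(
            n_species=3, p=4, specimens_per_species=10, individual_sd=0.1,
            missing_rate=0.0, cline_slope=tuple(beta),
            cline_direction=np.full(4, 0.5), seed=seed + r,
        )
        t = simulate_specimens(np.zeros((3, 4)), cfg)
        res = fit_rrr(
            np.log(t.measurements.to_numpy()),
            t.data[["latitude", "longitude"]].to_numpy(),
        )
        coss.append(abs(res.w[:, 0] @ bhat))
    cfg0 = SimConfig(
        n_species=3, p=4, specimens_per_species=10, individual_sd=0.0,
        missing_rate=0.0, cline_slope=tuple(beta),
        cline_direction=np.full(4, 0.5), seed=seed,
    )
    t0 = simulate_specimens(np.zeros((3, 4)), cfg0)
    res0 = fit_rrr(
        np.log(t0.measurements.to_numpy()),
        t0.data[["latitude", "longitude"]].to_numpy(),
    )
    return {
        "median_abs_cos": float(np.median(coss)),
        "noise_free_slope_abs_error": float(
            abs(res0.d[0] - np.linalg.norm(beta))
        ),
        "n": n_rep,
    }


def pls_permutation_type1(seed: int, n_rep: int = 500, n_perm: int = 199) -> dict:
    """Rejection rate of the PLS permutation test at α=0.05 on independent
    blocks (nominal: 0.05)."""
    rej = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seed + r)
        X = rng.standard_normal((16, 3))
        Y = rng.standard_normal((16, 2))
        p = pls_permutation_test(X, Y, n_perm=n_perm, seed=seed + 10_000 + r)
        rej += p <= 0.05
    return {"rate": rej / n_rep, "n": n_rep}


def mantel_type1(seed: int, n_rep: int = 500, n_perm: int = 199) -> dict:
    """Rejection rate of the Mantel test at α=0.05 with no spatial signal."""
    rej = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seed + r)
        coords = np.column_stack(
            [rng.uniform(-10, 10, 12), rng.uniform(-10, 10, 12)]
        )
        T = rng.standard_normal((12, 4))
        res = mantel_test(
            geodesic_distance_matrix(coords),
            phenotype_distance_matrix(T),
            n_perm=n_perm,
            seed=seed + 20_000 + r,
        )
        rej += res.p <= 0.05
    return {"rate": rej / n_rep, "n": n_rep}


def mantel_ibd_power(seed: int, n_rep: int = 200, n_perm: int = 199) -> dict:
    """Power of the Mantel test at α=0.05 under strong planted isolation by
    distance (drift-field SD twice the independent noise SD) at m=40."""
    rej = 0
    for r in range(n_rep):
        coords, X = simulate_ibd_field(40, 4, 2.0, seed + r)
        res = mantel_test(
            geodesic_distance_matrix(coords),
            phenotype_distance_matrix(X),
            n_perm=n_perm,
            seed=seed + 30_000 + r,
        )
        rej += res.p <= 0.05
    return {"rate": rej / n_rep, "n": n_rep}


def em_vs_mean_imputation(seed: int, n_rep: int = 200) -> dict:
    """Fraction of MVN replicates (p=5, equicorrelation 0.8, n=200, 10%
    MCAR) where EM imputation beats column-mean imputation on RMSE."""
    S = np.full((5, 5), 0.8)
    np.fill_diagonal(S, 1.0)
    L = np.linalg.cholesky(S)
    wins = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seed + r)
        X = rng.standard_normal((200, 5)) @ L.T
        mask = rng.random(X.shape) < 0.1
        full = mask.all(axis=1)
        for i in np.where(full)[0]:  # keep EM's ≥1-observed precondition
            mask[i, rng.integers(5)] = False
        Xm = X.copy()
        Xm[mask] = np.nan
        rep = em_impute(Xm)
        rmse_em = np.sqrt(np.mean((rep.completed[mask] - X[mask]) ** 2))
        colmean = np.nanmean(Xm, axis=0)
        rmse_mean = np.sqrt(
            np.mean((np.broadcast_to(colmean, X.shape)[mask] - X[mask]) ** 2)
        )
        wins += rmse_em < rmse_mean
    return {"fraction": wins / n_rep, "n": n_rep}
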