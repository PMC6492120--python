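import numpy as np
import pytest

import ecomorph as em
from ecomorph.core_io import ValidationError
from ecomorph.phylo import tree_to_covariance


# ------------------------------------------------------------- Yule trees


def test_yule_two_tips_topology():
    t = em.simulate_yule_tree(2, 0)
    assert t.n_tips == 2
    assert t.is_ultrametric()
    assert list(t.depths().values()) == pytest.approx([1.0, 1.0])


def test_yule_seed_determinism():
    a = em.simulate_yule_tree(12, 42).as_newick()
    b = em.simulate_yule_tree(12, 42).as_newick()
    assert a == b
    c = em.simulate_yule_tree(12, 43).as_newick()
    assert a != c


def test_yule_ultrametric_depth_one():
    t = em.simulate_yule_tree(50, 7)
    d = np.array(list(t.depths().values()))
    assert d.shape == (50,)
    np.testing.assert_allclose(d, 1.0, atol=1e-9)


def test_yule_too_few_tips():
    with pytest.raises(ValidationError):
        em.simulate_yule_tree(1, 0)


# ----------------------------------------------------- joint covariance


def test_joint_covariance_no_coupling_block_diagonal():
    cfg = em.SimConfig(n_species=4, p=3, q=2, coupling_rank=0)
    S = em.build_joint_covariance(cfg)
    np.testing.assert_array_equal(S[:3, 3:], 0.0)
    np.testing.assert_array_equal(S, S.T)


def test_joint_covariance_scalar_blocks():
    cfg = em.SimConfig(
        n_species=3, p=1, q=1, coupling_strength=0.5,
        coupling_u=np.array([1.0]), coupling_v=np.array([1.0]),
    )
    S = em.build_joint_covariance(cfg)
    np.testing.assert_allclose(S, [[1.0, 0.5], [0.5, 1.0]])


def test_joint_covariance_max_coupling_is_singular():
    # at c = σ² the coupled pair is perfectly correlated: smallest eigenvalue 0
    cfg = em.SimConfig(n_species=3, p=3, q=2, coupling_strength=1.0)
    S = em.build_joint_covariance(cfg)
    w = np.linalg.eigvalsh(S)
    assert abs(w[0]) < 1e-9


def test_joint_covariance_rejects_non_psd():
    with pytest.raises(ValidationError, match="maximal admissible"):
        cfg = em.SimConfig(n_species=3, p=2, q=2, coupling_strength=1.5)
        em.build_joint_covariance(cfg)


# --------------------------------------------------------- BM simulation


def test_bm_zero_covariance_gives_root_state():
    tree = em.simulate_yule_tree(5, 1)
    M = em.simulate_species_traits_bm(tree, np.zeros((3, 3)), 0)
    np.testing.assert_array_equal(M, 0.0)


def test_bm_star_tree_traits_uncorrelated():
    """On a star tree with Σ = I, traits are independent across species:
    the mean (over replicates) sample covariance of any trait pair is 0
    within 3 standard errors of that mean."""
    star = em.parse_newick("(" + ",".join(f"t{i+1}:1" for i in range(5)) + ");")
    covs = []
    for r in range(2000):
        M = em.simulate_species_traits_bm(star, np.eye(2), r)
        covs.append(np.cov(M.T, ddof=1)[0, 1])
    covs = np.array(covs)
    se = covs.std(ddof=1) / np.sqrt(len(covs))
    assert abs(covs.mean()) < 3 * se


def test_bm_planted_coupling_recovered_from_pooled_cross_covariance():
    """The empirical cross-covariance pooled over 2000 replicates has its
    first left singular vector aligned with the planted u*."""
    n, p, q = 32, 6, 4
    cfg = em.SimConfig(n_species=n, p=p, q=q, coupling_strength=0.9)
    S = em.build_joint_covariance(cfg)
    star = em.parse_newick(
        "(" + ",".join(f"t{i+1}:1" for i in range(n)) + ");"
    )
    acc = np.zeros((p, q))
    for r in range(2000):
        X, Y = em.simulate_species_traits_bm(star, S, r, p=p)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        acc += Xc.T @ Yc / (n - 1)
    u1 = np.linalg.svd(acc / 2000)[0][:, 0]
    assert abs(u1 @ cfg.coupling_u) >= 0.9


def test_bm_seed_determinism():
    tree = em.simulate_yule_tree(6, 3)
    S = np.eye(4)
    a = em.simulate_species_traits_bm(tree, S, 9)
    b = em.simulate_species_traits_bm(tree, S, 9)
    np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------- specimens


def test_specimens_noise_free_equal_species_means():
    # measurements are stored in mm; their logs equal the species means
    cfg = em.SimConfig(
        n_species=4, p=3, specimens_per_species=3, individual_sd=0.0,
        missing_rate=0.0, seed=5,
    )
    mu = np.arange(12, dtype=float).reshape(4, 3) / 4.0 + 1.0
    t = em.simulate_specimens(mu, cfg)
    V = np.log(t.measurements.to_numpy())
    for s in range(4):
        np.testing.assert_allclose(V[3 * s : 3 * (s + 1)], np.tile(mu[s], (3, 1)))


def test_specimens_missing_count_binomial():
    # ~45 specimens × 63 traits at rate 0.1: count within 4·binomial SD
    cfg = em.SimConfig(
        n_species=3, p=63, specimens_per_species=15, missing_rate=0.1, seed=2,
    )
    mu = np.full((3, 63), 2.0)
    t = em.simulate_specimens(mu, cfg)
    n_cells = 45 * 63
    expected = 0.1 * n_cells
    sd = np.sqrt(n_cells * 0.1 * 0.9)
    assert abs(t.n_missing - expected) < 4 * sd


def test_specimens_sex_effect_recovered():
    cfg = em.SimConfig(
        n_species=3, p=3, specimens_per_species=400, individual_sd=0.5,
        sex_effect=np.array([1.0, 0.0, 0.0]), missing_rate=0.0, seed=8,
    )
    mu = np.zeros((3, 3))
    t = em.simulate_specimens(mu, cfg)
    df = t.data.copy()
    df["m1"] = np.log(df["m1"])  # sex effect is additive on the log scale
    diff = (
        df[df.sex == "male"].groupby("species")["m1"].mean()
        - df[df.sex == "female"].groupby("species")["m1"].mean()
    )
    # MC error of a mean difference at sd=0.5, 200 per sex
    np.testing.assert_allclose(diff.to_numpy(), 1.0, atol=4 * 0.5 / np.sqrt(100))


def test_specimens_seed_determinism_and_missing_rate_domain():
    cfg = em.SimConfig(n_species=3, p=2, specimens_per_species=4, seed=1)
    mu = np.full((3, 2), 5.0)
    a = em.simulate_specimens(mu, cfg)
    b = em.simulate_specimens(mu, cfg)
    assert a.data.equals(b.data)
    with pytest.raises(ValidationError):
        em.SimConfig(n_species=3, missing_rate=1.0)


def test_ibd_field_seed_determinism():
    c1, x1 = em.simulate_ibd_field(10, 3, 1.5, 4)
    c2, x2 = em.simulate_ibd_field(10, 3, 1.5, 4)
    np.testing.assert_array_equal(c1, c2)
    np.testing.assert_array_equal(x1, x2)


def test_planted_cline_recovery_via_rrr():
    """Specimens simulated with β ≠ 0 yield an RRR whose first geographic
    direction matches β/‖β‖ (median |cos| ≥ 0.9 across replicates)."""
    beta = np.array([0.3, 0.1])
    coss = []
    for r in range(50):
        cfg = em.SimConfig(
            n_species=3, p=4, specimens_per_species=10, individual_sd=0.1,
            missing_rate=0.0, cline_slope=(0.3, 0.1),
            cline_direction=np.full(4, 0.5), seed=r,
        )
        mu = np.zeros((3, 4))
        t = em.simulate_specimens(mu, cfg)
        X = np.log(t.measurements.to_numpy())
        G = t.data[["latitude", "longitude"]].to_numpy()
        res = em.fit_rrr(X, G)
        coss.append(abs(res.w[:, 0] @ (beta / np.linalg.norm(beta))))
    assert np.median(coss) >= 0.9
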