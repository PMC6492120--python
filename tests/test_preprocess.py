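import numpy as np
import pandas as pd
import pytest

import ecomorph as em
from ecomorph.core_io import ValidationError


# ----------------------------------------------------------- log / scale


def test_log_transform_values_and_missing():
    M = np.array([[1.0, np.e], [np.nan, 1.0]])
    out = em.log_transform(M)
    assert out[0, 0] == 0.0
    assert out[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert np.isnan(out[1, 0])


def test_log_transform_rejects_nonpositive():
    with pytest.raises(ValidationError):
        em.log_transform(np.array([[0.0, 1.0]]))


def test_scale_unit_variance_sd_one():
    out = em.scale_unit_variance(np.array([[2.0], [4.0], [6.0]]))
    assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_scale_unit_variance_constant_column_named():
    df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
    with pytest.raises(ValidationError, match="flat"):
        em.scale_unit_variance(df)


def test_scale_unit_variance_scale_invariant():
    rng = np.random.default_rng(0)
    X = rng.uniform(1, 5, (10, 3))
    X2 = X.copy()
    X2[:, 1] *= 1000.0
    np.testing.assert_allclose(
        em.scale_unit_variance(X), em.scale_unit_variance(X2), atol=1e-9
    )


# --------------------------------------------------------- species means


def _table(rows):
    df = pd.DataFrame(rows)
    cols = [c for c in df.columns if c.startswith("m")]
    return em.SpecimenTable(df, cols)


def test_species_means_is_mean_of_sex_means_not_pooled():
    t = _table(
        [
            dict(species="A", sex="female", m1=10.0),
            dict(species="A", sex="female", m1=12.0),
            dict(species="A", sex="male", m1=14.0),
        ]
    )
    out = em.species_means(t, on_log_scale=False)
    assert out.loc["A", "m1"] == pytest.approx(12.5)  # not pooled mean 12.0


def test_species_means_balanced_identity():
    t = _table(
        [
            dict(species="A", sex="female", m1=5.0),
            dict(species="A", sex="male", m1=5.0),
        ]
    )
    out = em.species_means(t, on_log_scale=False)
    assert out.loc["A", "m1"] == pytest.approx(5.0)


def test_species_means_flags_missing_sex():
    t = _table(
        [
            dict(species="A", sex="female", m1=5.0),
            dict(species="A", sex="female", m1=6.0),
        ]
    )
    with pytest.warns(UserWarning, match="one sex"):
        out = em.species_means(t, on_log_scale=False)
    assert np.isnan(out.loc["A", "m1"])


def test_species_means_recovers_half_sex_effect():
    """Simulated sex effect s shifts the species mean by s/2 relative to the
    sexless truth, because the species mean averages the two sex means."""
    s = 1.0
    cfg = em.SimConfig(
        n_species=3, p=2, specimens_per_species=400, individual_sd=0.3,
        sex_effect=np.array([s, 0.0]), missing_rate=0.0, seed=4,
    )
    mu = np.full((3, 2), 2.0)  # log-mm
    t = em.simulate_specimens(mu, cfg)
    out = em.species_means(t, on_log_scale=True)
    np.testing.assert_allclose(out["m1"], 2.0 + s / 2, atol=0.1)
    np.testing.assert_allclose(out["m2"], 2.0, atol=0.1)


def test_species_means_row_order_invariant(balanced_table):
    a = em.species_means(balanced_table, on_log_scale=False)
    shuffled = em.SpecimenTable(
        balanced_table.data.iloc[::-1].reset_index(drop=True),
        balanced_table.measurement_cols,
    )
    b = em.species_means(shuffled, on_log_scale=False)
    pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------------- sex removal


def test_remove_sex_effects_centers_groups():
    t = _table(
        [
            dict(species="A", sex="male", m1=10.0),
            dict(species="A", sex="male", m1=12.0),
        ]
    )
    out = em.remove_sex_effects(t, on_log_scale=False)
    np.testing.assert_allclose(out["m1"].to_numpy(), [-1.0, 1.0])


def test_remove_sex_effects_identical_specimens_zero(balanced_table):
    df = balanced_table.data.copy()
    df[["m1", "m2"]] = 3.0
    t = em.SpecimenTable(df, ["m1", "m2"])
    out = em.remove_sex_effects(t, on_log_scale=False)
    np.testing.assert_array_equal(out.to_numpy(), 0.0)


def test_remove_sex_effects_no_residual_sex_slope():
    cfg = em.SimConfig(
        n_species=4, p=3, specimens_per_species=20, individual_sd=0.4,
        sex_effect=np.array([2.0, 1.0, 0.0]), missing_rate=0.0, seed=6,
    )
    t = em.simulate_specimens(np.zeros((4, 3)), cfg)
    dev = em.remove_sex_effects(t, on_log_scale=True).to_numpy()
    sex = (t.data["sex"] == "male").to_numpy(dtype=float)
    sex_c = sex - sex.mean()
    slope = dev.T @ sex_c / (sex_c @ sex_c)
    np.testing.assert_allclose(slope, 0.0, atol=1e-9)


def test_remove_sex_effects_singleton_warns():
    t = _table(
        [
            dict(species="A", sex="male", m1=10.0),
            dict(species="A", sex="female", m1=8.0),
            dict(species="A", sex="female", m1=9.0),
        ]
    )
    with pytest.warns(UserWarning, match="singleton"):
        out = em.remove_sex_effects(t, on_log_scale=False)
    assert out["m1"].iloc[0] == 0.0


def test_log_center_commutes_with_center_of_logs(balanced_table):
    logged = em.log_transform(balanced_table.measurements)
    direct = logged - logged.mean()
    via_dev = em.remove_sex_effects(balanced_table, on_log_scale=True)
    # both are linear centerings of the same logs: group-centering removes
    # the grand mean too when groups are balanced
    assert via_dev.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
    assert direct.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------------- EM


def test_em_no_missing_is_identity():
    X = np.arange(12, dtype=float).reshape(4, 3)
    rep = em.em_impute(X)
    np.testing.assert_array_equal(rep.completed, X)
    assert rep.n_iter == 0 and rep.converged


def test_em_exact_collinearity_imputed():
    x = np.arange(1.0, 10.0)
    M = np.column_stack([x, 2 * x])
    M = np.vstack([M, [3.0, np.nan]])
    rep = em.em_impute(M)
    assert rep.completed[-1, 1] == pytest.approx(6.0, abs=1e-3)


def test_em_never_alters_observed_cells():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((30, 4))
    Xm = X.copy()
    Xm[rng.random(X.shape) < 0.2] = np.nan
    miss = np.isnan(Xm)
    rep = em.em_impute(Xm)
    np.testing.assert_array_equal(rep.completed[~miss], X[~miss])


def test_em_monotone_delta_decrease():
    rng = np.random.default_rng(3)
    S = np.full((4, 4), 0.7)
    np.fill_diagonal(S, 1.0)
    X = rng.standard_normal((100, 4)) @ np.linalg.cholesky(S).T
    Xm = X.copy()
    Xm[rng.random(X.shape) < 0.1] = np.nan
    rep = em.em_impute(Xm)
    d = rep.deltas[3:]
    assert all(d[i + 1] <= d[i] + 1e-12 for i in range(len(d) - 1))


def test_em_rejects_empty_row():
    M = np.array([[1.0, 2.0], [np.nan, np.nan], [2.0, 3.0]])
    with pytest.raises(ValidationError, match="no observed"):
        em.em_impute(M)


def test_em_nonconvergence_reported_not_raised():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((40, 5))
    X[rng.random(X.shape) < 0.3] = np.nan
    X[np.isnan(X).all(axis=1), 0] = 0.0
    rep = em.em_impute(X, tol=1e-14, max_iter=3)
    assert not rep.converged
    assert rep.n_iter == 3
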