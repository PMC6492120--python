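"""Specimen tables → analysis-ready blocks.

Between-species analyses operate on natural-log measurements; species means
are the arithmetic mean of the female and male means (robust to unbalanced
sexes), computed on the log scale. Within-species analyses remove sex
differences by centering each specimen on its (species, sex) mean, and fill
measurement gaps from specimen damage by EM imputation under a multivariate
normal model, with a small ridge on the covariance because within-species
samples typically have more traits than specimens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SpecimenTable, ValidationError

logger = logging.getLogger(__name__)


def log_transform(M: pd.DataFrame | np.ndarray):
    """Natural log of every observed cell; missing cells stay missing."""
    vals = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"nonpositive value at row {i}, column {j}: cannot log-transform"
        )
    out = np.where(np.isnan(vals), np.nan, np.log(np.where(bad | np.isnan(vals), 1.0, vals)))
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def scale_unit_variance(block: pd.DataFrame | np.ndarray):
    """Divide each column by its standard deviation (ddof=1).

    Centering is handled downstream (by plain or GLS centering), so only the
    scale is removed here. Constant columns are rejected by name.
    """
    vals = block.to_numpy(dtype=float) if isinstance(block, pd.DataFrame) else np.asarray(block, dtype=float)
    sd = np.nanstd(vals, axis=0, ddof=1)
    zero = ~(sd > 0)
    if zero.any():
        if isinstance(block, pd.DataFrame):
            names = [str(c) for c, z in zip(block.columns, zero) if z]
        else:
            names = [str(j) for j in np.where(zero)[0]]
        raise ValidationError(f"zero-variance column(s): {names}")
    out = vals / sd
    if isinstance(block, pd.DataFrame):
        return pd.DataFrame(out, index=block.index, columns=block.columns)
    return out


def species_means(table: SpecimenTable, on_log_scale: bool = True) -> pd.DataFrame:
    """Species × trait means as the arithmetic mean of female and male means.

    Each cell is (mean over females + mean over males)/2 per trait, ignoring
    missing cells — deliberately NOT the pooled specimen mean, so unbalanced
    sex ratios do not bias the species value. A species-trait cell where one
    sex has no observed value is flagged as NaN with a warning. With
    ``on_log_scale`` the measurements are log-transformed first, so the
    means live on the scale all between-species analyses use.
    """
    M = table.measurements
    if on_log_scale:
        M = log_transform(M)
    df = pd.concat([table.data[["species", "sex"]], M], axis=1)
    by_sex = df.groupby(["species", "sex"], observed=True)[table.measurement_cols].mean()
    out = {}
    for sp in sorted(df["species"].unique()):
        try:
            f = by_sex.loc[(sp, "female")]
        except KeyError:
            f = pd.Series(np.nan, index=table.measurement_cols)
        try:
            m = by_sex.loc[(sp, "male")]
        except KeyError:
            m = pd.Series(np.nan, index=table.measurement_cols)
        cell = (f + m) / 2.0
        if cell.isna().any():
            warnings.warn(
                f"species {sp}: {int(cell.isna().sum())} trait(s) lack "
                "observed values for one sex; cells flagged as missing",
                stacklevel=2,
            )
        out[sp] = cell
    return pd.DataFrame(out).T[table.measurement_cols]


def remove_sex_effects(table: SpecimenTable, on_log_scale: bool = True) -> pd.DataFrame:
    """Center each specimen on its (species, sex) mean.

    Output values are deviations (specimen − group mean), so within every
    (species, sex) group each trait has mean 0. Missing cells stay missing.
    Singleton groups center to exactly 0 and are warned about, since they
    carry no within-group information.
    """
    M = table.measurements
    if on_log_scale:
        M = log_transform(M)
    df = pd.concat([table.data[["species", "sex"]], M], axis=1)
    grp = df.groupby(["species", "sex"], observed=True)
    sizes = grp.size()
    singletons = sizes[sizes < 2]
    if len(singletons):
        warnings.warn(
            f"singleton (species, sex) group(s): {list(singletons.index)}; "
            "their deviations are exactly 0",
            stacklevel=2,
        )
    centered = M - grp[table.measurement_cols].transform("mean")
    return centered


@dataclass
class ImputationReport:
    """Outcome of EM imputation of a specimen × trait matrix."""

    completed: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    n_iter: int
    converged: bool
    max_delta: float
    deltas: list[float] | None = None


def em_impute(
    M: np.ndarray | pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 100,
    ridge: float | None = None,
) -> ImputationReport:
    """EM imputation under a multivariate normal model.

    Alternates an E-step — replace each row's missing cells by their
    conditional expectation given the row's observed cells under the current
    (mu, Sigma), accumulating the conditional-covariance correction — with an
    M-step re-estimating mu and Sigma (maximum likelihood, denominator n)
    from the completed data plus corrections, until the largest absolute
    change in any imputed value drops below ``tol`` or ``max_iter`` is hit
    (reported as ``converged=False``, not an exception).

    ``ridge`` is added to Sigma's diagonal whenever p ≥ n or Sigma is
    numerically singular; the default is 1e-6 × mean diagonal of Sigma,
    needed because within-species samples often have more traits than
    specimens. Observed cells are never altered.
    """
    X = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float).copy()
    X = X.copy()
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValidationError("row(s) with no observed value cannot be imputed")
    if (miss.sum(axis=0) > n - 2).any():
        raise ValidationError("column(s) with fewer than 2 observed values")
    if not miss.any():
        mu = X.mean(axis=0)
        Sigma = np.cov(X, rowvar=False, ddof=0).reshape(p, p)
        return ImputationReport(X, mu, Sigma, 0, True, 0.0, [])

    # init: column-mean fill
    mu = np.nanmean(X, axis=0)
    Xc = np.where(miss, mu[None, :], X)
    Sigma = np.cov(Xc, rowvar=False, ddof=0).reshape(p, p)

    # group rows by missingness pattern: one linear solve per pattern
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)

    def _regularized(S: np.ndarray) -> np.ndarray:
        lam = ridge if ridge is not None else 1e-6 * np.mean(np.diag(S))
        if p >= n or np.linalg.matrix_rank(S, tol=1e-10 * max(1.0, np.trace(S))) < p:
            return S + lam * np.eye(p)
        return S

    prev_imputed = Xc[miss].copy()
    max_delta = np.inf
    deltas: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S = _regularized(Sigma)
        correction = np.zeros((p, p))
        for key, idxs in patterns.items():
            mrow = np.frombuffer(key, dtype=bool)
            if not mrow.any():
                continue
            o = ~mrow
            Soo = S[np.ix_(o, o)]
            Smo = S[np.ix_(mrow, o)]
            Smm = S[np.ix_(mrow, mrow)]
            coef = np.linalg.solve(Soo, Smo.T).T          # Σ_mo Σ_oo⁻¹
            cond_cov = Smm - coef @ Smo.T
            for i in idxs:
                Xc[i, mrow] = mu[mrow] + coef @ (Xc[i, o] - mu[o])
            correction[np.ix_(mrow, mrow)] += len(idxs) * cond_cov
        mu = Xc.mean(axis=0)
        Sigma = np.cov(Xc, rowvar=False, ddof=0).reshape(p, p) + correction / n
        cur = Xc[miss]
        max_delta = float(np.max(np.abs(cur - prev_imputed)))
        deltas.append(max_delta)
        prev_imputed = cur.copy()
        if max_delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM imputation did not converge (max_delta=%g)", max_delta)
    completed = np.where(miss, Xc, X)
    if isinstance(M, pd.DataFrame):
        completed_out = completed
    else:
        completed_out = completed
    return ImputationReport(completed_out, mu, Sigma, it, converged, max_delta, deltas)
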