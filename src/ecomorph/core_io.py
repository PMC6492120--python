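"""Domain types and file I/O for ecogeographic morphometric analyses.

The pipeline operates on three kinds of input: specimen-level trait tables
(CSV/TSV; linear measurements in mm plus specimen metadata), species-level
environmental tables (CSV), and a rooted, time-scaled phylogeny (Newick).
Results are serialized as JSON with full double precision so that
write → read round-trips are bit-stable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}
SEXES = {"female", "male"}
AGE_CLASSES = {"adult", "subadult"}
PROVENANCES = {"wild", "captive", "unknown"}

METADATA_FIELDS = (
    "specimen_id",
    "species",
    "sex",
    "age_class",
    "provenance",
    "latitude",
    "longitude",
)


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Table contents violate an invariant (e.g. nonpositive measurement)."""


# ---------------------------------------------------------------------------
# Trees


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths in time units.

    Thin wrapper around a :class:`dendropy.Tree`; tip labels must be unique
    and every non-root edge must carry a nonnegative branch length.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    "branch length missing on an edge; time-scaled lengths "
                    "are required for the Brownian-motion covariance"
                )
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        root = self.tree.seed_node
        if len(root.child_nodes()) < 2:
            raise ValidationError("root must have at least 2 children")

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in deterministic post-order (the canonical order)."""
        return [
            lf.taxon.label
            for lf in self.tree.leaf_node_iter()
        ]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            lf.taxon.label: lf.root_distance
            for lf in self.tree.leaf_node_iter()
        }

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def subtree(self, labels: Sequence[str]) -> "PhyloTree":
        """Prune to the given tips (preserving branch lengths)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")
        t = self.tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return PhyloTree(t)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths.

    Unlabeled internal nodes are allowed; a missing semicolon or unbalanced
    parentheses raise a parse error, and edges without branch lengths are
    rejected because all downstream covariances are in time units.
    """
    text = Path(path).read_text().strip()
    return parse_newick(text)


def parse_newick(text: str) -> PhyloTree:
    if not text.rstrip().endswith(";"):
        raise ValidationError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValidationError(f"Newick parse error: {exc}") from exc
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Specimen tables


@dataclass
class SpecimenTable:
    """Individual-level measurements with specimen metadata.

    ``data`` holds one row per specimen with the metadata columns
    (specimen_id, species, sex, age_class, provenance, latitude, longitude)
    followed by measurement columns (strictly positive mm, NaN = missing).
    """

    data: pd.DataFrame
    measurement_cols: list[str]

    def __post_init__(self) -> None:
        df = self.data
        if len(self.measurement_cols) != len(set(self.measurement_cols)):
            raise ValidationError("measurement column names must be unique")
        for col in ("species", "sex"):
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col}")
        if df["species"].isna().any():
            bad = df.index[df["species"].isna()].tolist()
            raise ValidationError(f"rows without species label: {bad}")
        bad_sex = set(df["sex"].dropna()) - SEXES
        if bad_sex:
            raise ValidationError(f"unknown sex tokens: {sorted(bad_sex)}")
        if "age_class" in df.columns:
            bad = set(df["age_class"].dropna()) - AGE_CLASSES
            if bad:
                raise ValidationError(f"unknown age_class tokens: {sorted(bad)}")
        has_lat = "latitude" in df.columns
        has_lon = "longitude" in df.columns
        if has_lat != has_lon:
            raise ValidationError("latitude/longitude must be present together")
        if has_lat:
            one_sided = df["latitude"].isna() != df["longitude"].isna()
            if one_sided.any():
                raise ValidationError(
                    "latitude/longitude must be missing together "
                    f"(rows {df.index[one_sided].tolist()})"
                )
            lat = df["latitude"].dropna()
            lon = df["longitude"].dropna()
            if ((lat < -90) | (lat > 90)).any():
                raise ValidationError("latitude outside [-90, 90]")
            if ((lon < -180) | (lon > 180)).any():
                raise ValidationError("longitude outside [-180, 180]")
        M = df[self.measurement_cols]
        nonpos = (M <= 0)
        if nonpos.any().any():
            rows = df.index[nonpos.any(axis=1)].tolist()
            raise ValidationError(
                f"nonpositive measurement(s) in row(s) {rows}"
            )

    @property
    def measurements(self) -> pd.DataFrame:
        return self.data[self.measurement_cols]

    @property
    def n_missing(self) -> int:
        return int(self.measurements.isna().sum().sum())

    @property
    def species(self) -> pd.Series:
        return self.data["species"]


def read_specimen_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    measurement_cols: Sequence[str] | None = None,
) -> SpecimenTable:
    """Read a specimen trait table from CSV or TSV.

    Parameters
    ----------
    path
        File path; the delimiter (comma or tab) is sniffed from the header.
    schema
        Map from canonical field names (``species``, ``sex``, ...) to the
        column names used in the file. Identity by default. This is the
        adapter for arbitrary museum-export layouts.
    measurement_cols
        Names (post-mapping) of the measurement columns. By default every
        non-metadata column is treated as a measurement.

    Missing measurements may be empty cells or ``NA`` — both occur in
    museum-derived exports.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open().readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(
        path, sep=sep, na_values=sorted(MISSING_TOKENS), keep_default_na=True
    )
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    for canonical, source in schema.items():
        if source not in df.columns:
            raise SchemaError(
                f"column '{source}' (mapped to '{canonical}') not in file"
            )
    df = df.rename(columns=rename)
    if measurement_cols is None:
        measurement_cols = [c for c in df.columns if c not in METADATA_FIELDS]
    else:
        missing = set(measurement_cols) - set(df.columns)
        if missing:
            raise SchemaError(f"measurement columns not in file: {sorted(missing)}")
        measurement_cols = list(measurement_cols)
    for col in measurement_cols:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return SpecimenTable(df, measurement_cols)


# ---------------------------------------------------------------------------
# Aligned species dataset


@dataclass
class SpeciesDataset:
    """Species-aligned blocks for between-species analysis.

    Rows of ``X`` (log-scale morphology means), ``Y`` (environment), and
    ``G`` (latitude, longitude of the range centroid) share one canonical
    species order, which equals the post-order tip sequence of ``tree``.
    """

    species: list[str]
    X: np.ndarray
    Y: np.ndarray
    G: np.ndarray
    tree: PhyloTree
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.species)
        if n < 3:
            raise ValidationError(f"need >= 3 species, got {n}")
        if len(set(self.species)) != n:
            raise ValidationError("duplicate species labels")
        for name, M in (("X", self.X), ("Y", self.Y), ("G", self.G)):
            if M.shape[0] != n:
                raise ValidationError(f"{name} has {M.shape[0]} rows, expected {n}")
            if np.isnan(M).any():
                raise ValidationError(f"missing cells in {name}")
        if self.G.shape[1] != 2:
            raise ValidationError("G must have 2 columns (latitude, longitude)")
        if self.tree.tip_labels != self.species:
            raise ValidationError("tree tip order must equal species order")

    @property
    def n(self) -> int:
        return len(self.species)


def align_dataset(
    morph: pd.DataFrame,
    env: pd.DataFrame,
    geo: pd.DataFrame,
    tree: PhyloTree,
    drop: Sequence[str] = (),
) -> SpeciesDataset:
    """Align species-mean tables, coordinates, and the tree on one order.

    All inputs are indexed by species label. Species absent from any input
    (or listed in ``drop``, e.g. a geographic outlier excluded from the
    spatial analysis) are removed with a logged warning. The canonical row
    order is the pruned tree's deterministic post-order tip sequence, which
    makes every downstream matrix reproducible across runs.
    """
    for name, df in (("morph", morph), ("env", env), ("geo", geo)):
        if df.index.duplicated().any():
            raise ValidationError(f"duplicate species labels in {name} table")
    shared = (
        set(morph.index) & set(env.index) & set(geo.index) & set(tree.tip_labels)
    )
    dropped = (
        (set(morph.index) | set(env.index) | set(geo.index) | set(tree.tip_labels))
        - shared
    ) | (shared & set(drop))
    shared -= set(drop)
    if dropped:
        logger.warning("dropping species absent from some input: %s", sorted(dropped))
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} species shared across inputs; need >= 3"
        )
    sub = tree.subtree(sorted(shared))
    order = sub.tip_labels
    if list(geo.columns[:2]) and geo.shape[1] >= 2:
        G = geo.loc[order].iloc[:, :2].to_numpy(dtype=float)
    else:
        raise ValidationError("geo table must have two coordinate columns")
    return SpeciesDataset(
        species=order,
        X=morph.loc[order].to_numpy(dtype=float),
        Y=env.loc[order].to_numpy(dtype=float),
        G=G,
        tree=sub,
        x_names=list(morph.columns),
        y_names=list(env.columns),
    )


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class PlsResult:
    """Two-block PLS decomposition of a cross-covariance matrix.

    ``u`` (p×K) and ``v`` (q×K) hold unit-norm loading columns, ``d`` the
    singular values (score covariances, descending), ``scores_x``/``scores_y``
    the latent-variable scores, ``r`` the per-dimension score correlations,
    and ``effect`` the fractions d_k²/Σd_i² of squared covariance.
    """

    u: np.ndarray
    v: np.ndarray
    d: np.ndarray
    scores_x: np.ndarray
    scores_y: np.ndarray
    r: np.ndarray
    effect: np.ndarray
    phylogenetic: bool
    p_values: dict[str, float] | None = None
    scores_x_raw: np.ndarray | None = None
    scores_y_raw: np.ndarray | None = None

    @property
    def dims(self) -> int:
        return len(self.d)


@dataclass
class RrrResult:
    """Reduced-rank regression of a trait block on (latitude, longitude).

    ``B`` is the p×2 matrix of partial regression coefficients; its SVD
    gives singular values ``d`` (maximal cline slopes, trait log-units per
    degree), morphological loadings ``u`` (p×2), and unit geographic
    gradient directions ``w`` (2×2, columns).
    """

    B: np.ndarray
    d: np.ndarray
    u: np.ndarray
    w: np.ndarray
    scores_x: np.ndarray
    scores_g: np.ndarray
    r: np.ndarray
    effect: np.ndarray
    phylogenetic: bool
    p_values: dict[str, float] | None = None


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValidationError(f"Mantel r {self.r} outside [-1, 1]")
        if self.p < 1.0 / (self.n_perm + 1) - 1e-15 or self.p > 1:
            raise ValidationError("p outside (1/(n_perm+1), 1]")


_RESULT_TYPES = {
    "PlsResult": PlsResult,
    "RrrResult": RrrResult,
    "MantelResult": MantelResult,
}

_ARRAY_FIELDS = {
    "u", "v", "d", "scores_x", "scores_y", "r", "effect", "B", "w",
    "scores_g", "scores_x_raw", "scores_y_raw",
}


def write_results(result, path: str | Path, header: dict | None = None) -> None:
    """Serialize a result object to JSON with full double precision."""
    payload: dict = {"type": type(result).__name__}
    if header:
        payload["header"] = header
    for name, val in vars(result).items():
        if isinstance(val, np.ndarray):
            payload[name] = val.tolist()
        elif isinstance(val, (np.floating, np.integer)):
            payload[name] = val.item()
        else:
            payload[name] = val
    Path(path).write_text(json.dumps(payload, indent=1))


def read_results(path: str | Path):
    """Read a result JSON written by :func:`write_results`."""
    payload = json.loads(Path(path).read_text())
    cls = _RESULT_TYPES[payload.pop("type")]
    payload.pop("header", None)
    kwargs = {}
    for name, val in payload.items():
        if name in _ARRAY_FIELDS and val is not None:
            kwargs[name] = np.asarray(val, dtype=float)
        else:
            kwargs[name] = val
    return cls(**kwargs)
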