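"""2D projections of chemical and explanation spaces.

Compounds are embedded into the plane with UMAP, either from selected
numeric attribute groups (fingerprints, latent vectors, descriptors),
optionally standardized to zero mean and unit variance, or from a
precomputed explanation-distance matrix. The explanation distance between
two compounds is ``1 - rho`` where ``rho`` is the Spearman rank correlation
of their per-feature attribution vectors — compounds whose explanations
rank features similarly end up close together.

Projections are named and stored on the table's projection registry so that
several alternative views of the same dataset can coexist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .sdf_io import CompoundTable, to_flat_table

logger = logging.getLogger(__name__)

DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1
DEFAULT_SEED = 42


@dataclass
class ProjectionResult:
    """A named 2D embedding plus the parameters that produced it."""

    name: str
    coords: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an n x 2 matrix")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")


@dataclass
class ExplanationDistanceMatrix:
    """Spearman correlation of per-compound feature-score vectors and the
    derived distance ``dist = 1 - rho``."""

    rho: np.ndarray
    dist: np.ndarray


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Scale each column to zero mean and unit population variance.

    Constant columns are mapped to all-zeros with a warning. Requires at
    least two rows.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize requires an n x p matrix with n >= 2")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population standard deviation
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant column(s) standardized to zeros", int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    out = (X - mean) / sd_safe
    out[:, constant] = 0.0
    return out


def _umap_embed(X: np.ndarray, seed: int, n_neighbors: int, min_dist: float,
                metric: str) -> np.ndarray:
    import umap  # deferred: numba compilation is slow at import

    n = X.shape[0]
    n_neighbors = max(2, min(n_neighbors, n - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about small n / forced seeds
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
        )
        coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=float)


def random_initial_positions(n: int, seed: int) -> np.ndarray:
    """Uniform random placement in the unit square, used when a dataset has
    no coordinates yet and no projection has been computed."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, 2))


def select_attribute_matrix(table: CompoundTable, attribute_groups) -> np.ndarray:
    """Extract the numeric matrix of the requested column groups from the
    flat table (in row order)."""
    df, groups, _ = to_flat_table(table)
    cols: list[str] = []
    for g in attribute_groups:
        if g not in groups:
            raise KeyError(f"unknown attribute group {g!r}; available: {sorted(groups)}")
        cols.extend(groups[g])
    sub = df[cols]
    bad = [c for c in cols if not np.issubdtype(sub[c].dtype, np.number)]
    if bad:
        raise TypeError(f"non-numeric column(s) selected for projection: {bad}")
    return sub.to_numpy(dtype=float)


def project(
    table: CompoundTable,
    attribute_groups=("fingerprint",),
    standardize_features: bool = False,
    seed: int = DEFAULT_SEED,
    name: str = "umap",
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
) -> ProjectionResult:
    """UMAP-project the compounds from selected attribute groups.

    Deterministic for a fixed seed. The result is registered on
    ``table.projections`` under ``name``; reusing a name raises.
    """
    if name in table.projections:
        raise ValueError(f"projection name {name!r} already stored")
    n = len(table)
    if n < 4:
        raise ValueError("projection requires at least 4 compounds")
    X = select_attribute_matrix(table, attribute_groups)
    if standardize_features:
        X = standardize(X)
    coords = _umap_embed(X, seed=seed, n_neighbors=n_neighbors, min_dist=min_dist,
                         metric="euclidean")
    result = ProjectionResult(
        name=name, coords=coords,
        params={"attribute_groups": list(attribute_groups),
                "standardized": standardize_features, "seed": seed,
                "n_neighbors": n_neighbors, "min_dist": min_dist,
                "metric": "euclidean"},
    )
    table.projections[name] = result
    return result


def spearman_distances(score_matrix: np.ndarray) -> ExplanationDistanceMatrix:
    """Pairwise Spearman rank correlation of the rows and ``1 - rho``.

    A row with zero variance has no defined rank correlation; its
    off-diagonal correlations are set to 0 (distance 1) with a warning.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError("score matrix must be n x L with n >= 2 and L >= 2")
    ranks = np.vstack([rankdata(row) for row in S])
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance score row(s): correlations set to 0",
                       int(degenerate.sum()))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = centered / (sd_safe[:, None] * np.sqrt(ranks.shape[1]))
    rho = Z @ Z.T
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return ExplanationDistanceMatrix(rho=rho, dist=dist)


def project_explanations(
    table: CompoundTable,
    score_matrix: np.ndarray,
    seed: int = DEFAULT_SEED,
    name: str = "umap_explanations",
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
) -> ProjectionResult:
    """UMAP with a precomputed Spearman explanation-distance matrix.

    ``score_matrix`` holds one per-feature attribution vector per compound,
    aligned with the table's row order.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.shape[0] != len(table):
        raise ValueError(f"score matrix has {S.shape[0]} rows for {len(table)} compounds")
    if name in table.projections:
        raise ValueError(f"projection name {name!r} already stored")
    dm = spearman_distances(S)
    coords = _umap_embed(dm.dist, seed=seed, n_neighbors=n_neighbors,
                         min_dist=min_dist, metric="precomputed")
    result = ProjectionResult(
        name=name, coords=coords,
        params={"seed": seed, "n_neighbors": n_neighbors, "min_dist": min_dist,
                "metric": "precomputed", "distance": "1 - spearman_rho"},
    )
    table.projections[name] = result
    return result


def apply_projection(table: CompoundTable, result: ProjectionResult) -> None:
    """Write a projection's coordinates onto the records as (x, y)."""
    for rec, (x, y) in zip(table.records, result.coords):
        rec.coords2d = (float(x), float(y))
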