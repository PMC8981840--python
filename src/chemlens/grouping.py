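"""Density-based grouping of compounds in a 2D projection.

Clusters are computed with HDBSCAN on the (x, y) coordinates of a
projection; points in no dense region get the noise label -1. The default
``min_cluster_size`` scales weakly with dataset size, ``max(5, n // 100)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

from .substructure import mcs


@dataclass
class ClusterAssignment:
    """Integer labels per point (-1 = noise) plus the hyperparameters used.

    Non-noise labels form a contiguous 0-based set.
    """

    labels: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


def default_min_cluster_size(n: int) -> int:
    return max(5, n // 100)


def cluster(coords: np.ndarray, min_cluster_size: int | None = None,
            **hyperparams) -> ClusterAssignment:
    """HDBSCAN clustering of 2D coordinates.

    Deterministic for fixed input. Datasets smaller than
    ``min_cluster_size`` are all noise. Extra keyword arguments are passed
    to the clusterer (e.g. ``min_samples``, ``cluster_selection_epsilon``).
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("coords must be an n x 2 matrix")
    if not np.isfinite(X).all():
        raise ValueError("coords contain non-finite values")
    n = X.shape[0]
    if min_cluster_size is None:
        min_cluster_size = default_min_cluster_size(n)
    params = {"min_cluster_size": int(min_cluster_size), **hyperparams}
    if n < max(2, min_cluster_size):
        return ClusterAssignment(labels=np.full(n, -1, dtype=int), params=params)
    hyperparams.setdefault("copy", True)
    model = HDBSCAN(min_cluster_size=int(min_cluster_size), **hyperparams)
    labels = model.fit_predict(X).astype(int)
    labels = _relabel_contiguous(labels)
    return ClusterAssignment(labels=labels, params=params)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber non-noise labels to 0..k-1 in order of first appearance."""
    out = np.full_like(labels, -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_summary(smiles: list[str], assignment: ClusterAssignment,
                    mcs_timeout_s: float = 5.0) -> dict[int, dict]:
    """Per-cluster report: member count and the members' maximum common
    substructure (the group summary shown for a compound column)."""
    summary: dict[int, dict] = {}
    labels = assignment.labels
    for lab in sorted(set(labels[labels >= 0])):
        members = [s for s, l in zip(smiles, labels) if l == lab]
        entry: dict = {"n_members": len(members)}
        entry["mcs"] = mcs(members, timeout_s=mcs_timeout_s).pattern
        summary[int(lab)] = entry
    return summary
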