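"""Nearest-subclass routing: each simulation sample goes to the subclass
whose mean center is closest in Mahalanobis distance (pooled training
covariance).  Ties break to the lowest subclass id."""

from __future__ import annotations

import numpy as np

from .cluster import SubclassPartition, mahalanobis

__all__ = ["assign_subclass", "assign_all"]


def assign_subclass(sample: np.ndarray, partition: SubclassPartition) -> tuple[int, float]:
    """Return (subclass id, distance to its center) for one sample."""
    sample = np.asarray(sample, dtype=float).ravel()
    if partition.n_subclasses == 0:
        raise ValueError("partition has no subclasses")
    if sample.shape[0] != partition.centers.shape[1]:
        raise ValueError(
            f"sample dimension {sample.shape[0]} != partition feature space "
            f"{partition.centers.shape[1]}"
        )
    V_inv = partition.pooled_inverse_covariance
    dists = np.array([mahalanobis(sample, c, V_inv) for c in partition.centers])
    best = int(np.argmin(dists))  # argmin returns the first (lowest-id) minimum
    return best + 1, float(dists[best])


def assign_all(X: np.ndarray, partition: SubclassPartition) -> tuple[np.ndarray, np.ndarray]:
    """Vector version: (ids, distances) for every row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = np.empty(X.shape[0], dtype=int)
    dists = np.empty(X.shape[0])
    for i, row in enumerate(X):
        ids[i], dists[i] = assign_subclass(row, partition)
    return ids, dists
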