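"""Sample-space ("horizontal") reduction: Mahalanobis distances, UPGMA
agglomerative clustering, tree cutting, and subclass summaries.

The between-cluster measure is the class average distance — the square
root of the mean of squared cross-pair distances — maintained efficiently
with the size-weighted Lance–Williams update on squared distances, which
is exactly equivalent to recomputing the cross-pair average from scratch
at each merge.  Mahalanobis distance (pooled covariance, pseudo-inverted
when singular) removes the influence of correlated features on the
grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MergeTree",
    "SubclassPartition",
    "pooled_covariance",
    "inverse_covariance",
    "mahalanobis",
    "pairwise_mahalanobis",
    "upgma_linkage",
    "cut_tree",
    "partition_summarize",
]


@dataclass
class MergeTree:
    """UPGMA merge history.

    ``merges`` lists (cluster_a, cluster_b, height, new_size) in merge
    order; leaves are numbered 0..leaf_count-1 and each merge creates
    cluster leaf_count + step (the scipy linkage numbering convention).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_count: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.leaf_count - 1:
            raise ValueError("a tree over n leaves must contain n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.asarray([m[2] for m in self.merges])

    def to_frame(self):
        """Merge list as a DataFrame (dendrogram export)."""
        import pandas as pd

        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "new_size"]
        )


@dataclass
class SubclassPartition:
    """A cut of the merge tree: per-sample subclass ids (1..K), subclass
    mean centers, and the pooled inverse covariance used for all
    Mahalanobis computations (routing included)."""

    assignment: np.ndarray
    centers: np.ndarray
    pooled_inverse_covariance: np.ndarray
    cut_value: float | int | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))

    @property
    def n_subclasses(self) -> int:
        return self.centers.shape[0]


def pooled_covariance(X: np.ndarray) -> np.ndarray:
    """Sample covariance with the n-1 denominator (symmetric PSD)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("covariance needs an (n ≥ 2, p) matrix")
    return np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])


def inverse_covariance(
    V: np.ndarray, method: str = "pinv", ridge_eps: float | None = None
) -> np.ndarray:
    """Invert a covariance matrix robustly.

    ``pinv`` (default) takes the Moore–Penrose pseudo-inverse, which keeps
    distances finite when clustering produced small subclasses or p ≥ n
    made V singular; ``ridge`` inverts V + εI with ε = 1e-8·trace(V)/p.
    """
    V = np.asarray(V, dtype=float)
    if method == "pinv":
        return np.linalg.pinv(V, hermitian=True)
    if method == "ridge":
        p = V.shape[0]
        eps = ridge_eps if ridge_eps is not None else 1e-8 * np.trace(V) / p
        return np.linalg.inv(V + eps * np.eye(p))
    raise ValueError(f"unknown inversion method {method!r}")


def mahalanobis(x_i: np.ndarray, x_j: np.ndarray, V_inv: np.ndarray) -> float:
    """d = sqrt((x_i - x_j)' V^{-1} (x_i - x_j))."""
    d = np.asarray(x_i, dtype=float).ravel() - np.asarray(x_j, dtype=float).ravel()
    if d.shape[0] != V_inv.shape[0]:
        raise ValueError("vector / V_inv dimension mismatch")
    return float(np.sqrt(max(d @ V_inv @ d, 0.0)))


def pairwise_mahalanobis(X: np.ndarray, V_inv: np.ndarray) -> np.ndarray:
    """Full symmetric distance matrix between the rows of X."""
    X = np.asarray(X, dtype=float)
    # (x_i - x_j)' Vinv (x_i - x_j) expanded through the Gram matrix
    G = X @ V_inv @ X.T
    sq = np.diag(G)[:, None] + np.diag(G)[None, :] - 2 * G
    D = np.sqrt(np.clip(sq, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return D


def upgma_linkage(D: np.ndarray) -> MergeTree:
    """Agglomerate by repeatedly merging the pair of clusters at smallest
    class-average distance.

    Works on squared distances internally (Lance–Williams:
    D²(k, p∪q) = (n_p/n_r) D²(k,p) + (n_q/n_r) D²(k,q)); reported merge
    heights are the unsquared average distances.  Ties break to the
    smallest (cluster id, cluster id) pair, which makes the tree
    deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 2:
        raise ValueError("need at least two samples to cluster")

    S = D.astype(float) ** 2  # squared class-average distances
    ids = list(range(n))  # active cluster ids, ascending
    sizes = {i: 1 for i in range(n)}
    pos = {i: i for i in range(n)}  # cluster id -> row of S
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                v = S[pos[a], pos[b]]
                if best is None or v < best[0] - 1e-15 * max(abs(best[0]), 1.0):
                    best = (v, a, b)
        v, a, b = best
        height = float(np.sqrt(max(v, 0.0)))
        new_id = n + step
        na, nb = sizes[a], sizes[b]
        nr = na + nb
        ra, rb = pos[a], pos[b]
        # Lance-Williams (average linkage on squared distances) into row ra
        for c in ids:
            if c in (a, b):
                continue
            rc = pos[c]
            upd = (na * S[rc, ra] + nb * S[rc, rb]) / nr
            S[rc, ra] = S[ra, rc] = upd
        ids.remove(a)
        ids.remove(b)
        ids.append(new_id)
        sizes[new_id] = nr
        pos[new_id] = ra
        merges.append((a, b, height, nr))
    return MergeTree(merges=merges, leaf_count=n)


def cut_tree(
    tree: MergeTree, lam: float | None = None, k: int | None = None
) -> np.ndarray:
    """Flatten the tree into subclass labels 1..K.

    λ rule: undo every merge at height > λ.  k rule: keep exactly the last
    k-1 merges undone.  Labels are assigned in order of first member
    appearance, so the labeling is deterministic.
    """
    n = tree.leaf_count
    if (lam is None) == (k is None):
        raise ValueError("provide exactly one of lam or k")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        applied = tree.merges[: n - k]
    else:
        if lam < 0:
            raise ValueError("lambda cutoff must be nonnegative")
        applied = [m for m in tree.merges if m[2] <= lam]

    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # union only the applied merges, preserving merge-created ids
    applied_set = set(id(m) for m in applied)
    for step, m in enumerate(tree.merges):
        new_id = n + step
        if id(m) in applied_set:
            parent[find(m[0])] = new_id
            parent[find(m[1])] = new_id

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[i] = seen[root]
    return labels


def partition_summarize(
    X: np.ndarray,
    assignment: np.ndarray,
    cov_method: str = "pinv",
    cut_value: float | int | None = None,
) -> SubclassPartition:
    """Compute subclass mean centers and the pooled inverse covariance of
    the full training matrix (pseudo-inverse when rank-deficient)."""
    X = np.asarray(X, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != X.shape[0]:
        raise ValueError("assignment length must equal sample count")
    ks = np.unique(assignment)
    if ks.min() < 1:
        raise ValueError("subclass ids must start at 1")
    centers = np.empty((ks.max(), X.shape[1]))
    for kk in range(1, ks.max() + 1):
        members = X[assignment == kk]
        if members.shape[0] == 0:
            raise ValueError(f"subclass {kk} is empty")
        centers[kk - 1] = members.mean(axis=0)
    V = pooled_covariance(X) if X.shape[0] >= 2 else np.eye(X.shape[1])
    return SubclassPartition(
        assignment=assignment,
        centers=centers,
        pooled_inverse_covariance=inverse_covariance(V, method=cov_method),
        cut_value=cut_value,
    )
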