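"""Traced Lloyd's algorithm for k-means clustering.

The selective test conditions on the *entire path* of a single k-means run:
the randomly sampled initial centroids, the initial nearest-centroid
assignment, and every subsequent assignment produced by the
assign/update iteration.  :class:`ClusterTrace` records all of these so that
the conditioning event can later be expressed analytically.

Conventions fixed here and relied on everywhere the assignment step is
re-evaluated (in particular by the truncation-set machinery):

* distances are squared Euclidean;
* ties in the nearest-centroid assignment are broken toward the lowest
  cluster index (``numpy.argmin`` semantics);
* cluster labels are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyClusterError

__all__ = [
    "ClusterTrace",
    "sample_initial_centroids",
    "assign_to_nearest",
    "update_centroids",
    "lloyd_with_trace",
    "within_cluster_ss",
]


def _as_data_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"data must be a 2-d matrix, got shape {x.shape}")
    if x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError(f"need n >= 2 observations and q >= 1 features, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data matrix contains non-finite entries")
    return x


@dataclass(frozen=True)
class ClusterTrace:
    """Complete record of one k-means run.

    Attributes
    ----------
    K : int
        Number of clusters.
    init_indices : ndarray of int, shape (K,)
        Row indices of the observations sampled as initial centroids.
    assignments : ndarray of int, shape (T + 1, n)
        Row ``t`` holds the cluster labels after iteration ``t``; row 0 is
        the nearest-initial-centroid assignment.
    centroids : tuple of ndarray, each (K, q)
        ``centroids[0]`` are the sampled data rows; ``centroids[t]`` for
        ``t >= 1`` are the within-cluster means implied by assignment row
        ``t - 1``.
    T : int
        Number of update iterations performed (``assignments`` has
        ``T + 1`` rows).
    converged : bool
        True iff the assignments stabilized (row T equals row T - 1)
        within the iteration cap.
    """

    K: int
    init_indices: np.ndarray
    assignments: np.ndarray
    centroids: tuple = field(repr=False)
    T: int = 0
    converged: bool = False

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    @property
    def final_labels(self) -> np.ndarray:
        return self.assignments[-1]

    def cluster_sizes(self, t: int = -1) -> np.ndarray:
        return np.bincount(self.assignments[t], minlength=self.K)


def sample_initial_centroids(x, K: int, rng) -> np.ndarray:
    """Sample ``K`` distinct row indices uniformly without replacement."""
    x = _as_data_matrix(x)
    n = x.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must satisfy 1 <= K <= n = {n}, got {K}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.choice(n, size=K, replace=False)


def assign_to_nearest(x, centroids) -> np.ndarray:
    """Assign each row of ``x`` to its nearest centroid (squared Euclidean).

    Ties go to the lowest cluster index.
    """
    x = np.asarray(x, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != x.shape[1]:
        raise ValueError(
            f"centroid shape {centroids.shape} incompatible with data shape {x.shape}"
        )
    # ||x_i - m_k||^2 = ||x_i||^2 - 2 <x_i, m_k> + ||m_k||^2; the ||x_i||^2
    # term is constant in k.  Argmin of the exact distances is used instead
    # of the expanded form so that ties resolve identically wherever this
    # rule is re-evaluated.
    d2 = np.square(x[:, None, :] - centroids[None, :, :]).sum(axis=2)
    return np.argmin(d2, axis=1)


def update_centroids(x, labels, K: int) -> np.ndarray:
    """Within-cluster means for each of the ``K`` clusters.

    Raises :class:`EmptyClusterError` if any label in ``0..K-1`` is absent:
    the mean weights are undefined for an empty cluster.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=K)
    if len(counts) > K:
        raise ValueError("labels outside 0..K-1")
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise EmptyClusterError(int(empty[0]), iteration=-1)
    sums = np.zeros((K, x.shape[1]))
    np.add.at(sums, labels, x)
    return sums / counts[:, None]


def within_cluster_ss(x, labels, K: int) -> float:
    """Within-cluster sum of squares (the k-means objective)."""
    m = update_centroids(x, labels, K)
    return float(np.square(np.asarray(x, dtype=float) - m[labels]).sum())


def lloyd_with_trace(x, K: int, init_indices, max_iter: int = 300) -> ClusterTrace:
    """Run Lloyd's algorithm from given initial centroid rows, keeping the trace.

    Iterates centroid updates and nearest-centroid reassignment until the
    assignments repeat or ``max_iter`` update iterations have been
    performed.  A non-converged run still yields a valid trace (the
    selective test conditions on whatever iterations were realized), but is
    flagged ``converged=False``.
    """
    x = _as_data_matrix(x)
    init_indices = np.asarray(init_indices, dtype=int)
    if init_indices.ndim != 1 or len(np.unique(init_indices)) != len(init_indices):
        raise ValueError("init_indices must be distinct")
    if len(init_indices) != K:
        raise ValueError(f"expected {K} initial indices, got {len(init_indices)}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    centroids = [x[init_indices].copy()]
    assignments = [assign_to_nearest(x, centroids[0])]
    converged = False
    for t in range(1, max_iter + 1):
        try:
            m = update_centroids(x, assignments[-1], K)
        except EmptyClusterError as e:
            raise EmptyClusterError(e.cluster, iteration=t) from None
        labels = assign_to_nearest(x, m)
        centroids.append(m)
        assignments.append(labels)
        if np.array_equal(labels, assignments[-2]):
            converged = True
            break
    return ClusterTrace(
        K=K,
        init_indices=init_indices,
        assignments=np.vstack(assignments),
        centroids=tuple(centroids),
        T=len(assignments) - 1,
        converged=converged,
    )
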