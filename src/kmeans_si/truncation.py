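"""Analytic characterization of the k-means conditioning set.

The selective p-value conditions on every intermediate cluster assignment of
a single Lloyd run.  Along the one-dimensional perturbation of the data that
moves the two tested cluster centroids apart (coordinate ``phi``, equal to
the test statistic at the observed data), each "observation i stays in its
cluster rather than switching to cluster k at iteration t" requirement is a
quadratic inequality in ``phi``:

* squared distances between two perturbed rows, and between a perturbed row
  and a fixed convex combination of perturbed rows, are quadratic
  polynomials in ``phi`` whose coefficients follow from the affine form
  ``x'(phi)_i = base_i + phi * s_i * v``;
* the conditioning event at iteration t compares the distance to the
  assigned centroid against the distance to each competitor, giving a
  difference of two such quadratics — still quadratic.

The conditioning set S_T is the intersection of all n*K*(T+1) quadratic
solution sets, computed here by a single sort over interval endpoints.

Crucially, the centroid *weights* entering the iteration-t constraints are
those of the original run (the event holds them fixed), and the iteration-0
centroids are the perturbed rows at the originally sampled indices; only the
rows of ``x'(phi)`` vary with phi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyClusterError
from .intervals import DEFAULT_TOL, IntervalUnion
from .kmeans import ClusterTrace

__all__ = [
    "ContrastVector",
    "PerturbationLine",
    "QuadraticConstraint",
    "contrast_vector",
    "perturbation_line",
    "pairwise_coeffs",
    "weighted_coeffs",
    "build_constraints",
    "truncation_region",
]


@dataclass(frozen=True)
class ContrastVector:
    """Observation weights encoding a difference between two cluster means.

    ``nu`` has entries ``1/n1`` on cluster ``k1``, ``-1/n2`` on cluster
    ``k2`` and zero elsewhere, so ``x.T @ nu`` is the difference between the
    two cluster centroids.
    """

    nu: np.ndarray
    pair: tuple
    n1: int
    n2: int

    @property
    def sq_norm(self) -> float:
        """``||nu||_2^2 = 1/n1 + 1/n2``."""
        return 1.0 / self.n1 + 1.0 / self.n2

    @property
    def norm(self) -> float:
        return float(np.sqrt(self.sq_norm))


def contrast_vector(labels, k1: int, k2: int) -> ContrastVector:
    labels = np.asarray(labels)
    if k1 == k2:
        raise ValueError("the two cluster labels must differ")
    in1 = labels == k1
    in2 = labels == k2
    n1, n2 = int(in1.sum()), int(in2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"cluster pair ({k1}, {k2}) has an empty member")
    nu = np.zeros(labels.shape[0])
    nu[in1] = 1.0 / n1
    nu[in2] = -1.0 / n2
    return ContrastVector(nu=nu, pair=(int(k1), int(k2)), n1=n1, n2=n2)


@dataclass(frozen=True)
class PerturbationLine:
    """Affine family ``x'(phi)_i = base_i + phi * row_scales_i * direction``.

    ``base`` is the projection of the data onto the orthogonal complement of
    the contrast vector, ``row_scales = nu / ||nu||^2``, and ``direction``
    is the (feature-space) unit vector along the observed centroid
    difference — or, in the known-covariance variant, that unit vector
    premultiplied by the covariance square root, in which case it is not of
    unit norm.  ``phi_obs`` is the parameter value at which the family
    reproduces the observed data exactly.
    """

    base: np.ndarray
    row_scales: np.ndarray
    direction: np.ndarray
    phi_obs: float

    def at(self, phi: float) -> np.ndarray:
        return self.base + phi * np.outer(self.row_scales, self.direction)

    def at_batch(self, phis) -> np.ndarray:
        """Stack of perturbed datasets, shape (len(phis), n, q)."""
        phis = np.asarray(phis, dtype=float)
        return self.base[None] + phis[:, None, None] * np.outer(
            self.row_scales, self.direction
        )[None]


def perturbation_line(x, nu: ContrastVector, direction=None) -> PerturbationLine:
    """Build the perturbation family for data ``x`` and contrast ``nu``.

    With the default ``direction`` (the unit vector along ``x.T @ nu``) the
    family moves the tested centroids apart while fixing everything
    orthogonal to the contrast, and ``at(phi_obs)`` returns ``x`` exactly
    with ``phi_obs = ||x.T @ nu||_2``.
    """
    x = np.asarray(x, dtype=float)
    xv = x.T @ nu.nu
    stat = float(np.linalg.norm(xv))
    if direction is None:
        if stat == 0.0:
            direction = np.zeros(x.shape[1])
        else:
            direction = xv / stat
    direction = np.asarray(direction, dtype=float)
    dnorm = float(np.linalg.norm(direction))
    if dnorm == 0.0 and stat > 0.0:
        raise ValueError("zero direction with a nonzero observed statistic")
    scales = nu.nu / nu.sq_norm
    base = x - np.outer(scales, xv)  # projection onto the complement of nu
    phi_obs = stat / dnorm if dnorm > 0 else 0.0
    return PerturbationLine(
        base=base, row_scales=scales, direction=direction, phi_obs=phi_obs
    )


def pairwise_coeffs(x, nu: ContrastVector, direction, i: int, j: int):
    """Coefficients (a, b, g) with ``||x'(phi)_i - x'(phi)_j||^2 = a phi^2 + b phi + g``.

    For a unit ``direction`` these are the closed-form row-pair coefficients
    ``a = {(nu_i - nu_j)/||nu||^2}^2`` etc.; the general form multiplies the
    leading coefficient by ``||direction||^2``.
    """
    if i == j:
        raise ValueError("row indices must differ")
    line = perturbation_line(x, nu, direction)
    d = line.base[i] - line.base[j]
    ds = line.row_scales[i] - line.row_scales[j]
    v = line.direction
    return (
        ds * ds * float(v @ v),
        2.0 * ds * float(d @ v),
        float(d @ d),
    )


def weighted_coeffs(x, nu: ContrastVector, direction, i: int, weights, tol: float = 1e-8):
    """Coefficients of the squared distance from row ``i`` of ``x'(phi)`` to a
    fixed weighted mean of the rows of ``x'(phi)``.

    ``weights`` must be non-negative and sum to one (within ``tol``) — the
    within-cluster mean weights of the original run.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < -tol) or abs(weights.sum() - 1.0) > tol:
        raise ValueError("weights must be non-negative and sum to 1")
    line = perturbation_line(x, nu, direction)
    d = line.base[i] - weights @ line.base
    ds = line.row_scales[i] - float(weights @ line.row_scales)
    v = line.direction
    return (
        ds * ds * float(v @ v),
        2.0 * ds * float(d @ v),
        float(d @ d),
    )


@dataclass(frozen=True)
class QuadraticConstraint:
    """One inequality ``a*phi^2 + b*phi + c <= 0`` of the conditioning event.

    ``provenance = (t, i, k)``: at iteration ``t``, observation ``i`` must
    be at least as close to its assigned centroid as to competitor ``k``.
    """

    a: float
    b: float
    c: float
    provenance: tuple


def _weights_matrix(labels: np.ndarray, K: int) -> np.ndarray:
    """K x n matrix of within-cluster mean weights implied by ``labels``."""
    counts = np.bincount(labels, minlength=K)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise EmptyClusterError(int(empty[0]), iteration=-1)
    W = np.zeros((K, labels.shape[0]))
    W[labels, np.arange(labels.shape[0])] = 1.0 / counts[labels]
    return W


def _round_coefficients(line: PerturbationLine, cbase: np.ndarray, cscales: np.ndarray):
    """Quadratic coefficients of ||x'(phi)_i - centroid_k(phi)||^2 for all (i, k).

    Centroid k is itself affine in phi: ``cbase_k + phi * cscales_k * v``.
    Returns three (n, K) arrays.
    """
    v = line.direction
    v2 = float(v @ v)
    ds = line.row_scales[:, None] - cscales[None, :]          # (n, K)
    bv = line.base @ v                                        # (n,)
    cv = cbase @ v                                            # (K,)
    bn = np.einsum("ij,ij->i", line.base, line.base)          # (n,)
    cn = np.einsum("kj,kj->k", cbase, cbase)                  # (K,)
    cross = line.base @ cbase.T                               # (n, K)
    A = ds * ds * v2
    B = 2.0 * ds * (bv[:, None] - cv[None, :])
    C = bn[:, None] + cn[None, :] - 2.0 * cross
    return A, B, C


def _constraint_rounds(x: np.ndarray, trace: ClusterTrace, line: PerturbationLine):
    """Yield per-round (A, B, C) arrays of assigned-vs-competitor differences.

    Round 0 compares against the perturbed rows at the sampled initial
    indices; round t >= 1 against the fixed-weight centroids implied by the
    original assignment row t - 1.
    """
    for t in range(trace.T + 1):
        if t == 0:
            cbase = line.base[trace.init_indices]
            cscales = line.row_scales[trace.init_indices]
        else:
            W = _weights_matrix(trace.assignments[t - 1], trace.K)
            cbase = W @ line.base
            cscales = W @ line.row_scales
        A, B, C = _round_coefficients(line, cbase, cscales)
        labels = trace.assignments[t]
        rows = np.arange(trace.n)
        yield t, (
            A[rows, labels][:, None] - A,
            B[rows, labels][:, None] - B,
            C[rows, labels][:, None] - C,
        )


def build_constraints(x, trace: ClusterTrace, nu: ContrastVector, direction=None):
    """All n*K*(T+1) quadratic constraints defining the conditioning set.

    Constraints with ``k`` equal to the assigned cluster are identically
    zero and returned as such.
    """
    x = np.asarray(x, dtype=float)
    line = perturbation_line(x, nu, direction)
    out = []
    for t, (dA, dB, dC) in _constraint_rounds(x, trace, line):
        for i in range(trace.n):
            for k in range(trace.K):
                out.append(
                    QuadraticConstraint(
                        float(dA[i, k]), float(dB[i, k]), float(dC[i, k]), (t, i, k)
                    )
                )
    return out


def _violation_intervals(a, b, c, tol: float):
    """Open intervals where a*phi^2 + b*phi + c > 0, vectorized.

    Inputs are per-constraint coefficient arrays, already normalized to unit
    max magnitude.  Returns an (m, 2) array of interval bounds (a constraint
    violated everywhere yields (-inf, inf)).
    """
    rows = []
    quad = np.abs(a) > tol
    lin = ~quad & (np.abs(b) > tol)
    const = ~quad & ~lin

    if np.any(const & (c > tol)):
        return np.array([[-np.inf, np.inf]])

    if np.any(lin):
        r = -c[lin] / b[lin]
        pos = b[lin] > 0
        rows.append(np.column_stack([r[pos], np.full(pos.sum(), np.inf)]))
        rows.append(np.column_stack([np.full((~pos).sum(), -np.inf), r[~pos]]))

    if np.any(quad):
        aq, bq, cq = a[quad], b[quad], c[quad]
        disc = bq * bq - 4.0 * aq * cq
        # convex constraints hold at phi_obs, so a negative discriminant
        # there can only be rounding noise: clamp to a double root
        disc = np.where((aq > 0) & (disc < 0), 0.0, disc)
        sq = np.sqrt(np.maximum(disc, 0.0))
        r1 = (-bq - sq) / (2.0 * aq)
        r2 = (-bq + sq) / (2.0 * aq)
        lo, hi = np.minimum(r1, r2), np.maximum(r1, r2)
        pos = aq > 0
        rows.append(np.column_stack([np.full(pos.sum(), -np.inf), lo[pos]]))
        rows.append(np.column_stack([hi[pos], np.full(pos.sum(), np.inf)]))
        neg = ~pos & (disc > 0)
        rows.append(np.column_stack([lo[neg], hi[neg]]))

    if not rows:
        return np.empty((0, 2))
    return np.vstack(rows)


def truncation_region(
    x,
    trace: ClusterTrace,
    nu: ContrastVector,
    direction=None,
    tol: float = DEFAULT_TOL,
) -> IntervalUnion:
    """The conditioning set S_T, intersected with the non-negative half-line.

    Solves all constraint quadratics at once: the feasible set is the
    complement of the union of the per-constraint violation intervals, and
    that union needs only one sort of the O(nKT) endpoints.  The reference
    distribution of phi is a scaled chi, supported on [0, inf), so the
    negative part of S_T is discarded.  The observed statistic is always a
    member.
    """
    x = np.asarray(x, dtype=float)
    line = perturbation_line(x, nu, direction)
    violations = []
    for _t, (dA, dB, dC) in _constraint_rounds(x, trace, line):
        a, b, c = dA.ravel(), dB.ravel(), dC.ravel()
        scale = np.maximum.reduce([np.abs(a), np.abs(b), np.abs(c)])
        live = scale > tol  # drops self-comparisons and vanishing constraints
        if not np.any(live):
            continue
        s = scale[live]
        violations.append(_violation_intervals(a[live] / s, b[live] / s, c[live] / s, tol))
    if violations:
        viol = IntervalUnion.from_intervals(np.vstack(violations), tol)
        region = viol.complement(tol).clip_nonnegative(tol)
    else:
        region = IntervalUnion(np.array([[0.0, np.inf]]))
    guard = 1e-7 * (1.0 + abs(line.phi_obs))
    if not region.contains(line.phi_obs, guard):
        raise RuntimeError(
            "observed statistic fell outside the computed conditioning set; "
            "this indicates a numerically degenerate clustering (e.g. exact ties)"
        )
    return region
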