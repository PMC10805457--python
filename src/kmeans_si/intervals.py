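"""Finite unions of real intervals, and quadratic-inequality solving.

The conditioning set of the selective test is an intersection of O(nKT)
quadratic inequalities in the perturbation coordinate phi.  Each inequality's
solution set is a union of at most two intervals; the intersection of the
whole family is computed by one sort over all endpoints (union the
complements, then complement back), which matches the near-linear operation
count the analytic characterization admits.

All constraints are non-strict, so every finite endpoint is attained;
intervals are stored closed at finite endpoints and open at infinite ones.
Endpoint comparisons use an absolute tolerance (default 1e-10) — under the
continuous sampling model, boundary ties have probability zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntervalUnion", "solve_quadratic_inequality", "intersect_all", "DEFAULT_TOL"]

DEFAULT_TOL = 1e-10

_INF = np.inf


def _canonicalize(bounds: np.ndarray, tol: float) -> np.ndarray:
    """Sort, drop empty, and merge overlapping/touching intervals."""
    if bounds.size == 0:
        return bounds.reshape(0, 2)
    bounds = bounds[bounds[:, 1] >= bounds[:, 0] - tol]
    if bounds.size == 0:
        return bounds.reshape(0, 2)
    bounds = bounds[np.argsort(bounds[:, 0], kind="stable")]
    merged = [list(bounds[0])]
    for lo, hi in bounds[1:]:
        if lo <= merged[-1][1] + tol:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return np.array(merged, dtype=float)


@dataclass(frozen=True)
class IntervalUnion:
    """A finite union of disjoint real intervals in canonical form.

    ``bounds`` is an (m, 2) array of ``[lo, hi]`` rows, sorted and pairwise
    disjoint.  Finite endpoints are closed, infinite ones open.
    """

    bounds: np.ndarray

    @classmethod
    def from_intervals(cls, intervals, tol: float = DEFAULT_TOL) -> "IntervalUnion":
        return cls(_canonicalize(np.asarray(intervals, dtype=float).reshape(-1, 2), tol))

    @classmethod
    def real_line(cls) -> "IntervalUnion":
        return cls(np.array([[-_INF, _INF]]))

    @classmethod
    def empty(cls) -> "IntervalUnion":
        return cls(np.empty((0, 2)))

    @property
    def is_empty(self) -> bool:
        return self.bounds.shape[0] == 0

    def __iter__(self):
        return iter(map(tuple, self.bounds))

    def contains(self, x: float, tol: float = DEFAULT_TOL) -> bool:
        return bool(
            np.any((self.bounds[:, 0] - tol <= x) & (x <= self.bounds[:, 1] + tol))
        )

    def complement(self, tol: float = DEFAULT_TOL) -> "IntervalUnion":
        """Closure of the complement in the real line."""
        if self.is_empty:
            return IntervalUnion.real_line()
        pts = np.concatenate([[-_INF], self.bounds.ravel(), [_INF]])
        gaps = pts.reshape(-1, 2)
        keep = gaps[:, 1] > gaps[:, 0] + tol
        # keep unbounded gaps even when the neighbouring endpoint is infinite
        keep |= np.isinf(gaps).any(axis=1) & (gaps[:, 1] > gaps[:, 0])
        return IntervalUnion(_canonicalize(gaps[keep], tol))

    def intersect(self, other: "IntervalUnion", tol: float = DEFAULT_TOL) -> "IntervalUnion":
        if self.is_empty or other.is_empty:
            return IntervalUnion.empty()
        out = []
        i = j = 0
        a, b = self.bounds, other.bounds
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi >= lo - tol:
                out.append((lo, hi))
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalUnion.from_intervals(out, tol)

    def clip_nonnegative(self, tol: float = DEFAULT_TOL) -> "IntervalUnion":
        return self.intersect(IntervalUnion(np.array([[0.0, _INF]])), tol)

    def to_json_obj(self) -> list:
        out = []
        for lo, hi in self.bounds:
            out.append(
                {
                    "lo": None if np.isneginf(lo) else float(lo),
                    "hi": None if np.isposinf(hi) else float(hi),
                    "lo_closed": bool(np.isfinite(lo)),
                    "hi_closed": bool(np.isfinite(hi)),
                }
            )
        return out

    @classmethod
    def from_json_obj(cls, obj) -> "IntervalUnion":
        rows = [
            [
                -_INF if iv["lo"] is None else iv["lo"],
                _INF if iv["hi"] is None else iv["hi"],
            ]
            for iv in obj
        ]
        return cls(np.asarray(rows, dtype=float).reshape(-1, 2))


def solve_quadratic_inequality(
    a: float, b: float, c: float, tol: float = DEFAULT_TOL
) -> IntervalUnion:
    """Exact solution set of ``a*phi^2 + b*phi + c <= 0`` over the reals.

    Coefficients whose magnitude is below ``tol`` (after normalizing by the
    largest magnitude among the three) are treated as zero, so a numerically
    vanishing polynomial yields the whole line.
    """
    scale = max(abs(a), abs(b), abs(c))
    if scale <= tol:
        return IntervalUnion.real_line()
    a, b, c = a / scale, b / scale, c / scale
    if abs(a) <= tol:
        if abs(b) <= tol:
            return IntervalUnion.real_line() if c <= tol else IntervalUnion.empty()
        r = -c / b
        return IntervalUnion.from_intervals(
            [(-_INF, r)] if b > 0 else [(r, _INF)], tol
        )
    disc = b * b - 4 * a * c
    if disc < 0:
        # no real roots: the parabola never touches zero
        return IntervalUnion.empty() if a > 0 else IntervalUnion.real_line()
    sq = float(np.sqrt(disc))
    r1, r2 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
    r1, r2 = min(r1, r2), max(r1, r2)
    if a > 0:
        return IntervalUnion.from_intervals([(r1, r2)], tol)
    return IntervalUnion.from_intervals([(-_INF, r1), (r2, _INF)], tol)


def intersect_all(sets, tol: float = DEFAULT_TOL) -> IntervalUnion:
    """Intersection of many interval unions by one endpoint sort.

    The intersection is the complement of the union of the complements; the
    union of all complement intervals is computed by sorting their left
    endpoints once, so the cost is O(m log m) in the total interval count m.
    An empty collection yields the whole real line.
    """
    comps = []
    for s in sets:
        comp = s.complement(tol)
        if not comp.is_empty:
            comps.append(comp.bounds)
    if not comps:
        return IntervalUnion.real_line()
    union = _canonicalize(np.vstack(comps), tol)
    return IntervalUnion(union).complement(tol)
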