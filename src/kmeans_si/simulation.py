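"""Synthetic data, calibration/power experiments, and brute-force oracles.

The generators reproduce the study conditions of the selective test's
evaluation: matrix-normal data with independent rows and spherical noise,
either with zero mean (global null — every cluster-pair null hypothesis
true) or with three equidistant population clusters whose pairwise mean
separation is ``delta``.

Two brute-force oracles re-derive, by direct re-clustering of the perturbed
data, the quantities the analytic machinery computes in closed form: the
conditioning-set membership of a grid of perturbation values, and the
selective p-value by rejection sampling.  They exist so that the analytic
path can be validated against an implementation that shares nothing with it
beyond the assignment rule itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyClusterError, ZeroMassRegionError
from .inference import (
    TruncatedChiSpec,
    naive_p,
    sigma_med,
    sigma_sample,
    truncated_chi_survival,
)
from .kmeans import ClusterTrace, lloyd_with_trace, sample_initial_centroids
from .truncation import (
    ContrastVector,
    contrast_vector,
    perturbation_line,
    truncation_region,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "gen_global_null",
    "gen_three_cluster",
    "is_true_pair",
    "type1_experiment",
    "power_experiment",
    "grid_oracle_region",
    "mc_oracle_p",
]

SELECTIVE_METHODS = ("selective", "selective_med", "selective_sample")
ALL_METHODS = ("naive",) + SELECTIVE_METHODS


# ---------------------------------------------------------------------------
# generators


def gen_global_null(n: int, q: int, sigma: float, rng) -> np.ndarray:
    """i.i.d. Normal(0, sigma^2) data matrix: no mean structure at all."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return sigma * rng.standard_normal((n, q))


def gen_three_cluster(n: int, q: int, delta: float, sigma: float, rng):
    """Three equal-sized clusters with all pairwise mean distances ``delta``.

    The first and last thirds sit at ``-delta/2`` and ``+delta/2`` on the
    first coordinate; the middle third sits at ``sqrt(3) * delta / 2`` on
    the last coordinate, which makes the three population means the vertices
    of an equilateral triangle with side ``delta``.  Returns the data matrix
    and the true partition (three index blocks of size n/3).
    """
    if n % 3 != 0:
        raise ValueError("n must be divisible by 3")
    if q < 2:
        raise ValueError("need q >= 2 for the equidistant three-cluster design")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    third = n // 3
    mu = np.zeros((n, q))
    mu[:third, 0] = -delta / 2.0
    mu[third : 2 * third, q - 1] = np.sqrt(3.0) * delta / 2.0
    mu[2 * third :, 0] = delta / 2.0
    x = mu + sigma * rng.standard_normal((n, q))
    truth = [np.arange(third), np.arange(third, 2 * third), np.arange(2 * third, n)]
    return x, truth


def is_true_pair(est_pair_members, truth) -> bool:
    """Do both estimated clusters coincide exactly with true clusters?"""
    truth_sets = {frozenset(map(int, block)) for block in truth}
    return all(frozenset(map(int, c)) in truth_sets for c in est_pair_members)


# ---------------------------------------------------------------------------
# experiment scaffolding


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one calibration or power experiment.

    ``reps`` Monte Carlo replicates of n x q matrix-normal data with noise
    level ``sigma``; k-means with ``K`` clusters; tests at level ``alpha``
    on a uniformly random cluster pair.  ``delta`` is the cluster-mean
    separation of the three-cluster alternative and is ignored under the
    global null.
    """

    reps: int
    n: int
    q: int
    sigma: float = 1.0
    K: int = 3
    delta: Optional[float] = None
    alpha: float = 0.05
    seed: Optional[int] = None
    max_iter: int = 300

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.delta is not None and self.n % 3 != 0:
            raise ValueError("the three-cluster design needs n divisible by 3")


@dataclass
class SimulationResult:
    """Tidy per-replicate p-values plus experiment-level summaries.

    ``table`` has one row per (replicate, method); ``conditional_power``
    entries are None when no replicate recovered the true clusters.
    """

    config: SimulationConfig
    table: pd.DataFrame
    rejection_rates: dict
    detection_probability: Optional[float] = None
    conditional_power: Optional[dict] = None
    redraws: int = 0

    def summary(self) -> dict:
        out = {
            "reps": int(self.config.reps),
            "alpha": self.config.alpha,
            "rejection_rates": self.rejection_rates,
            "redraws": self.redraws,
        }
        if self.detection_probability is not None:
            out["detection_probability"] = self.detection_probability
            out["conditional_power"] = self.conditional_power
        return out


def _replicate_pvalues(x, K, pair, sigma, init_indices, max_iter):
    """All four p-values for one dataset, sharing a single conditioning set."""
    trace = lloyd_with_trace(x, K, init_indices, max_iter=max_iter)
    labels = trace.final_labels
    counts = np.bincount(labels, minlength=K)
    if np.any(counts == 0):
        raise EmptyClusterError(int(np.flatnonzero(counts == 0)[0]), trace.T)
    nu = contrast_vector(labels, *pair)
    stat = float(np.linalg.norm(x.T @ nu.nu))
    region = truncation_region(x, trace, nu)
    q = x.shape[1]
    scales = {
        "selective": sigma,
        "selective_med": sigma_med(x),
        "selective_sample": sigma_sample(x),
    }
    pvals = {"naive": naive_p(stat, q, sigma * nu.norm)}
    for name, s in scales.items():
        spec = TruncatedChiSpec(df=q, scale=s * nu.norm, region=region)
        pvals[name] = truncated_chi_survival(stat, spec)
    return pvals, trace, labels


def _random_pair(rng, K):
    pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]
    return pairs[rng.integers(len(pairs))]


def _run_experiment(cfg: SimulationConfig, draw):
    """Shared replicate loop: ``draw(rng)`` yields (x, truth-or-None)."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    redraws = 0
    rep = 0
    while rep < cfg.reps:
        x, truth = draw(rng)
        init = sample_initial_centroids(x, cfg.K, rng)
        pair = _random_pair(rng, cfg.K)
        try:
            pvals, trace, labels = _replicate_pvalues(
                x, cfg.K, pair, cfg.sigma, init, cfg.max_iter
            )
        except EmptyClusterError:
            redraws += 1
            continue
        detected = None
        if truth is not None:
            members = (np.flatnonzero(labels == pair[0]), np.flatnonzero(labels == pair[1]))
            detected = is_true_pair(members, truth)
        for method, p in pvals.items():
            rows.append(
                {
                    "rep": rep,
                    "method": method,
                    "p": p,
                    "rejected": p <= cfg.alpha,
                    "detected": detected,
                }
            )
        rep += 1
    return pd.DataFrame(rows), redraws


def type1_experiment(cfg: SimulationConfig) -> SimulationResult:
    """Global-null calibration: rejection rates of all four p-values.

    Under the null every pair hypothesis is true, so the selective tests'
    rejection fractions at ``alpha`` estimate their selective Type I error;
    the naive test's fraction exhibits its anti-conservativeness.
    """
    table, redraws = _run_experiment(
        cfg, lambda rng: (gen_global_null(cfg.n, cfg.q, cfg.sigma, rng), None)
    )
    rates = {
        m: float(table.loc[table.method == m, "rejected"].mean()) for m in ALL_METHODS
    }
    return SimulationResult(cfg, table, rates, redraws=redraws)


def power_experiment(cfg: SimulationConfig) -> SimulationResult:
    """Three-cluster alternative: detection probability and conditional power.

    Detection probability is the fraction of replicates in which both tested
    clusters exactly coincide with true clusters; conditional power is the
    rejection rate among those replicates (None when there are none).
    """
    if cfg.delta is None:
        raise ValueError("power experiment requires delta")
    table, redraws = _run_experiment(
        cfg,
        lambda rng: gen_three_cluster(cfg.n, cfg.q, cfg.delta, cfg.sigma, rng),
    )
    rates = {
        m: float(table.loc[table.method == m, "rejected"].mean()) for m in ALL_METHODS
    }
    per_rep = table[table.method == "selective"]
    detection = float(per_rep["detected"].mean())
    cond_power = {}
    for m in SELECTIVE_METHODS:
        sub = table[(table.method == m) & (table.detected == True)]  # noqa: E712
        cond_power[m] = float(sub["rejected"].mean()) if len(sub) else None
    return SimulationResult(
        cfg,
        table,
        rates,
        detection_probability=detection,
        conditional_power=cond_power,
        redraws=redraws,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def grid_oracle_region(
    x,
    trace: ClusterTrace,
    nu: ContrastVector,
    direction=None,
    grid=None,
    batch: int = 4096,
) -> np.ndarray:
    """Conditioning-set membership of each grid value, by re-clustering.

    For each perturbation value, rebuild the perturbed dataset, re-run the
    assignment/update recursion from the original initial indices with the
    same lowest-index tie-break for exactly T iterations, and report whether
    every assignment row reproduces the trace.  Once a row fails to match,
    the value is excluded (subsequent rounds are not consulted: the event
    requires *all* rows to match).
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    line = perturbation_line(x, nu, direction)
    weights = []
    for t in range(1, trace.T + 1):
        labels = trace.assignments[t - 1]
        counts = np.bincount(labels, minlength=trace.K)
        W = np.zeros((trace.K, trace.n))
        W[labels, np.arange(trace.n)] = 1.0 / counts[labels]
        weights.append(W)

    out = np.zeros(grid.shape[0], dtype=bool)
    for start in range(0, grid.shape[0], batch):
        phis = grid[start : start + batch]
        X = line.at_batch(phis)  # (B, n, q)
        ok = np.ones(phis.shape[0], dtype=bool)
        for t in range(trace.T + 1):
            if not ok.any():
                break
            if t == 0:
                cents = X[:, trace.init_indices, :]
            else:
                cents = np.einsum("kn,bnq->bkq", weights[t - 1], X)
            d2 = np.square(X[:, :, None, :] - cents[:, None, :, :]).sum(axis=3)
            lab = d2.argmin(axis=2)
            ok &= (lab == trace.assignments[t][None, :]).all(axis=1)
        out[start : start + batch] = ok
    return out


def mc_oracle_p(
    x,
    trace: ClusterTrace,
    nu: ContrastVector,
    sigma: float,
    draws: int,
    rng,
    batch: int = 20000,
):
    """Rejection-sampling estimate of the selective p-value, with its SE.

    Draw the perturbation coordinate from its unconditional scaled chi
    distribution, keep the draws whose re-clustering reproduces the trace,
    and report the tail fraction at the observed statistic among the kept
    draws together with its binomial standard error.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    q = x.shape[1]
    scale = sigma * nu.norm
    phis = scale * np.sqrt(rng.chisquare(q, size=draws))
    accept = grid_oracle_region(x, trace, nu, grid=phis, batch=batch)
    n_acc = int(accept.sum())
    if n_acc == 0:
        raise ZeroMassRegionError(
            "no rejection-sampling draws landed in the conditioning set; "
            "increase the number of draws"
        )
    stat = float(np.linalg.norm(x.T @ nu.nu))
    est = float(np.mean(phis[accept] >= stat))
    se = float(np.sqrt(est * (1.0 - est) / n_acc))
    return est, se
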