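"""Exact p-values for a difference in means between two k-means clusters.

Under the matrix-normal model (independent Gaussian rows, spherical feature
covariance), the statistic ``||x.T @ nu||_2`` — the Euclidean length of the
difference between the two tested cluster centroids — follows a scaled chi
distribution with q degrees of freedom under the null.  The *naive* p-value
is its unconditional tail probability and is anti-conservative, because the
contrast was chosen by clustering the same data.  The *selective* p-value
conditions on the event that every intermediate assignment of the k-means
run is reproduced, which truncates the reference distribution to the set
computed in :mod:`kmeans_si.truncation`.

Extensions: a known non-spherical feature covariance (either whiten first
and cluster the transformed data, or cluster the raw data and condition
directly), and plug-in noise-level estimators for unknown sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .errors import NotPositiveDefiniteError, ZeroMassRegionError
from .intervals import IntervalUnion
from .kmeans import ClusterTrace, lloyd_with_trace, sample_initial_centroids
from .truncation import ContrastVector, contrast_vector, truncation_region

__all__ = [
    "TruncatedChiSpec",
    "TestResult",
    "naive_p",
    "truncated_chi_survival",
    "selective_test",
    "selective_test_plugin",
    "whitened_selective_test",
    "cov_selective_test",
    "sigma_med",
    "sigma_sample",
    "inv_sqrt_psd",
    "ridge_whitening_estimate",
]


# ---------------------------------------------------------------------------
# truncated chi survival machinery


@dataclass(frozen=True)
class TruncatedChiSpec:
    """Reference distribution: ``scale * chi_df`` truncated to ``region``."""

    df: int
    scale: float
    region: IntervalUnion


def _chi_logsf(x, df: int):
    """log survival function of chi_df, finite even in the deep tail.

    scipy's log-survival underflows to -inf once the tail mass drops below
    the smallest double; beyond that point the upper incomplete gamma
    expansion ``sf(x) ~ x^(df-2) exp(-x^2/2) / (2^(df/2-1) Gamma(df/2))``
    supplies the leading-order value.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.atleast_1d(stats.chi.logsf(x, df))
    x = np.atleast_1d(x)
    deep = np.isneginf(out) & np.isfinite(x) & (x > 0)
    if np.any(deep):
        xd = x[deep]
        out[deep] = (
            (df - 2.0) * np.log(xd)
            - 0.5 * xd * xd
            - (df / 2.0 - 1.0) * np.log(2.0)
            - gammaln(df / 2.0)
        )
    return out


def _log_mass(region: IntervalUnion, df: int, scale: float) -> float:
    """log P(scale * chi_df falls in ``region``), by compensated per-interval
    accumulation in log space."""
    if region.is_empty:
        return -np.inf
    lo = np.maximum(region.bounds[:, 0], 0.0) / scale
    hi = region.bounds[:, 1] / scale
    keep = hi > lo
    if not np.any(keep):
        return -np.inf
    lo, hi = lo[keep], hi[keep]
    ls_lo = _chi_logsf(lo, df)
    ls_hi = np.where(np.isposinf(hi), -np.inf, _chi_logsf(np.where(np.isposinf(hi), 1.0, hi), df))
    # log(SF(lo) - SF(hi)) = logsf(lo) + log1p(-exp(logsf(hi) - logsf(lo)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = ls_lo + np.log1p(-np.exp(ls_hi - ls_lo))
    terms = np.where(np.isnan(terms), -np.inf, terms)
    return float(logsumexp(terms))


def naive_p(stat: float, df: int, scale: float) -> float:
    """Unconditional tail probability of the scaled chi distribution."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return float(stats.chi.sf(stat / scale, df))


def truncated_chi_survival(stat: float, spec: TruncatedChiSpec) -> float:
    """P(phi >= stat | phi in region) for phi ~ scale * chi_df.

    Evaluated per interval as differences of survival functions accumulated
    in log space, so that regions far in the tail (where both the numerator
    and denominator masses underflow as plain doubles) still yield a finite,
    accurate ratio.
    """
    if spec.region.is_empty:
        raise ZeroMassRegionError("truncation region is empty")
    upper = spec.region.intersect(IntervalUnion(np.array([[stat, np.inf]])))
    log_num = _log_mass(upper, spec.df, spec.scale)
    log_den = _log_mass(spec.region, spec.df, spec.scale)
    if not np.isfinite(log_den):
        raise ZeroMassRegionError(
            "truncation region carries no numerically resolvable mass; "
            "use the Monte Carlo estimator (simulation.mc_oracle_p) instead"
        )
    if not np.isfinite(log_num):
        return 0.0
    return float(min(1.0, np.exp(log_num - log_den)))


# ---------------------------------------------------------------------------
# test results


@dataclass(frozen=True)
class TestResult:
    """Outcome of one selective test of a cluster-pair mean difference."""

    stat: float
    p_selective: float
    p_naive: float
    region: IntervalUnion
    sigma: float
    sigma_source: str
    pair: tuple
    K: int
    T: int
    converged: bool
    n: int
    q: int
    seed: object = None


def _run_clustering(x, K, pair, seed=None, max_iter=300, init_indices=None):
    x = np.asarray(x, dtype=float)
    if init_indices is None:
        rng = np.random.default_rng(seed)
        init_indices = sample_initial_centroids(x, K, rng)
    trace = lloyd_with_trace(x, K, init_indices, max_iter=max_iter)
    k1, k2 = pair
    labels = trace.final_labels
    if k1 not in labels or k2 not in labels:
        raise ValueError(f"cluster pair {pair} not present in the final assignment")
    nu = contrast_vector(labels, k1, k2)
    return x, trace, nu


def _assemble(x, trace, nu, stat, region, scale, sigma, sigma_source, seed):
    spec = TruncatedChiSpec(df=x.shape[1], scale=scale, region=region)
    return TestResult(
        stat=stat,
        p_selective=truncated_chi_survival(stat, spec),
        p_naive=naive_p(stat, x.shape[1], scale),
        region=region,
        sigma=sigma,
        sigma_source=sigma_source,
        pair=nu.pair,
        K=trace.K,
        T=trace.T,
        converged=trace.converged,
        n=x.shape[0],
        q=x.shape[1],
        seed=seed,
    )


def selective_test(
    x, K: int, pair, sigma: float, seed=None, max_iter: int = 300, init_indices=None
) -> TestResult:
    """Selective test for a difference in means between two estimated clusters.

    Runs traced k-means on ``x``, forms the contrast for the requested
    cluster pair, computes the conditioning set along the perturbation of
    the centroid difference, and evaluates the truncated chi tail
    probability with known noise level ``sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x, trace, nu = _run_clustering(x, K, pair, seed, max_iter, init_indices)
    stat = float(np.linalg.norm(x.T @ nu.nu))
    region = truncation_region(x, trace, nu)
    return _assemble(x, trace, nu, stat, region, sigma * nu.norm, sigma, "known", seed)


def selective_test_plugin(
    x, K: int, pair, estimator: str = "med", seed=None, max_iter: int = 300,
    init_indices=None,
) -> TestResult:
    """Selective test with a plug-in noise-level estimate.

    The conditioning set does not involve sigma, so only the reference scale
    changes relative to the known-sigma test.
    """
    x = np.asarray(x, dtype=float)
    if estimator == "med":
        sig = sigma_med(x)
    elif estimator == "sample":
        sig = sigma_sample(x)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; expected 'med' or 'sample'")
    if sig == 0:
        raise ValueError("plug-in noise estimate is zero; data are degenerate")
    x, trace, nu = _run_clustering(x, K, pair, seed, max_iter, init_indices)
    stat = float(np.linalg.norm(x.T @ nu.nu))
    region = truncation_region(x, trace, nu)
    return _assemble(x, trace, nu, stat, region, sig * nu.norm, sig, estimator, seed)


def whitened_selective_test(
    x, Sigma, K: int, pair, seed=None, max_iter: int = 300, init_indices=None
) -> TestResult:
    """Whiten by the inverse symmetric covariance square root, then test.

    Clustering is performed on the transformed data, so the hypothesis
    concerns the whitened cluster means.
    """
    M = inv_sqrt_psd(Sigma)
    xw = np.asarray(x, dtype=float) @ M  # M symmetric: row-wise M @ x_i
    return selective_test(xw, K, pair, sigma=1.0, seed=seed, max_iter=max_iter,
                          init_indices=init_indices)


def cov_selective_test(
    x, Sigma, K: int, pair, seed=None, max_iter: int = 300, init_indices=None
) -> TestResult:
    """Known-covariance selective test with clustering on the raw data.

    The statistic is ``||Sigma^{-1/2} x.T nu||_2`` with reference
    distribution ``||nu||_2 * chi_q``; the perturbation direction in data
    space is the covariance square root applied to the whitened centroid
    difference, which keeps every row affine in phi so the same conditioning
    machinery applies.
    """
    x, trace, nu = _run_clustering(x, K, pair, seed, max_iter, init_indices)
    Minv = inv_sqrt_psd(Sigma)
    Mhalf = _sqrt_psd(Sigma)
    w = Minv @ (x.T @ nu.nu)
    stat = float(np.linalg.norm(w))
    direction = Mhalf @ (w / stat) if stat > 0 else np.zeros(x.shape[1])
    region = truncation_region(x, trace, nu, direction=direction)
    return _assemble(x, trace, nu, stat, region, nu.norm, 1.0, "covariance", seed)


# ---------------------------------------------------------------------------
# noise-level estimators and covariance utilities


def sigma_med(x) -> float:
    """Median-based noise-level estimate, robust to sparse mean structure.

    Subtract each column's median, square the residuals, take the overall
    median, and normalize by the median of the chi-squared distribution with
    one degree of freedom (evaluated from its quantile function).
    """
    x = np.asarray(x, dtype=float)
    resid = x - np.median(x, axis=0, keepdims=True)
    med = float(np.median(np.square(resid)))
    if med == 0.0:
        warnings.warn("all residuals are zero; returning sigma = 0", stacklevel=2)
        return 0.0
    m_chi2 = float(stats.chi2.ppf(0.5, df=1))
    return float(np.sqrt(med / m_chi2))


def sigma_sample(x) -> float:
    """Column-mean-centered root mean square with divisor nq - q."""
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    if n < 2:
        raise ValueError("need at least two observations")
    resid = x - x.mean(axis=0, keepdims=True)
    return float(np.sqrt(np.square(resid).sum() / (n * q - q)))


def _eigh_psd(Sigma, tol: float = 1e-10):
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise NotPositiveDefiniteError(f"expected a square matrix, got {Sigma.shape}")
    if not np.allclose(Sigma, Sigma.T, atol=tol * max(1.0, np.abs(Sigma).max())):
        raise NotPositiveDefiniteError("covariance matrix is not symmetric")
    vals, vecs = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    if vals.min() <= tol * max(1.0, vals.max()):
        raise NotPositiveDefiniteError(
            f"covariance matrix is not positive definite (min eigenvalue {vals.min():g})"
        )
    return vals, vecs


def inv_sqrt_psd(Sigma) -> np.ndarray:
    """Unique symmetric positive-definite square root of ``Sigma^{-1}``."""
    vals, vecs = _eigh_psd(Sigma)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _sqrt_psd(Sigma) -> np.ndarray:
    vals, vecs = _eigh_psd(Sigma)
    return (vecs * np.sqrt(vals)) @ vecs.T


def ridge_whitening_estimate(x, ridge: float = 0.01) -> np.ndarray:
    """Ridge-regularized inverse square root of the sample covariance.

    Eigendecompose the sample covariance ``U diag(lam) U.T`` and return
    ``U (diag(lam) + ridge I)^(-1/2) U.T``; the ridge keeps the transform
    well defined when the sample covariance is rank deficient.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two observations")
    S = np.cov(x, rowvar=False)
    S = np.atleast_2d(S)
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    return (vecs / np.sqrt(np.maximum(vals, 0.0) + ridge)) @ vecs.T
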