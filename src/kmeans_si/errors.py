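"""Exception types shared across the package."""


class KmeansSIError(Exception):
    """Base class for all package-specific errors."""


class EmptyClusterError(KmeansSIError):
    """A cluster lost all of its members during Lloyd's algorithm.

    The within-cluster mean weights are undefined for an empty cluster, so
    neither the clustering step nor the selective-inference machinery can
    proceed.  Re-running with a different initialization seed usually avoids
    the problem.
    """

    def __init__(self, cluster: int, iteration: int):
        self.cluster = cluster
        self.iteration = iteration
        super().__init__(
            f"cluster {cluster} became empty at iteration {iteration}; "
            "re-run with a different initialization seed"
        )


class NotPositiveDefiniteError(KmeansSIError):
    """A covariance matrix is not symmetric positive definite."""


class ZeroMassRegionError(KmeansSIError):
    """The truncation region carries numerically zero probability mass.

    Raised only after log-space accumulation and the deep-tail asymptotic
    have both failed.  The Monte Carlo estimator
    :func:`kmeans_si.simulation.mc_oracle_p` can still produce an answer.
    """
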