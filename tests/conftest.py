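import numpy as np
import pytest

import kmeans_si as ks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(seed, n=12, q=2, K=2, sigma=1.0, delta=0.0):
    """A clustered instance: (x, trace, nu) for the (0, 1) cluster pair.

    Retries with successive seeds when an initialization hits an empty
    cluster, so callers always get a valid instance.
    """
    for s in range(seed, seed + 50):
        rng = np.random.default_rng(s)
        if delta > 0:
            x, _ = ks.gen_three_cluster(n - n % 3, q, delta, sigma, rng)
        else:
            x = ks.gen_global_null(n, q, sigma, rng)
        try:
            init = ks.sample_initial_centroids(x, K, rng)
            trace = ks.lloyd_with_trace(x, K, init)
            labels = trace.final_labels
            if np.any(np.bincount(labels, minlength=K) == 0):
                continue
            nu = ks.contrast_vector(labels, 0, 1)
        except (ks.EmptyClusterError, ValueError):
            continue
        return x, trace, nu
    raise RuntimeError("could not build a valid instance")


@pytest.fixture
def small_instance():
    return make_instance(0)
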