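import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulseshift import (
    ScaledTraitVector,
    SimulationConfig,
    read_newick,
    simulate_levy_traits,
    simulate_pure_birth_tree,
)
from pulseshift.model_fit import _align

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule10():
    return simulate_pure_birth_tree(10, 60, seed=1)


@pytest.fixture(scope="session")
def yule10_bm_trait(yule10):
    return simulate_levy_traits(
        yule10, SimulationConfig("BM", {"sigma2": 1.0}, tip_noise_sd=0.1, seed=2)
    )


def dense_gaussian_reml(tree, trait, sigma2, sigma_tip, *, rescaled=None):
    """Independent oracle: REML log-likelihood from the dense tip covariance
    matrix (shared path lengths) with the grand mean profiled out by GLS."""
    base = rescaled if rescaled is not None else tree
    tips = tree.tip_indices
    n = len(tips)
    paths = []
    for v in tips:
        anc = {}
        u = int(v)
        while u != -1:
            anc[u] = base.node_depths[u]
            u = int(tree.parent[u])
        paths.append(anc)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            C[i, j] = max(paths[i][u] for u in shared)
    V = sigma2 * C + sigma_tip**2 * np.eye(n)
    x = _align(tree, trait)[tips]
    one = np.ones(n)
    Vi = np.linalg.inv(V)
    mu = one @ Vi @ x / (one @ Vi @ one)
    r = x - mu
    return -0.5 * (
        (n - 1) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.log(one @ Vi @ one)
        + r @ Vi @ r
    )
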