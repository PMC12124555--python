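import numpy as np
import pytest

from kgreg import Graph, GraphFilter, KernelSpec, SelectionPattern


def random_graph(rng, n, density=0.6):
    """Random symmetric weighted graph with zero diagonal."""
    A = rng.random((n, n))
    A = 0.5 * (A + A.T)
    A *= rng.random((n, n)) < density
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return Graph(A)


def random_instance(seed, n=7, t=9, n_prime=5, t_prime=6, m=3):
    """A random partially observed regression problem for oracle tests."""
    rng = np.random.default_rng(seed)
    graph = random_graph(rng, n)
    sel = SelectionPattern(
        np.sort(rng.choice(n, n_prime, replace=False)),
        np.sort(rng.choice(t, t_prime, replace=False)),
        n_total=n,
        t_total=t,
    )
    X = rng.standard_normal((m, t))
    Y = rng.standard_normal((n_prime, t_prime))
    return graph, sel, X, Y


def random_spd(rng, n, cond=3.0):
    B = rng.standard_normal((n, n))
    return B @ B.T + cond * n * np.eye(n) / 10.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exp_filter():
    return GraphFilter("exponential", 1.0)


@pytest.fixture
def kernel():
    return KernelSpec(sigma=1.5)
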