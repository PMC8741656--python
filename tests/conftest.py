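import numpy as np
import pytest

from netreliance import Atlas, Connectome, SimConfig, make_atlas, \
    simulate_twin_traits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_atlas():
    """12 nodes, 3 networks of 4."""
    return make_atlas(12, [4, 4, 4], ["A", "B", "C"])


@pytest.fixture
def random_connectome(rng):
    """Symmetric zero-diagonal 20-node matrix with distinct weights."""
    n = 20
    w = rng.normal(0.3, 0.2, size=(n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return Connectome(subject_id="toy", values=w)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast default-structure cohort: 40 MZ + 40 DZ pairs."""
    cfg = SimConfig(n_mz_pairs=40, n_dz_pairs=40, seed=7)
    return simulate_twin_traits(cfg)


def make_random_graph(rng, n, density=1.0):
    """Random weighted graph as a ThresholdedGraph at the given density."""
    from netreliance import proportional_threshold

    w = rng.uniform(0.01, 1.0, size=(n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return proportional_threshold(Connectome("g", w), density)


def brute_force_attack(adjacency):
    """From-scratch oracle: rebuild the surviving subgraph and recompute
    all degrees at every step; max degree removed, ties -> lowest index."""
    adj = adjacency.copy()
    n = adj.shape[0]
    alive = list(range(n))
    order = []
    while alive:
        sub = adj[np.ix_(alive, alive)]
        deg = sub.sum(axis=1)
        best = int(np.argmax(deg))  # first max = lowest surviving index
        order.append(alive[best])
        alive.pop(best)
    return np.array(order)
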