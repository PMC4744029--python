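import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wmilink import WeightedGraph
from wmilink.synth_networks import fixture_suite

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")

_NODE_POOL = [chr(ord("a") + i) for i in range(12)]


def random_graph(seed: int, n_min: int = 4, n_max: int = 12,
                 weighted: bool = True) -> WeightedGraph:
    """Seeded random weighted graph on at most 12 string-labelled nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.25, 0.7))
    nodes = _NODE_POOL[:n]
    g = WeightedGraph(nodes=nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.2, 3.0)) if weighted else 1.0
                g.add_edge(nodes[i], nodes[j], w)
    return g


def all_pairs(g: WeightedGraph):
    """Every unordered node pair of ``g`` (edges included)."""
    nodes = g.sorted_nodes()
    return [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]]


def rank_equivalent(s1: dict, s2: dict, rtol: float = 1e-9) -> bool:
    """True if two score maps induce the same ranking up to ties.

    For every pair of candidates the score differences must agree in
    sign; differences below tolerance (ties) are allowed to disagree
    only with other ties.
    """
    keys = sorted(s1.keys(), key=str)
    assert set(keys) == set(s2.keys())
    a = np.array([s1[k] for k in keys], dtype=float)
    b = np.array([s2[k] for k in keys], dtype=float)

    def sgn(v, scale):
        out = np.sign(v)
        out[np.abs(v) <= rtol * max(scale, 1e-300)] = 0.0
        return out

    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    return bool(np.all(sgn(da, np.abs(a).max(initial=0.0))
                       == sgn(db, np.abs(b).max(initial=0.0))))


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture
def wmi4(fixtures):
    return fixtures["wmi4"]
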