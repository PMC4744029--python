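"""Seeded weighted-graph generators with plantable weight–structure coupling.

Real weighted networks differ in what a weight *means*: it may encode
affinity (synapse counts between neurons — large weight, likely link) or
effort/distance (long haul between stations — large weight, unlikely
link).  The generators here make that distinction explicit so the
weak-tie machinery can be exercised without external data: an unweighted
backbone (small-world ring lattice with rewiring, preferential-attachment
scale-free, or Erdős–Rényi) gets per-edge weights

    w_ij = exp(β · cn(i, j) + ε),   ε ~ Normal(0, noise_sd),

where cn(i, j) counts the common neighbors of the edge's endpoints in the
full backbone (the ground-truth network, before any train/probe split).
``weight_mode="positive"`` uses β = +1 (weights correlate with structural
similarity: strong ties are informative), ``"negative"`` uses β = −1
(weights anti-correlate: weak ties are the informative ones) and
``"iid"`` uses β = 0.  The exponential map keeps every weight strictly
positive for any noise draw.  With β = ±1 and the default noise_sd = 0.3
the planted signal is ~3 standard deviations per common-neighbor unit —
a clear, not marginal, correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import WeightedGraph

__all__ = ["SynthSpec", "generate", "fixture_suite"]

_BACKBONES = ("small-world", "scale-free", "random")
_WEIGHT_MODES = ("positive", "negative", "iid")

#: |slope| of the log-weight on the common-neighbor count in the
#: positive/negative modes.
WEIGHT_SLOPE = 1.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic weighted network.

    backbone : {"small-world", "scale-free", "random"}
    n : number of nodes (≥ 10)
    mean_degree : target mean degree (≥ 2)
    rewire_or_attach : rewiring probability (small-world; default 0.1) —
        ignored by the other backbones, which are parameterized by
        ``mean_degree`` alone
    weight_mode : {"positive", "negative", "iid"} — sign of the planted
        weight / structural-similarity correlation
    noise_sd : standard deviation of the log-weight noise (≥ 0)
    seed : RNG seed for backbone and weights
    """

    backbone: str = "small-world"
    n: int = 300
    mean_degree: int = 8
    rewire_or_attach: float = 0.1
    weight_mode: str = "iid"
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ValueError(f"backbone must be one of {_BACKBONES}")
        if self.weight_mode not in _WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {_WEIGHT_MODES}")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.mean_degree < 2:
            raise ValueError("mean_degree must be >= 2")
        if self.mean_degree >= self.n:
            raise ValueError("mean_degree must be < n")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.rewire_or_attach <= 1):
            raise ValueError("rewire_or_attach must be in [0, 1]")


def _backbone(spec: SynthSpec) -> nx.Graph:
    if spec.backbone == "small-world":
        k = spec.mean_degree - (spec.mean_degree % 2)  # WS needs even k
        return nx.connected_watts_strogatz_graph(
            spec.n, max(k, 2), spec.rewire_or_attach, seed=spec.seed)
    if spec.backbone == "scale-free":
        m = max(1, spec.mean_degree // 2)
        return nx.barabasi_albert_graph(spec.n, m, seed=spec.seed)
    m_edges = round(spec.n * spec.mean_degree / 2)
    return nx.gnm_random_graph(spec.n, m_edges, seed=spec.seed)


def generate(spec: SynthSpec) -> WeightedGraph:
    """Build the backbone, then plant weights coupled to local structure.

    Node identifiers are the strings "0" … "n−1".  Deterministic given
    ``spec.seed``; the weight noise uses an independent stream derived
    from the same seed.
    """
    bb = _backbone(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    beta = {"positive": WEIGHT_SLOPE,
            "negative": -WEIGHT_SLOPE,
            "iid": 0.0}[spec.weight_mode]
    g = WeightedGraph(nodes=(str(v) for v in bb.nodes))
    for u, v in sorted(bb.edges()):
        cn = len(set(bb[u]) & set(bb[v]))
        eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        g.add_edge(str(u), str(v), float(np.exp(beta * cn + eps)))
    return g


def fixture_suite() -> dict:
    """Deterministic unit-test graphs.

    * ``triangle`` — 3-clique, unit weights: N△ = 1, N∧ = 0 at every node.
    * ``star3`` — center "z" with 3 leaves: N△z = 0, N∧z = 3.
    * ``square`` — 4-cycle a–b–c–d–a, unit weights.
    * ``path3`` — path a–b–c.
    * ``wmi4`` — 4 nodes, 5 edges a–c(1), b–c(2), a–d(1), b–d(1), c–d(3):
      the worked mutual-information example (pair (a,b): both common
      neighbors have C_z = 2/3 raw, score 2·log₂(4/5)).
    * ``cliques53`` — disjoint K5 ∪ K3 with unit weights: every node's
      neighborhood is a clique (C_z = 1 raw), so the MI ranking must
      coincide with common-neighbor counting.
    """
    out = {}
    out["triangle"] = WeightedGraph(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    out["star3"] = WeightedGraph(
        [("z", "a", 1.0), ("z", "b", 1.0), ("z", "c", 1.0)])
    out["square"] = WeightedGraph(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("a", "d", 1.0)])
    out["path3"] = WeightedGraph([("a", "b", 1.0), ("b", "c", 1.0)])
    out["wmi4"] = WeightedGraph(
        [("a", "c", 1.0), ("b", "c", 2.0), ("a", "d", 1.0),
         ("b", "d", 1.0), ("c", "d", 3.0)])
    cl = []
    k5 = ["p", "q", "r", "s", "t"]
    for i, u in enumerate(k5):
        for v in k5[i + 1:]:
            cl.append((u, v, 1.0))
    k3 = ["u", "v", "w"]
    for i, u in enumerate(k3):
        for v in k3[i + 1:]:
            cl.append((u, v, 1.0))
    out["cliques53"] = WeightedGraph(cl)
    return out
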