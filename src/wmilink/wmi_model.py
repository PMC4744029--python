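"""Mutual-information link scoring and its weight-fused (WMI) variants.

The connection likelihood of a candidate pair (x, y) is scored by the
mutual information between the event L¹_xy ("x and y are linked") and the
pair's common neighbors, assumed independent:

    s_xy = Σ_{z ∈ O_xy} I(L¹; z),    I(L¹; z) = I(L¹) − I(L¹ | z)

The prior self-information uses the training-graph link density,
I(L¹) = −log(M^T / M) with M = |V|(|V|−1)/2 possible pairs and M^T
training links.  The conditional term is estimated from the pair-form
clustering coefficient of the common neighbor z,

    C_z = N△z / (N△z + N∧z),    I(L¹ | z) = −log C_z,

where N△z / N∧z count the connected / disconnected unordered pairs among
z's neighbors (so N△z + N∧z = d_z(d_z−1)/2).  A common neighbor sitting in
a dense neighborhood is strong evidence for a link; one in a sparse
neighborhood may carry negative information.  If C_z = 1 everywhere the
score is proportional to the common-neighbor count.

The weighted model multiplies each neighbor's information contribution by
the weight kernel of a classical index family,

    s_xy = Σ_z f(W_xz, W_zy) · I(L¹; z),

with f the CN / AA / RA kernel at weak-tie exponent α (α = 1 gives the
pure WMI indices).

Numerical conventions
---------------------
* Logarithms default to base 2 (scores in bits).  Rankings — and hence
  Precision — are invariant to the base, which only rescales all scores
  by the same positive factor.
* C_z = 0 (no edges among z's neighbors) makes −log C_z infinite under the
  raw estimator.  The default ``laplace`` smoothing uses
  (N△z + 1)/(N△z + N∧z + 2) and stays finite; ``raw`` keeps the literal
  estimator and maps each −∞ contribution to the finite sentinel
  ``NEG_SENTINEL`` so affected pairs rank below every finite-scored pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import Node, WeightedGraph, common_neighbors
from .local_indices import IndexConfig

__all__ = [
    "MIContext",
    "MIScore",
    "NEG_SENTINEL",
    "build_context",
    "prior_information",
    "conditional_information",
    "mi_score",
    "wmi_score",
    "mi_score_matrix",
    "wmi_score_matrix",
]

#: Finite stand-in for a −∞ per-neighbor contribution under raw smoothing.
NEG_SENTINEL = -1.0e9

_SMOOTHINGS = ("laplace", "raw")


@dataclass(frozen=True)
class MIContext:
    """Per-training-graph cache of the quantities the MI score needs.

    Attributes
    ----------
    m_total : int
        M = |V|(|V|−1)/2, possible node pairs.
    m_train : int
        M^T = |E^T|, links in the training graph.
    pair_counts : dict
        node -> (N△z, N∧z): connected / disconnected neighbor-pair counts.
    smoothing : {"laplace", "raw"}
    log_base : float
    """

    m_total: int
    m_train: int
    pair_counts: dict
    smoothing: str = "laplace"
    log_base: float = 2.0

    def clustering(self, z: Node) -> float:
        """Pair-form clustering coefficient C_z under the context smoothing."""
        n_con, n_dis = self.pair_counts[z]
        if self.smoothing == "laplace":
            return (n_con + 1) / (n_con + n_dis + 2)
        if n_con + n_dis == 0:
            raise ValueError(
                f"node {z!r} has degree < 2; C_z is undefined")
        return n_con / (n_con + n_dis)


def build_context(g_train: WeightedGraph, smoothing: str = "laplace",
                  log_base: float = 2.0) -> MIContext:
    """Count connected/disconnected neighbor pairs on the training graph.

    N△z equals the number of triangles through z; N∧z is the remainder of
    the d_z(d_z−1)/2 unordered neighbor pairs.  Counts are a property of z
    alone, computed once — the pair being scored later is itself one of
    the disconnected pairs counted here, and is never adjusted per query.
    """
    if smoothing not in _SMOOTHINGS:
        raise ValueError(
            f"smoothing must be one of {_SMOOTHINGS}, got {smoothing!r}")
    if g_train.number_of_nodes == 0:
        raise ValueError("training graph is empty")
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"invalid log base {log_base!r}")
    nxg = g_train.to_networkx()
    triangles = nx.triangles(nxg)
    counts = {}
    for z in nxg.nodes:
        d = nxg.degree[z]
        total = d * (d - 1) // 2
        n_con = triangles[z]
        counts[z] = (n_con, total - n_con)
    return MIContext(m_total=g_train.m_possible,
                     m_train=g_train.number_of_edges,
                     pair_counts=counts, smoothing=smoothing,
                     log_base=float(log_base))


def _log(x: float, base: float) -> float:
    return math.log(x) / math.log(base)


def prior_information(ctx: MIContext) -> float:
    """I(L¹) = −log(M^T / M): self-information of the link prior."""
    if ctx.m_train == 0:
        raise ValueError("no training links: prior probability is 0")
    return -_log(ctx.m_train / ctx.m_total, ctx.log_base)


def conditional_information(ctx: MIContext, z: Node) -> float:
    """I(L¹ | z) = −log C_z for a common neighbor z (degree ≥ 2 required).

    Under raw smoothing a node with C_z = 0 returns +∞ (``math.inf``); the
    scoring layer converts the resulting −∞ contribution to the
    ``NEG_SENTINEL``.
    """
    n_con, n_dis = ctx.pair_counts[z]
    if n_con + n_dis == 0:
        raise ValueError(f"node {z!r} has degree < 2 and cannot be a "
                         f"common neighbor")
    if ctx.smoothing == "raw" and n_con == 0:
        return math.inf
    return -_log(ctx.clustering(z), ctx.log_base)


@dataclass(frozen=True)
class MIScore:
    """Score of one pair with its per-common-neighbor decomposition."""

    value: float
    per_neighbor: dict


def _information_gain(ctx: MIContext, z: Node) -> float:
    """I(L¹; z) = I(L¹) − I(L¹|z); −∞ mapped to the finite sentinel."""
    cond = conditional_information(ctx, z)
    if math.isinf(cond):
        return NEG_SENTINEL
    return prior_information(ctx) - cond


def mi_score(g_train: WeightedGraph, pair: tuple[Node, Node],
             ctx: MIContext) -> MIScore:
    """Structural (weight-free) mutual-information score of one pair."""
    o_xy = common_neighbors(g_train, pair)
    per = {z: _information_gain(ctx, z) for z in o_xy}
    return MIScore(value=math.fsum(per.values()), per_neighbor=per)


def wmi_score(g_train: WeightedGraph, pair: tuple[Node, Node],
              ctx: MIContext, cfg: IndexConfig) -> float:
    """Weight-fused MI score Σ_z f(W_xz, W_zy) · I(L¹; z) for one pair."""
    if not cfg.mi_fused:
        raise ValueError("wmi_score requires cfg.mi_fused=True")
    from .local_indices import _kernel

    x, y = pair
    o_xy = common_neighbors(g_train, (x, y))
    terms = []
    for z in o_xy:
        gain = _information_gain(ctx, z)
        kern = _kernel(g_train, x, z, y, cfg) if cfg.weighted else 1.0
        terms.append(kern * gain)
    return math.fsum(terms)


# -- dense fast path ---------------------------------------------------------

def _gain_vector(ctx: MIContext, nodes, index) -> np.ndarray:
    """I(L¹; z) per node; 0 for degree < 2 nodes (never common neighbors)."""
    gains = np.zeros(len(nodes))
    for z in nodes:
        n_con, n_dis = ctx.pair_counts[z]
        if n_con + n_dis == 0:
            continue
        gains[index[z]] = _information_gain(ctx, z)
    return gains


def mi_score_matrix(g_train: WeightedGraph, ctx: MIContext):
    """All-pairs MI score matrix: Σ over common neighbors of I(L¹; z).

    Returns ``(nodes, index, S)`` with the diagonal zeroed; S_xy is exactly
    the :func:`mi_score` value.
    """
    nodes, index, W = g_train.adjacency_arrays()
    A = (W > 0).astype(float)
    gains = _gain_vector(ctx, nodes, index)
    S = (A * gains) @ A
    np.fill_diagonal(S, 0.0)
    return nodes, index, S


def wmi_score_matrix(g_train: WeightedGraph, ctx: MIContext,
                     cfg: IndexConfig):
    """All-pairs weight-fused MI score matrix.

    Per common neighbor z the contribution is (B_xz + B_zy)·k_z·I(L¹;z)
    with B = W^α on edges and k_z the family denominator factor, realised
    as ``(B·diag(k·I))·A + transpose``.
    """
    if not cfg.mi_fused:
        raise ValueError("wmi_score_matrix requires cfg.mi_fused=True")
    nodes, index, W = g_train.adjacency_arrays()
    A = (W > 0).astype(float)
    gains = _gain_vector(ctx, nodes, index)
    if not cfg.weighted:
        S = (A * gains) @ A
        np.fill_diagonal(S, 0.0)
        return nodes, index, S
    B = np.zeros_like(W)
    mask = W > 0
    B[mask] = W[mask] ** cfg.alpha
    if cfg.family == "cn":
        k = np.ones(len(nodes))
    else:
        s = (W.sum(axis=1) if cfg.plain_strength else B.sum(axis=1))
        denom = np.log1p(s) if cfg.family == "aa" else s
        k = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
    half = (B * (k * gains)) @ A
    S = half + half.T
    np.fill_diagonal(S, 0.0)
    return nodes, index, S
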