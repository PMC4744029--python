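"""Classical neighbor-based similarity indices and their weighted forms.

Three families, each summing over the common neighbors z of a candidate
pair (x, y):

* CN (common neighbors):          s = Σ_z (W_xz^α + W_zy^α)
* AA (Adamic-Adar, log-damped):   s = Σ_z (W_xz^α + W_zy^α) / log(1 + S_z)
* RA (resource allocation):       s = Σ_z (W_xz^α + W_zy^α) / S_z

with S_z = Σ_{z'∈Γ(z)} W_zz'^α the α-powered node strength.  The weak-tie
exponent α tunes the relative contribution of weak links: α < 1 amplifies
them, α > 1 suppresses them, α = 0 discards weights entirely (S_z becomes
the degree and the indices reduce to the unweighted CN/AA/RA rankings),
and α = 1 is the plainly weighted case.

Unweighted configurations (``weighted=False``) use the textbook values
|O_xy|, Σ 1/log(1+d_z) and Σ 1/d_z, i.e. the α = 0 forms divided by two —
rank-identical to the α = 0 limit.

The AA denominator uses the natural logarithm; any fixed base rescales all
denominators by the same factor, so rankings (and hence Precision) do not
depend on the choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .graph_core import Node, WeightedGraph, common_neighbors, node_strength

__all__ = ["IndexConfig", "score_pair", "score_all", "score_matrix"]

_FAMILIES = ("cn", "aa", "ra")


@dataclass(frozen=True)
class IndexConfig:
    """Which index to compute.

    Parameters
    ----------
    family : {"cn", "aa", "ra"}
        Denominator form: none, log(1 + S_z), or S_z.
    weighted : bool
        If False, ignore link weights (textbook unweighted index); alpha
        is then irrelevant.
    mi_fused : bool
        If True the per-neighbor kernel multiplies the mutual-information
        contribution of z (consumed by :mod:`wmilink.wmi_model`).
    alpha : float
        Weak-tie exponent applied to link weights; any finite real.
    plain_strength : bool
        If True, S_z in the AA/RA denominators is the plain (α = 1)
        strength instead of the α-powered one.  Affects only α ≠ 1.
    """

    family: str = "cn"
    weighted: bool = True
    mi_fused: bool = False
    alpha: float = 1.0
    plain_strength: bool = False

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(
                f"family must be one of {_FAMILIES}, got {self.family!r}")
        if not math.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha!r}")

    def with_alpha(self, alpha: float) -> "IndexConfig":
        return replace(self, alpha=float(alpha))


def _strength(g: WeightedGraph, z: Node, cfg: IndexConfig) -> float:
    return node_strength(g, z, 1.0 if cfg.plain_strength else cfg.alpha)


def _kernel(g: WeightedGraph, x: Node, z: Node, y: Node,
            cfg: IndexConfig) -> float:
    """Per-common-neighbor weight kernel f(W_xz, W_zy) for one z."""
    num = g.weight(x, z) ** cfg.alpha + g.weight(z, y) ** cfg.alpha
    if cfg.family == "cn":
        return num
    s_z = _strength(g, z, cfg)
    if cfg.family == "aa":
        return num / math.log1p(s_z)
    return num / s_z


def score_pair(g: WeightedGraph, pair: tuple[Node, Node],
               cfg: IndexConfig) -> float:
    """Similarity score of one node pair under ``cfg``.

    The pair need not be a non-edge; scoring existing links is allowed for
    diagnostics.  A pair with no common neighbors scores 0.
    """
    if cfg.mi_fused:
        raise ValueError("mi_fused configs are scored by wmilink.wmi_model")
    x, y = pair
    o_xy = common_neighbors(g, (x, y))
    if not o_xy:
        return 0.0
    if not cfg.weighted:
        if cfg.family == "cn":
            return float(len(o_xy))
        if cfg.family == "aa":
            return sum(1.0 / math.log1p(g.degree(z)) for z in o_xy)
        return sum(1.0 / g.degree(z) for z in o_xy)
    return sum(_kernel(g, x, z, y, cfg) for z in o_xy)


def score_all(g: WeightedGraph, candidates, cfg: IndexConfig):
    """Score every candidate pair; returns ``{pair: score}``.

    Uses the dense matrix fast path; values agree with :func:`score_pair`
    to floating tolerance.
    """
    candidates = list(candidates)
    if not candidates:
        return {}
    nodes, index, scores = score_matrix(g, cfg)
    return {(x, y): float(scores[index[x], index[y]]) for x, y in candidates}


def score_matrix(g: WeightedGraph, cfg: IndexConfig,
                 weights: np.ndarray | None = None):
    """Dense all-pairs score matrix for a non-MI index.

    Writing A for the binary adjacency, B = W^α on edges and c_z for the
    per-neighbor denominator factor, the score matrix is
    ``(B·diag(c))·A + its transpose`` — each (x, y) entry sums
    ``(B_xz + B_zy)·c_z`` over common neighbors z.  Returns
    ``(nodes, index, S)``; the diagonal is meaningless and zeroed.
    """
    if cfg.mi_fused:
        raise ValueError("mi_fused configs are scored by wmilink.wmi_model")
    if weights is None:
        nodes, index, W = g.adjacency_arrays()
    else:
        nodes, index, W = weights
    A = (W > 0).astype(float)
    if not cfg.weighted:
        d = A.sum(axis=1)
        if cfg.family == "cn":
            S = A @ A
        else:
            with np.errstate(divide="ignore"):
                c = (1.0 / np.log1p(d) if cfg.family == "aa" else 1.0 / d)
            c = np.where(d > 0, c, 0.0)
            S = (A * c) @ A
    else:
        B = np.zeros_like(W)
        mask = W > 0
        B[mask] = W[mask] ** cfg.alpha
        if cfg.family == "cn":
            half = B @ A
        else:
            s = (W.sum(axis=1) if cfg.plain_strength else B.sum(axis=1))
            denom = np.log1p(s) if cfg.family == "aa" else s
            with np.errstate(divide="ignore"):
                c = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0),
                             0.0)
            half = (B * c) @ A
        S = half + half.T
    np.fill_diagonal(S, 0.0)
    return nodes, index, S
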