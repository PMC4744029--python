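# Methods

## Problem setting

An undirected simple graph G(V, E, W) with strictly positive symmetric
link weights is given.  A fraction of the observed links is hidden (the
probe set Eᴾ); every node pair absent from the remaining training graph
Eᵀ is a candidate, scored for its likelihood of being a (missing) link.
Candidates are ranked by descending score and Precision@L = L_r/L
measures how many of the top L candidates are probe links.

## Similarity indices

For a candidate pair (x, y) with common-neighbor set
O_xy = Γ(x) ∩ Γ(y):

| family | score |
|---|---|
| WCN_α | Σ_z (W_xz^α + W_zy^α) |
| WAA_α | Σ_z (W_xz^α + W_zy^α) / log(1 + S_z) |
| WRA_α | Σ_z (W_xz^α + W_zy^α) / S_z |

with S_z = Σ_{z'∈Γ(z)} W_zz'^α the α-powered strength.  The weak-tie
exponent α rescales the influence of weak links; at α = 0 the indices
collapse to the unweighted rankings (S_z becomes the degree), at α = 1
to the plainly weighted ones.  Unweighted configurations are computed
directly as |O_xy|, Σ 1/log(1 + d_z) and Σ 1/d_z — half the α = 0
values, hence rank-identical.

## Mutual-information model

The self-information of the link event is estimated from the training
link density, I(L¹) = −log(Mᵀ/M) with M = |V|(|V|−1)/2.  Conditioned on
a common neighbor z, the link probability is estimated by the pair-form
clustering coefficient C_z = N△z/(N△z + N∧z), where N△z and N∧z count
the connected and disconnected unordered pairs among z's neighbors
(N△z is the triangle count through z; the identity
N△z + N∧z = d_z(d_z−1)/2 is enforced by construction and tested).  The
per-neighbor information gain I(L¹; z) = I(L¹) + log C_z is summed over
O_xy assuming independent common neighbors; the weighted model
multiplies each term by the family kernel f(W_xz, W_zy) at exponent α.
Pairs without common neighbors score exactly 0.

Counts are a property of z alone, computed once per training graph —
including the disconnected pair (x, y) currently being scored.  All
structural quantities come from the training graph only; probe links
contribute nothing.  The per-split context is rebuilt from scratch (no
incremental updates): at the few-hundred-node scale a rebuild is
milliseconds.

## Numerical conventions

* **Log base**: base 2 (scores in bits).  Rankings, and therefore every
  Precision value, are invariant to the base, which multiplies all
  scores by one positive constant; the property is tested for bases
  2, e and 10.
* **C_z = 0** (a common neighbor none of whose neighbors inter-connect)
  makes −log C_z infinite under the raw estimator.  The default
  `laplace` smoothing uses (N△z + 1)/(N△z + N∧z + 2), which keeps all
  scores finite and shrinks extreme clustering estimates of low-degree
  nodes toward 1/2.  `smoothing="raw"` keeps the literal estimator and
  maps each −∞ contribution to a finite sentinel (−10⁹ per neighbor),
  so affected pairs rank below every finite-scored pair; the worked
  fixture and the clique-degeneracy property use raw smoothing, where
  C_z is exact.
* **S_z in the fused AA/RA kernels** uses the α-powered strength,
  matching the definition attached to the parameterized indices; a
  `plain_strength` switch restores the plain (α = 1) strength for the
  denominator, since the fused equations admit either reading.  Both
  are implemented and tested; the default affects nothing at α = 1.
* **AA logarithm**: natural log.  Any fixed base rescales all
  denominators equally and leaves rankings unchanged.
* **Weights must be finite and > 0**: zero-weight records are rejected
  at the I/O boundary rather than treated as absent edges, because
  negative α would make 0^α undefined or infinite.
* **Tie-breaking**: candidates with equal scores are permuted uniformly
  at random by the run's seeded RNG.  Deterministic lexicographic
  tie-breaking would bias Precision for integer-scored indices such as
  CN, where top-L cutoffs routinely fall inside large tied blocks.
* **Degenerate inputs**: isolated nodes have strength 0 and stay in the
  candidate universe; nodes of degree < 2 can never be common
  neighbors, and asking for their conditional information is an error.

## Evaluation protocol

`random_split` draws a uniformly random probe subset of
round(fraction·|E|) links (default 10%); the training view keeps the
full node set.  `evaluate` repeats split → score-all-non-edges → rank →
Precision@L with per-run seed pairs spawned from one master seed, so a
result is a pure function of its arguments, and two configurations
evaluated with the same seed see identical splits (paired comparisons).
`alpha_sweep` shares run seeds across grid points and reports the
argmax α*, ties broken toward the smallest |α|.

`select_alpha_validated` divides links 80/10/10 into
train/validation/test, picks α̂ by validation Precision using the 80%
graph, and reports test Precision with train+validation re-fused into a
90% graph (a flag keeps the bare 80% graph instead; re-fusing mirrors
how the protocol would be deployed, where validation links are known
links).  The RMSD between Precision at α̂ and at α*, across the six
index families, summarizes the cost of estimating the exponent.

## Synthetic networks

The generator separates backbone topology from weight semantics.
Backbones: connected Watts–Strogatz ring lattice with rewiring
probability 0.1 (default; clustering is tunable through the rewiring
rate), Barabási–Albert preferential attachment, or Erdős–Rényi at the
target density.  Each edge then receives

    w_ij = exp(β·cn(i,j) + ε),  ε ~ Normal(0, noise_sd)

with cn(i,j) the common-neighbor count of the edge's endpoints in the
full backbone, computed before any splitting — the planted correlation
is a property of the ground-truth network, which the evaluation's
splits then partially hide.  β = +1, −1 or 0 for the positive,
negative and iid modes; the exponential keeps weights positive for any
noise draw.  With |β| = 1 and the default noise_sd = 0.3 the planted
signal is about three noise standard deviations per common-neighbor
unit — an unambiguous, not marginal, coupling.  Defaults n = 300,
mean degree 8.

What the generator does *not* emulate: heavy-tailed weight
distributions, degree–weight correlations, community structure, or the
degree sequences of any particular real network.  Passing the synthetic
tests therefore demonstrates that the machinery responds correctly to
the *sign and presence* of a weight–structure coupling, not that any
particular Precision level will be attained on a given real network.

## Problem sizes and stochastic-test calibration

Property checks that compare against the brute-force reference run on
hundreds of random graphs of ≤ 12 nodes, where literal enumeration is
exact and fast.  The weak-tie and validation studies use n = 300,
mean degree 8, 10 generator seeds, 3 evaluation runs per configuration
and an α grid of −2 … 3 in steps of 0.25 (CLI sweeps default to the
finer −5 … 5 step 0.01 grid for production use; the coarse grid locates
the optimum of these smooth, single-peaked Precision curves to well
within the tolerance of the sign-recovery and RMSD checks).  The
sign-recovery thresholds (≥ 8 of 10 seeds) and the RMSD bound (≤ 0.05)
are calibration choices for stochastic tests, fixed before the package
was tuned against them.

## Known limitations

* Scoring is dense O(|V|²) per split — appropriate at desk scale
  (hundreds to a few thousand nodes), not for million-node graphs.
* Common neighbors are assumed independent when their information is
  summed; in clustered graphs this double-counts overlapping evidence.
* The model uses only one-hop structure: path-based, global and
  reliable-route indices are out of scope, as is weight prediction.
* Directed graphs and multigraphs are not modelled; raw multigraph
  edge lists can be collapsed at load time with the `sum` duplicate
  policy.
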