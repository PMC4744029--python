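# wmilink

Link prediction in undirected weighted networks, combining the mutual
information of local network structure with link weights.

In many networks — neural wiring, air traffic, food webs, co-occurrence
graphs — measuring every link is expensive, and a good predictor of
missing links saves real experimental or observational effort.  The
classical local predictors score a candidate pair (x, y) by its common
neighbors: CN counts them, AA and RA down-weight neighbors with large
degree/strength.  Their weighted forms add link weights, and a weak-tie
exponent α on the weights (`W^α`) tunes how much weak links matter:
α < 1 amplifies weak ties, α > 1 suppresses them, α = 0 recovers the
unweighted index.

`wmilink` implements these families together with a mutual-information
model: the information a common neighbor z carries about a link is

    I(L¹; z) = −log(Mᵀ/M) + log C_z

where Mᵀ/M is the training-graph link density (M = |V|(|V|−1)/2) and
C_z = N△z/(N△z + N∧z) is the fraction of z's neighbor pairs that are
actually linked.  The weighted mutual-information (WMI) score fuses this
with a weight kernel:

    s_xy = Σ_{z ∈ O_xy} f(W_xz, W_zy) · I(L¹; z)

with f the CN / AA / RA kernel at exponent α.  The package also ships
the full evaluation protocol (random 90/10 train/probe splits,
Precision@L with randomized tie-breaking, paired α grid sweeps, 80/10/10
validation-based α estimation, RMSD summaries) and seeded synthetic
weighted-graph generators whose weights are plantably correlated or
anti-correlated with structural similarity — the two regimes in which
strong respectively weak ties carry the predictive signal.

## Worked example

```python
from wmilink import IndexConfig, build_context, mi_score, wmi_score
from wmilink.synth_networks import fixture_suite

g = fixture_suite()["wmi4"]          # 4 nodes, 5 weighted edges
ctx = build_context(g, smoothing="raw", log_base=2.0)
print(mi_score(g, ("a", "b"), ctx).value)
# -0.6439 bits: both common neighbors have C_z = 2/3 against a 5/6 prior,
# so each contributes log2(4/5) — the local evidence argues *against* a-b.
cfg = IndexConfig("cn", mi_fused=True, alpha=1.0)
print(wmi_score(g, ("a", "b"), ctx, cfg))
# -1.6096 bits: the same evidence scaled by the weight kernels 3 and 2.
```

Running `python examples/03_evaluate_precision.py` evaluates a
300-node synthetic network whose weights encode similarity:

```
CN (unweighted)      mean Precision@100 = 0.234
WCN (alpha=1)        mean Precision@100 = 0.422
MI (structural)      mean Precision@100 = 0.218
WMI-WCN (alpha=1)    mean Precision@100 = 0.402
```

i.e. out of the 100 top-ranked candidate links, the weighted variants
recover roughly 40 genuinely held-out links versus roughly 22 for their
unweighted counterparts.  `examples/04_weak_tie_sweep.py` shows the
Precision-optimal exponent flipping from α* = +1.0 to α* = −0.5 when
the weight–similarity coupling changes sign.

## Command line

A thin `wmilink` CLI wraps the library:

```
wmilink synth --backbone small-world --n 300 --k 8 --mode negative --seed 1 --out g.tsv
wmilink score --graph g.tsv --index ra --mi --alpha 0.5 --top 100 --out scores.tsv
wmilink evaluate --graph g.tsv --index cn --runs 100 --top 100 --seed 1 --out result.json
wmilink sweep --graph g.tsv --index cn --grid -2:3:0.25 --runs 10 --out sweep.tsv
```

Graphs are read as whitespace-separated weighted edge lists
(`node node weight`, `#` comments) or Pajek `.net` files; every output
carries a provenance header with the version, seed and configuration.

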