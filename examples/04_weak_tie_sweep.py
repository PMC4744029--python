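"""How the optimal weak-tie exponent reveals what weights mean.

Generates two synthetic networks from the same small-world backbone
family: one whose weights are positively coupled to structural
similarity (think synapse counts) and one anti-coupled (think
distances).  Sweeping the exponent α of the weighted common-neighbor
index over a grid shows where Precision peaks: α* > 0 when strong ties
are informative, α* < 1 (typically negative) when the weak ties are the
ones that matter.
"""

import numpy as np

from wmilink import IndexConfig, alpha_sweep
from wmilink.synth_networks import SynthSpec, generate

grid = [round(a, 2) for a in np.arange(-2.0, 3.001, 0.5)]

for mode in ("positive", "negative"):
    g = generate(SynthSpec(n=300, mean_degree=8, weight_mode=mode,
                           noise_sd=0.3, seed=11))
    res = alpha_sweep(g, IndexConfig("cn"), grid, runs=3, L=100, seed=11)
    print(f"{mode}-coupled weights:")
    for a in grid:
        bar = "#" * int(60 * res.mean_precision_at[a])
        star = "  <-- alpha*" if a == res.alpha_star else ""
        print(f"  alpha={a:+.1f}  P@100={res.mean_precision_at[a]:.3f} "
              f"{bar}{star}")
    print(f"  optimal alpha* = {res.alpha_star:+.2f}\n")

print("A single sign flip in the weight-similarity coupling moves the")
print("Precision-optimal exponent from amplifying strong ties to")
print("amplifying weak ones.")
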