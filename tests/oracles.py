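"""Brute-force reference implementations used only by the test suite.

Everything here recomputes scores from first principles — literal set
intersections, literal enumeration of all node pairs — and deliberately
shares no code with the package's scoring paths.
"""

import math

_SENTINEL = -1.0e9  # stand-in for a -inf contribution (raw smoothing, C_z=0)


def adjacency(g):
    adj = {n: {} for n in g.nodes}
    for x, y, w in g.edges():
        adj[x][y] = w
        adj[y][x] = w
    return adj


def brute_local(g, pair, family, weighted=True, alpha=1.0,
                plain_strength=False):
    """Eqs-style neighbor index by literal enumeration."""
    x, y = pair
    adj = adjacency(g)
    common = [z for z in adj if z in adj[x] and z in adj[y]]
    total = 0.0
    for z in common:
        if not weighted:
            d = len(adj[z])
            if family == "cn":
                total += 1.0
            elif family == "aa":
                total += 1.0 / math.log(1 + d)
            else:
                total += 1.0 / d
            continue
        num = adj[x][z] ** alpha + adj[z][y] ** alpha
        s_alpha = 1.0 if plain_strength else alpha
        s_z = sum(w ** s_alpha for w in adj[z].values())
        if family == "cn":
            total += num
        elif family == "aa":
            total += num / math.log(1 + s_z)
        else:
            total += num / s_z
    return total


def brute_clustering(g, z, smoothing="laplace"):
    """C_z by enumerating every pair of z's neighbors."""
    adj = adjacency(g)
    nbrs = sorted(adj[z])
    con = dis = 0
    for i, u in enumerate(nbrs):
        for v in nbrs[i + 1:]:
            if v in adj[u]:
                con += 1
            else:
                dis += 1
    if smoothing == "laplace":
        return (con + 1) / (con + dis + 2)
    if con + dis == 0:
        raise ValueError("degree < 2")
    return con / (con + dis)


def brute_gain(g, z, smoothing, base):
    """I(link; z) = -log(M^T/M) + log C_z, sentinel for C_z = 0 raw."""
    n = len(g.nodes)
    m = n * (n - 1) // 2
    mt = sum(1 for _ in g.edges())
    prior = -math.log(mt / m, base)
    c = brute_clustering(g, z, smoothing)
    if c == 0.0:
        return _SENTINEL
    return prior + math.log(c, base)


def brute_mi(g, pair, smoothing="laplace", base=2.0):
    x, y = pair
    adj = adjacency(g)
    common = [z for z in adj if z in adj[x] and z in adj[y]]
    return math.fsum(brute_gain(g, z, smoothing, base) for z in common)


def brute_wmi(g, pair, family, alpha=1.0, smoothing="laplace", base=2.0,
              plain_strength=False):
    x, y = pair
    adj = adjacency(g)
    common = [z for z in adj if z in adj[x] and z in adj[y]]
    total = []
    for z in common:
        num = adj[x][z] ** alpha + adj[z][y] ** alpha
        s_alpha = 1.0 if plain_strength else alpha
        s_z = sum(w ** s_alpha for w in adj[z].values())
        if family == "cn":
            f = num
        elif family == "aa":
            f = num / math.log(1 + s_z)
        else:
            f = num / s_z
        total.append(f * brute_gain(g, z, smoothing, base))
    return math.fsum(total)
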