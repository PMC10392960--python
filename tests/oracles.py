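"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: dictionaries
and explicit loops over joint states for the information measures, and a
hand-rolled union-find over the explicit link list for avalanche
components.
"""

import math
from collections import Counter


def mi_brute(x):
    """Lag-1 mutual information by direct summation over the 4-state joint."""
    pairs = list(zip(x[:-1], x[1:]))
    n = len(pairs)
    cj = Counter(pairs)
    cx = Counter(a for a, _ in pairs)
    cy = Counter(b for _, b in pairs)
    total = 0.0
    for (a, b), c in cj.items():
        total += c / n * math.log2((c / n) / ((cx[a] / n) * (cy[b] / n)))
    return total


def te_brute(x, y):
    """Transfer entropy by direct summation over the 8-state joint."""
    trips = list(zip(x[:-1], x[1:], y[:-1]))
    n = len(trips)
    cj = Counter(trips)
    c_xy = Counter((a, c) for a, _, c in trips)
    c_xx1 = Counter((a, b) for a, b, _ in trips)
    c_x = Counter(a for a, _, _ in trips)
    total = 0.0
    for (a, b, c), cnt in cj.items():
        q_full = cnt / c_xy[(a, c)]
        q_marg = c_xx1[(a, b)] / c_x[a]
        total += cnt / n * math.log2(q_full / q_marg)
    return total


def components_brute(nodes, links):
    """Connected components by naive union-find over an explicit link list.

    Returns a frozenset of frozensets of nodes.
    """
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            v = parent[v]
        return v

    for a, b in links:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return frozenset(frozenset(g) for g in groups.values())
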