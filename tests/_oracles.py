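"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit enumeration,
combinatorial summation) and deliberately shares no code with the
package under test.
"""

from itertools import combinations
from math import comb


def degree_counts(nodes, edges):
    """Per-node degree by scanning the edge list."""
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def degree_histogram(nodes, edges):
    """n(k) by direct counting."""
    deg = degree_counts(nodes, edges)
    hist = {}
    for k in deg.values():
        hist[k] = hist.get(k, 0) + 1
    return hist


def clustering(nodes, edges):
    """C_i = 2 * (edges among neighbors) / (k (k - 1)) by enumerating all
    neighbor pairs; 0 for degree < 2."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def hypergeom_tail(overlap, list_size, category_size, universe_size):
    """P(X >= overlap) by direct combinatorial summation."""
    total = comb(universe_size, list_size)
    if total == 0:
        return 1.0
    acc = 0
    for k in range(overlap, min(list_size, category_size) + 1):
        if list_size - k > universe_size - category_size:
            continue
        acc += comb(category_size, k) * comb(universe_size - category_size, list_size - k)
    return acc / total


def hub_adjacency_counts(genes, hubs, edges):
    """x_i = number of hubs adjacent to each gene, by edge-list scan."""
    hubs = set(hubs)
    out = {}
    for g in genes:
        adjacent = set()
        for u, v in edges:
            if u == g and v in hubs:
                adjacent.add(v)
            elif v == g and u in hubs:
                adjacent.add(u)
        out[g] = len(adjacent)
    return out


def min_cover_size(hit_sets, target):
    """Minimum number of hit-sets whose union covers target, by full
    subset enumeration; None when infeasible."""
    target = frozenset(target)
    if not target:
        return 0
    items = list(hit_sets)
    for size in range(1, len(items) + 1):
        for subset in combinations(items, size):
            union = frozenset().union(*subset)
            if target <= union:
                return size
    return None
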