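"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exhaustive
topology search for trees, naive maximal-run scanning for segments.
"""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Exhaustive unrooted tree search (least-squares fit to a distance matrix)
# ---------------------------------------------------------------------------

def _all_topologies(n_taxa):
    """All unrooted binary topologies by sequential taxon addition.

    A tree is an edge list over node ids; taxa are 0..n-1, internal nodes
    get ids >= n. Yields (edges, next_node_id).
    """
    assert n_taxa >= 3
    base = ([(0, n_taxa), (1, n_taxa), (2, n_taxa)], n_taxa + 1)
    trees = [base]
    for taxon in range(3, n_taxa):
        nxt = []
        for edges, nid in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                new_edges = edges[:k] + edges[k + 1:]
                new_edges += [(u, nid), (v, nid), (taxon, nid)]
                nxt.append((new_edges, nid + 1))
        trees = nxt
    return [e for e, _ in trees]


def _paths(edges, n_taxa):
    """Edge-incidence of every leaf-pair path: dict pair -> edge index set."""
    adj = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))

    def path(a, b):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node == b:
                return used
            for nb, ek in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node, used + [ek]))
        raise AssertionError("disconnected tree")

    return {(i, j): path(i, j)
            for i, j in itertools.combinations(range(n_taxa), 2)}


def ls_best_topology(d):
    """Exhaustive least-squares tree: returns (bipartitions, rss, patristic).

    Fits branch lengths by unconstrained OLS for each of the possible
    unrooted topologies and keeps the best residual sum of squares.
    ``bipartitions`` are frozensets of taxon indices (side not containing
    taxon 0); ``patristic`` is the fitted leaf-to-leaf distance matrix.
    """
    n = d.shape[0]
    best = None
    for edges in _all_topologies(n):
        pairs = _paths(edges, n)
        keys = sorted(pairs)
        a = np.zeros((len(keys), len(edges)))
        y = np.array([d[i, j] for i, j in keys])
        for r, key in enumerate(keys):
            a[r, pairs[key]] = 1.0
        x, *_ = np.linalg.lstsq(a, y, rcond=None)
        rss = float(np.sum((a @ x - y) ** 2))
        if best is None or rss < best[1] - 1e-12:
            fitted = np.zeros_like(d)
            for (i, j), _ in zip(keys, range(len(keys))):
                fitted[i, j] = fitted[j, i] = sum(x[k] for k in pairs[(i, j)])
            best = (_bipartitions_from_edges(edges, n), rss, fitted)
    return best


def _bipartitions_from_edges(edges, n_taxa):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) is cut
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_taxa:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < n_taxa - 1:
            out.add(frozenset(side) if 0 not in side
                    else frozenset(set(range(n_taxa)) - side))
    return out


def random_additive_matrix(n_taxa, rng):
    """Random binary topology with branch lengths in [0.1, 1]; returns
    (distance matrix, bipartition set)."""
    topos = _all_topologies(n_taxa)
    edges = topos[rng.integers(0, len(topos))]
    lengths = rng.uniform(0.1, 1.0, len(edges))
    pairs = _paths(edges, n_taxa)
    d = np.zeros((n_taxa, n_taxa))
    for (i, j), eks in pairs.items():
        d[i, j] = d[j, i] = sum(lengths[k] for k in eks)
    return d, _bipartitions_from_edges(edges, n_taxa)


# ---------------------------------------------------------------------------
# Naive maximal-run scanner (shared-segment oracle)
# ---------------------------------------------------------------------------

def naive_segments(x, y, cm, bp, min_markers, min_cm, missing=-1):
    """All kept shared segments between two haplotype vectors, by direct
    scan: maximal runs of (match or missing), trimmed to informative
    markers, thresholded on informative count and cM span.

    Returns (start, end, bp_length) tuples in marker coordinates.
    """
    n = len(x)
    out = []
    s = 0
    for e in range(n + 1):
        mismatch = e == n or (x[e] != missing and y[e] != missing and x[e] != y[e])
        if mismatch:
            info = [k for k in range(s, e)
                    if x[k] != missing and y[k] != missing]
            if info:
                s2, e2 = info[0], info[-1] + 1
                if (len(info) >= min_markers
                        and cm[e2 - 1] - cm[s2] >= min_cm):
                    out.append((s2, e2, int(bp[e2 - 1] - bp[s2] + 1)))
            s = e + 1
    return out
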