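"""IBS distances, neighbor-joining trees, bootstrap support, consensus.

The distance used is allele-mismatch identity-by-state: per marker typed
in both samples, identical genotypes score 0, het vs either hom 0.5,
opposite homozygotes 1, and the pairwise distance is the mean over
co-typed markers ("flat missing" handling: missing markers drop out of
that pair's denominator only).

Trees are dendropy objects wrapped in :class:`SupportTree`, which also
carries per-bipartition bootstrap support. The NJ implementation is the
Saitou-Nei agglomeration with a deterministic lowest-index tie-break and
negative branch lengths clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")


@dataclass
class SupportTree:
    """A tree plus per-internal-bipartition bootstrap support (percent).

    Bipartitions are keyed by the frozenset of leaf labels on the side
    *not* containing the reference (lexicographically smallest) leaf, so
    keys are stable under rerooting.
    """
    tree: dendropy.Tree
    support: dict[frozenset, float] = field(default_factory=dict)
    replicates: list = field(default_factory=list, repr=False)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)

    def newick(self) -> str:
        """Newick with bootstrap supports as internal-node labels."""
        t = self.tree.clone(depth=1)
        labels = {l.taxon.label for l in t.leaf_node_iter()}
        ref = min(labels)
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            key = side if ref not in side else frozenset(labels - side)
            if key in self.support:
                node.label = f"{self.support[key]:g}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def _normalize(side: frozenset, labels: frozenset, ref: str) -> frozenset:
    return side if ref not in side else labels - side


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions, each as the normalized leaf-label side."""
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = _normalize(side, labels, ref)
        if 1 < len(key) < len(labels) - 1:
            out.add(key)
    return out


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------

def _ibs_matrix(g: np.ndarray, ids: list[str]) -> np.ndarray:
    n = len(ids)
    gf = g.astype(np.float64)
    gf[g == MISSING] = np.nan
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(gf[i + 1:] - gf[i])          # nan where either missing
        denom = np.sum(~np.isnan(diff), axis=1)
        bad = np.flatnonzero(denom == 0)
        if bad.size:
            j = i + 1 + bad[0]
            raise ValueError(
                f"samples {ids[i]!r} and {ids[j]!r} share no co-typed markers")
        with np.errstate(invalid="ignore"):
            d[i, i + 1:] = np.nansum(diff, axis=1) / denom / 2.0
    return d + d.T


def ibs_distance(ds: GenotypeDataset) -> DistanceMatrix:
    """1 - IBS allele-sharing distance with flat missing handling."""
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    return DistanceMatrix(ds.sample_ids, _ibs_matrix(ds.genotypes, ds.sample_ids))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining; unrooted, negative lengths clamped to 0.

    Q-criterion ties are broken by the lowest (i, j) pair in the current
    node ordering, which makes the result deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in dm.ids]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima: lexicographic scan of argwhere
        qmin = q.min()
        i_loc, j_loc = map(int, np.argwhere(np.isclose(q, qmin, rtol=0, atol=0))[0])
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        ai, aj = active[i_loc], active[j_loc]
        dij = d[ai, aj]
        li = 0.5 * dij + (row_sums[i_loc] - row_sums[j_loc]) / (2 * (r - 2))
        lj = dij - li
        new = dendropy.Node()
        new.add_child(nodes[ai])
        nodes[ai].edge.length = clamp(li)
        new.add_child(nodes[aj])
        nodes[aj].edge.length = clamp(lj)
        # distances from the new node
        dnew = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, dnew])
        d = np.hstack([d, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = clamp(ln)
    if n_clamped:
        logger.info("neighbor_joining: clamped %d negative branch length(s)", n_clamped)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return SupportTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(ds: GenotypeDataset, n_reps: int = 100,
                      seed: int = 0) -> SupportTree:
    """NJ tree on the full data with marker-bootstrap support.

    Each replicate resamples markers with replacement, recomputes the IBS
    distance and NJ tree; support of a bipartition of the base tree is the
    percentage of replicates containing it. The replicate trees are kept
    on ``.replicates`` for consensus / monophyly queries.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = neighbor_joining(ibs_distance(ds))
    m = ds.markers.n_markers
    reps = []
    for _ in range(n_reps):
        cols = rng.integers(0, m, m)
        rep_dm = DistanceMatrix(ds.sample_ids,
                                _ibs_matrix(ds.genotypes[:, cols], ds.sample_ids))
        reps.append(neighbor_joining(rep_dm))
    counts: dict[frozenset, int] = {}
    for rep in reps:
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    base.support = {bp: 100.0 * counts.get(bp, 0) / n_reps
                    for bp in base.bipartitions()}
    base.replicates = reps
    return base


def majority_consensus(trees: list) -> SupportTree:
    """Extended majority-rule consensus.

    Bipartitions occurring in more than half the trees are retained, then
    remaining bipartitions are added in decreasing frequency order when
    compatible with everything already accepted.
    """
    trees = [t.tree if isinstance(t, SupportTree) else t for t in trees]
    if not trees:
        raise ValueError("need at least one tree")
    leaf_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    labels = leaf_sets[0]
    if any(ls != labels for ls in leaf_sets):
        raise ValueError("consensus requires identical leaf sets")
    ref = min(labels)
    n = len(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for bp in tree_bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1

    def compatible(c: frozenset, accepted: list[frozenset]) -> bool:
        return all(c.isdisjoint(a) or c <= a or a <= c for a in accepted)

    order = sorted(counts, key=lambda c: (-counts[c], -len(c), tuple(sorted(c))))
    accepted: list[frozenset] = []
    for c in order:
        if counts[c] * 2 > n:
            accepted.append(c)     # majority bipartitions are mutually compatible
        elif compatible(c, accepted):
            accepted.append(c)

    # build a rooted-at-ref clade tree and unroot it
    taxa = dendropy.TaxonNamespace(sorted(labels))
    top = dendropy.Node()
    rest = frozenset(labels - {ref})
    placed: list[tuple[frozenset, dendropy.Node]] = [(rest, top)]
    support: dict[frozenset, float] = {}
    for c in sorted(accepted, key=len, reverse=True):
        container = min((p for p in placed if c <= p[0]), key=lambda p: len(p[0]))
        node = dendropy.Node()
        node.edge.length = 1.0
        container[1].add_child(node)
        placed.append((c, node))
        support[c] = 100.0 * counts[c] / n
    for leaf in sorted(labels):
        lnode = dendropy.Node(taxon=taxa.get_taxon(leaf))
        lnode.edge.length = 1.0
        if leaf == ref:
            top.add_child(lnode)
        else:
            container = min((p for p in placed if leaf in p[0]),
                            key=lambda p: len(p[0]))
            container[1].add_child(lnode)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=top)
    tree.is_rooted = False
    return SupportTree(tree, support)


def root_with_outgroup(st: SupportTree, outgroup_label: str) -> SupportTree:
    """Root at the midpoint of the outgroup's pendant edge."""
    t = st.tree.clone(depth=1)
    node = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup_label:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_label!r} not in tree")
    if node.parent_node is not None and node.parent_node.parent_node is None \
            and len(node.parent_node.child_nodes()) == 2:
        return SupportTree(t, dict(st.support))    # already rooted there
    length = node.edge.length or 0.0
    t.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                     update_bipartitions=False)
    t.is_rooted = True
    return SupportTree(t, dict(st.support))


def monophyly_frequency(bootstrap_trees: list, label_group, query: str | None = None) -> float:
    """Percent of replicate trees in which the group forms a clade.

    With ``query`` set, the tested group is group ∪ {query} (e.g. does the
    focal breed join the clade). A group forms a clade on an unrooted tree
    when the corresponding bipartition exists or the group is trivial
    (empty complement, singletons).
    """
    group = set(label_group)
    if query is not None:
        group.add(query)
    if not group:
        raise ValueError("empty group")
    trees = [t.tree if isinstance(t, SupportTree) else t for t in bootstrap_trees]
    hits = 0
    for t in trees:
        labels = frozenset(l.taxon.label for l in t.leaf_node_iter())
        if not group <= labels:
            raise ValueError("group contains labels absent from the tree")
        if len(group) <= 1 or len(labels) - len(group) <= 1:
            hits += 1
            continue
        key = _normalize(frozenset(group), labels, min(labels))
        if key in tree_bipartitions(t):
            hits += 1
    return 100.0 * hits / len(trees)


def collapse_breed_clades(st: SupportTree, breed_map: dict,
                          support_threshold: float = 100.0) -> str:
    """Breed-level cladogram rendering: newick in which any clade with
    bootstrap support >= ``support_threshold`` whose samples all belong
    to one breed is collapsed to a single tip labeled with that breed.

    ``breed_map`` maps leaf labels to breed codes. A reporting helper;
    the tree itself is not modified.
    """
    labels = frozenset(l.taxon.label for l in st.tree.leaf_node_iter())
    ref = min(labels)

    def render(node):
        if node.is_leaf():
            return node.taxon.label
        leaves = [l.taxon.label for l in node.leaf_iter()]
        breeds = {breed_map.get(l) for l in leaves}
        if len(breeds) == 1 and None not in breeds and node.parent_node is not None:
            side = frozenset(leaves)
            key = _normalize(side, labels, ref)
            sup = st.support.get(key, 100.0 if len(leaves) == 1 else None)
            if sup is not None and sup >= support_threshold:
                return next(iter(breeds))
        parts = ",".join(render(c) for c in node.child_nodes())
        sup = None
        if node.parent_node is not None:
            key = _normalize(frozenset(leaves), labels, ref)
            sup = st.support.get(key)
        return f"({parts})" + (f"{sup:g}" if sup is not None else "")

    return render(st.tree.seed_node) + ";"
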