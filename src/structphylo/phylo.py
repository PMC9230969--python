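"""Distance-based tree inference and tree utilities.

Implements Saitou-Nei neighbour joining and Gascuel's BioNJ (the
variance-weighted NJ variant used for the structure tree), midpoint rooting,
Felsenstein bootstrap supports over p-distance NJ replicates, Newick I/O and
Robinson-Foulds comparison.  Trees are carried as dendropy trees inside a
thin wrapper so that Newick round-trips and rooting reuse the standard
machinery.

Both tree builders are bitwise deterministic: joins that tie on the Q
criterion are resolved by the lexicographically smallest label pair, where a
cluster is labelled by the smallest leaf it contains.  Negative branch-length
estimates are clamped to zero (PHYLIP convention) and the deficit logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from structphylo.structio import DistanceMatrix, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class BootstrapParams:
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


class PhyloTree:
    """Rooted or unrooted phylogeny with branch lengths and optional supports."""

    def __init__(self, dtree: dendropy.Tree):
        self.dtree = dtree

    # -- construction / serialisation -------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(dt)

    def to_newick(self) -> str:
        return (
            self.dtree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".6g",
            ).strip()
        )

    # -- basic accessors ----------------------------------------------------
    @property
    def leaf_labels(self) -> list:
        return sorted(lf.taxon.label for lf in self.dtree.leaf_node_iter())

    def branch_lengths(self) -> list:
        return [
            e.length for e in self.dtree.preorder_edge_iter()
            if e.length is not None
        ]

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaf pairs."""
        pdm = self.dtree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self.dtree.taxon_namespace}
        n = len(labels)
        M = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        return DistanceMatrix(labels, M)

    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets of the side excluding the
        lexicographically smallest leaf (rooting-independent encoding)."""
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)
        splits = set()
        for node in self.dtree.preorder_internal_node_iter():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
                continue
            if anchor in side:
                side = frozenset(all_leaves - side)
            splits.add(side)
        return splits


# ---------------------------------------------------------------------------
# score -> distance
# ---------------------------------------------------------------------------

def tm_to_distance(tm: DistanceMatrix, transform: str = "one_minus") -> DistanceMatrix:
    """Convert a TM-score matrix to distances.

    ``one_minus`` (default): d = 1 - TM, the minimal monotone transform with
    d(x, x) = 0.  ``neg_log``: d = -ln(TM).
    """
    V = tm.values
    if np.any(V <= 0):
        raise ValueError("TM-scores must be in (0, 1]")
    if transform == "one_minus":
        D = 1.0 - V
    elif transform == "neg_log":
        D = -np.log(V)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(D, 0.0)
    D[D < 0] = 0.0
    return DistanceMatrix(list(tm.labels), D)


# ---------------------------------------------------------------------------
# NJ / BioNJ agglomeration
# ---------------------------------------------------------------------------

def _check_distance_input(D: DistanceMatrix):
    V = D.values
    if np.any(V < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(V, V.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative branch estimate %.6g at %s clamped to 0", length, context)
        return 0.0
    return length


def _agglomerate(D: DistanceMatrix, bionj: bool) -> PhyloTree:
    _check_distance_input(D)
    n0 = len(D.labels)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    tns = dendropy.TaxonNamespace()
    # active cluster state: node, canonical label (min leaf label)
    nodes = []
    keys = []
    for lab in D.labels:
        taxon = tns.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        keys.append(lab)
    dist = D.values.astype(float).copy()
    var = dist.copy()  # BioNJ variance estimates, initialised to distances
    active = list(range(n0))

    while len(active) > 2:
        n = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist[i, j]
        li = _clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2)), f"join({keys[i]},{keys[j]})")
        lj = _clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))),
                    f"join({keys[j]},{keys[i]})")
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # variance-weighted reduction (lambda = 1/2 recovers plain NJ)
        if bionj and var[i, j] > 1e-12 and n > 3:
            others = [k for k in active if k != i and k != j]
            lam = 0.5 + sum(var[j, k] - var[i, k] for k in others) / (
                2.0 * (n - 2) * var[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = i  # reuse slot i for the merged cluster
        for k in active:
            if k == i or k == j:
                continue
            duk = lam * (dist[i, k] - li) + (1.0 - lam) * (dist[j, k] - lj)
            vuk = lam * var[i, k] + (1.0 - lam) * var[j, k] - lam * (1.0 - lam) * var[i, j]
            dist[u, k] = dist[k, u] = max(0.0, duk)
            var[u, k] = var[k, u] = max(0.0, vuk)
        nodes[u] = parent
        keys[u] = min(keys[i], keys[j])
        active.remove(j)

    i, j = active
    dij = dist[i, j]
    if nodes[i].is_leaf() and nodes[j].is_leaf():
        root = dendropy.Node()
        root.add_child(nodes[i]); nodes[i].edge.length = dij / 2.0
        root.add_child(nodes[j]); nodes[j].edge.length = dij / 2.0
    else:
        # graft the second cluster onto the first internal node so that the
        # final edge keeps its full length (unrooted semantics)
        if nodes[i].is_leaf():
            i, j = j, i
        root = nodes[i]
        root.add_child(nodes[j])
        nodes[j].edge.length = max(0.0, dij)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour-joining tree (unrooted)."""
    return _agglomerate(D, bionj=False)


def bionj_tree(D: DistanceMatrix) -> PhyloTree:
    """Gascuel's BioNJ tree (unrooted): NJ joins with variance-weighted
    reduction of the distance matrix."""
    return _agglomerate(D, bionj=True)


# ---------------------------------------------------------------------------
# rooting, RF, bootstrap
# ---------------------------------------------------------------------------

def midpoint_root(t: PhyloTree) -> PhyloTree:
    """Root on the midpoint of the longest leaf-to-leaf path.

    The midpoint is located by an explicit walk along the longest path
    (treating the tree as an undirected graph), so a pre-existing degree-2
    root splitting the central edge is handled correctly; the two
    root-to-extreme-leaf distances of the result are equal to within 1e-9.
    """
    total = sum(l for l in t.branch_lengths() if l)
    dt = dendropy.Tree(t.dtree)  # work on a clone
    if total <= 0:
        warnings.warn("all-zero branch lengths: rooting arbitrarily at first internal node")
        internal = next(dt.preorder_internal_node_iter())
        dt.reroot_at_node(internal)
        dt.is_rooted = True
        return PhyloTree(dt)

    # undirected adjacency with edge lengths
    adj = {}
    for node in dt.preorder_node_iter():
        for ch in node.child_nodes():
            w = ch.edge.length or 0.0
            adj.setdefault(node, []).append((ch, w))
            adj.setdefault(ch, []).append((node, w))

    def far_from(start):
        dist, prev = {start: 0.0}, {start: None}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        leaves = [n for n in dist if n.is_leaf()]
        end = max(leaves, key=lambda n: dist[n])
        return end, dist, prev

    some_leaf = next(dt.leaf_node_iter())
    u, _, _ = far_from(some_leaf)
    v, dist_u, prev_u = far_from(u)
    half = dist_u[v] / 2.0
    # walk the u -> v path until the midpoint falls inside (or on) an edge
    path = [v]
    while prev_u[path[-1]] is not None:
        path.append(prev_u[path[-1]])
    path.reverse()  # u ... v
    node = u
    for nxt in path[1:]:
        w = next(w for nbr, w in adj[node] if nbr is nxt)
        if dist_u[node] + w >= half - 1e-12:
            offset = half - dist_u[node]
            if offset <= 1e-12 and not node.is_leaf():
                dt.reroot_at_node(node, update_bipartitions=False)
            elif w - offset <= 1e-12 and not nxt.is_leaf():
                dt.reroot_at_node(nxt, update_bipartitions=False)
            else:
                # identify the parent->child orientation of this edge
                child = nxt if nxt.parent_node is node else node
                from_parent = offset if child is nxt else w - offset
                dt.reroot_at_edge(child.edge, length1=from_parent,
                                  length2=w - from_parent,
                                  update_bipartitions=False)
            break
        node = nxt
    dt.suppress_unifurcations()
    dt.seed_node.edge.length = None  # drop any inherited root-edge length
    dt.is_rooted = True
    return PhyloTree(dt)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple:
    """Robinson-Foulds distance: splits present in exactly one tree.

    Returns (rf, normalized) with the normaliser 2*(n-3), the maximum for
    binary unrooted trees.
    """
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        only1, only2 = sorted(l1 - l2), sorted(l2 - l1)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    s1, s2 = t1.bipartitions(), t2.bipartitions()
    rf = len(s1 ^ s2)
    n = len(l1)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


def p_distance_matrix(records: list) -> DistanceMatrix:
    """Pairwise p-distances over an aligned set, skipping sites where either
    sequence has a gap."""
    labels = [r.id for r in records]
    arr = np.array([list(r.seq) for r in records])
    gap = (arr == "-") | (arr == ".")
    n = len(records)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gap[i] | gap[j])
            nv = int(valid.sum())
            if nv == 0:
                warnings.warn(f"no comparable sites for {labels[i]}/{labels[j]}")
                p = 0.0
            else:
                p = float(np.sum(arr[i, valid] != arr[j, valid])) / nv
            M[i, j] = M[j, i] = p
    return DistanceMatrix(labels, M)


def bootstrap_supports(records: list, params: BootstrapParams) -> PhyloTree:
    """NJ tree on p-distances with Felsenstein bootstrap supports.

    Columns are resampled with replacement (seeded); the support of each
    internal edge of the reference tree is the fraction of replicate trees
    containing the same bipartition.  Supports are stored as internal-node
    labels (fractions in [0, 1]).
    """
    if len(records) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    ncols = len(records[0].seq)
    if ncols < 2:
        raise ValueError("alignment must have at least 2 columns")
    if len({r.seq for r in records}) < 2:
        raise ValueError("alignment has fewer than 2 distinct sequences")
    records = sorted(records, key=lambda r: r.id)  # row-order invariance
    ref = nj_tree(p_distance_matrix(records))
    ref_splits = ref.bipartitions()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(params.seed)
    arr = np.array([list(r.seq) for r in records])
    for _ in range(params.n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        boot = [
            SequenceRecord(r.id, "".join(arr[k][cols])) for k, r in enumerate(records)
        ]
        rep_splits = nj_tree(p_distance_matrix(boot)).bipartitions()
        for s in ref_splits & rep_splits:
            counts[s] += 1
    all_leaves = set(ref.leaf_labels)
    anchor = min(all_leaves)
    for node in ref.dtree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        if anchor in side:
            side = frozenset(all_leaves - side)
        node.label = f"{counts[side] / params.n_replicates:.3f}"
    return ref


def newick_read(path_or_text) -> PhyloTree:
    """Read a Newick tree from a path or a literal string."""
    text = str(path_or_text)
    if not text.lstrip().startswith("("):
        from pathlib import Path
        text = Path(path_or_text).read_text()
    return PhyloTree.from_newick(text)


def newick_write(t: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(t.to_newick() + "\n")
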