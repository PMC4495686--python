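"""Distance-based phylogeny from the variant supermatrix.

The internal tree builder is deliberately distance-based: pairwise
p-distances (or their JC69 transform) are computed from the variant
supermatrix with pairwise deletion of missing cells -- the pipeline
deliberately retains missing-rich matrices, so complete-case deletion would
discard most of the signal -- and a neighbor-joining tree (Saitou-Nei
Q-criterion, deterministic lexicographic tie-breaking, negative branch
lengths clamped to zero) is estimated.  Node support comes from the
nonparametric bootstrap: columns are resampled with replacement, the tree is
re-estimated per replicate, and each internal bipartition of the point
estimate is annotated with the percentage of replicates containing it
(1,000 replicates by default).  For maximum-likelihood inference with
ascertainment-bias correction, export the matrix as PHYLIP instead and use
an external program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .supermatrix import VariantSupermatrix

__all__ = [
    "SpeciesTree",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "compare_topologies",
    "newick_bipartitions",
]


@dataclass
class SpeciesTree:
    """Unrooted phylogeny: newick, leaf set, canonical bipartitions and
    (after bootstrapping) internal-node support percentages in [0, 100]."""

    newick: str
    leaves: frozenset
    bipartitions: frozenset  # of frozensets, canonical (side w/o min leaf)
    support: dict = field(default_factory=dict)  # bipartition -> pct

    def as_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 taxon_namespace=taxon_namespace)


def distance_matrix(matrix: VariantSupermatrix,
                    model: str = "p-distance") -> tuple[list[str], np.ndarray]:
    """Pairwise distances with pairwise deletion of missing cells.

    p-distance = mismatches / shared non-missing columns; JC69 applies
    -(3/4) ln(1 - 4p/3) and is undefined at p >= 0.75.  A species pair with
    zero shared columns is an error naming the pair.
    """
    if model not in ("p-distance", "JC69"):
        raise ValueError(f"unknown distance model {model!r}")
    sp = matrix.species
    n = len(sp)
    present = matrix.data != "N"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            n_shared = int(np.sum(shared))
            if n_shared == 0:
                raise ValueError(f"species pair ({sp[i]}, {sp[j]}) shares "
                                 f"no non-missing columns")
            p = float(np.sum(matrix.data[i, shared] != matrix.data[j, shared])
                      ) / n_shared
            if model == "JC69":
                if p >= 0.75:
                    raise ValueError(f"JC69 distance undefined for pair "
                                     f"({sp[i]}, {sp[j]}): p = {p:.3f} >= 0.75")
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return list(sp), d


class _Node:
    __slots__ = ("name", "children", "leafset", "key")

    def __init__(self, name, children, leafset, key):
        self.name = name
        self.children = children  # list of (node, branch_length)
        self.leafset = leafset
        self.key = key  # min leaf name, for deterministic tie-breaking


def _render(node: _Node, support: dict | None, all_leaves: frozenset) -> str:
    if not node.children:
        return node.name
    inner = ",".join(f"{_render(ch, support, all_leaves)}:{bl:.6f}"
                     for ch, bl in node.children)
    label = ""
    if support is not None:
        bip = _canonical(node.leafset, all_leaves)
        if bip in support:
            label = f"{support[bip]:g}"
    return f"({inner}){label}"


def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Represent a bipartition by the side not containing the smallest leaf."""
    return side if min(all_leaves) not in side else all_leaves - side


def neighbor_joining(names: list[str], d: np.ndarray,
                     support: dict | None = None) -> SpeciesTree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the lexicographically smallest (min leaf
    of i, min leaf of j) pair; negative branch-length estimates are clamped
    to zero.  Requires >= 3 taxa.
    """
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    all_leaves = frozenset(names)
    nodes = [_Node(nm, [], frozenset([nm]), nm) for nm in names]
    active = list(range(n))
    dd = {(i, j): float(d[i, j]) for i in range(n) for j in range(n)}
    bips = set()
    next_id = n

    def dist(i, j):
        return dd[(i, j)] if i <= j else dd[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = tuple(sorted((nodes[i].key, nodes[j].key)))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(None, [(nodes[i], li), (nodes[j], lj)],
                    nodes[i].leafset | nodes[j].leafset,
                    min(nodes[i].key, nodes[j].key))
        u = next_id
        next_id += 1
        nodes.append(new)
        for k in active:
            if k not in (i, j):
                dd[(min(k, u), max(k, u))] = \
                    (dist(i, k) + dist(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]
        if 2 <= len(new.leafset) <= len(all_leaves) - 2:
            bips.add(_canonical(new.leafset, all_leaves))

    a, b, c = sorted(active, key=lambda k: nodes[k].key)
    la = max((dist(a, b) + dist(a, c) - dist(b, c)) / 2.0, 0.0)
    lb = max((dist(a, b) + dist(b, c) - dist(a, c)) / 2.0, 0.0)
    lc = max((dist(a, c) + dist(b, c) - dist(a, b)) / 2.0, 0.0)
    root = _Node(None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)],
                 all_leaves, min(nodes[k].key for k in active))
    newick = _render(root, support, all_leaves) + ";"
    return SpeciesTree(newick, all_leaves, frozenset(bips),
                       dict(support) if support else {})


def bootstrap_support(matrix: VariantSupermatrix, n_replicates: int = 1000,
                      seed: int = 0, model: str = "p-distance") -> SpeciesTree:
    """Bootstrap the supermatrix columns and annotate the point-estimate tree.

    Support of an internal bipartition is the percentage of replicate trees
    containing it.  Replicates in which a species pair loses all shared
    columns (possible in missing-rich matrices) are skipped; support is
    relative to the completed replicates.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    names, d = distance_matrix(matrix, model)
    point = neighbor_joining(names, d)
    rng = np.random.default_rng(seed)
    counts = {bip: 0 for bip in point.bipartitions}
    completed = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, matrix.n_columns, size=matrix.n_columns)
        resampled = VariantSupermatrix(matrix.species, matrix.data[:, cols])
        try:
            rn, rd = distance_matrix(resampled, model)
        except ValueError:
            continue
        rep = neighbor_joining(rn, rd)
        completed += 1
        for bip in counts:
            if bip in rep.bipartitions:
                counts[bip] += 1
    denom = max(completed, 1)
    support = {bip: 100.0 * c / denom for bip, c in counts.items()}
    return neighbor_joining(names, d, support=support)


def newick_bipartitions(newick: str) -> tuple[frozenset, frozenset]:
    """(leaf set, canonical internal bipartitions) of a newick tree,
    treated as unrooted."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(_canonical(side, leaves))
    return leaves, frozenset(bips)


def compare_topologies(tree_a, tree_b) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree.

    Arguments may be SpeciesTree objects or newick strings; leaf sets must
    match.
    """
    la, ba = (tree_a.leaves, tree_a.bipartitions) \
        if isinstance(tree_a, SpeciesTree) else newick_bipartitions(tree_a)
    lb, bb = (tree_b.leaves, tree_b.bipartitions) \
        if isinstance(tree_b, SpeciesTree) else newick_bipartitions(tree_b)
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(ba ^ bb)
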