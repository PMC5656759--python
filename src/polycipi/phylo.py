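"""Distance-based phylogenetics: p-distances, neighbor joining, monophyly.

The clade claims exercised here — the family forms one clade, and the three
genera form sub-clades — only need distance-based topology at desk scale,
so the module builds p-distance matrices from pairwise global alignments
(distance = 1 − identity/100, no multiple-hit correction) and joins them
with Saitou–Nei neighbor joining under the Studier–Keppler Q criterion.
Tie-breaking is deterministic (lexicographic by the smallest leaf label
under each node) so trees are reproducible byte for byte. Trees are
scikit-bio ``TreeNode`` objects; Newick I/O and midpoint rooting follow.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .homology import global_align


def pdistance_matrix(peptides: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distance matrix, d(i,j) = 1 − identity(i,j)/100.

    Identity comes from the affine-gap global alignment over all columns.
    Needs at least three peptides; an empty peptide is an error naming the
    taxon.
    """
    if len(peptides) < 3:
        raise ValueError("need at least 3 peptides")
    for tid, pep in peptides:
        if not pep:
            raise ValueError(f"empty peptide for taxon {tid!r}")
    ids = [tid for tid, _ in peptides]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    n = len(peptides)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_align(peptides[i][1], peptides[j][1]).pct_identity
            d[i, j] = d[j, i] = 1.0 - pct / 100.0
    return DistanceMatrix(d, ids)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Q ties are broken by the lexicographically smallest (taxon, taxon)
    key pair, where a node's key is the smallest leaf label beneath it.
    Negative branch lengths are clamped to 0; the total clamped deficit is
    recorded on the returned (unrooted, trifurcating-root) tree as
    ``tree.nj_clamp_deficit``.
    """
    if not isinstance(matrix, DistanceMatrix):
        matrix = DistanceMatrix(matrix)  # validates symmetry / hollowness
    ids = list(matrix.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix[i, j])

    def d(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(min(i, j), max(i, j))]

    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    keys: dict[int, str] = {i: ids[i] for i in range(n)}
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best_q is None or q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and key < best):
                    best_q, best = q, key
                    pair = (i, j)
        i, j = pair
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d(i, j) - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        u = TreeNode(children=[child_i, child_j])
        uid = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(uid, k), max(uid, k))] = (d(i, k) + d(j, k) - d(i, j)) / 2
        nodes[uid] = u
        keys[uid] = min(keys[i], keys[j])
        active = [k for k in active if k not in (i, j)] + [uid]

    i, j, k = active
    root = TreeNode()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        nodes[a].length = clamp((d(a, b) + d(a, c) - d(b, c)) / 2)
        root.append(nodes[a])
    root.nj_clamp_deficit = deficit
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least 2 leaves")
    if len(tips) == 2:
        # a single edge: split it in half explicitly
        a, b = tips
        total = (a.length or 0.0) + (b.length or 0.0)
        left, right = TreeNode(name=a.name), TreeNode(name=b.name)
        left.length = right.length = total / 2
        return TreeNode(children=[left, right])
    return tree.root_at_midpoint()


def is_monophyletic(tree_rooted: TreeNode, taxa_subset: set[str]) -> bool:
    """True iff some node's leaf set equals exactly ``taxa_subset``."""
    subset = set(taxa_subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    leaves = {t.name for t in tree_rooted.tips()}
    if not subset <= leaves:
        raise ValueError(f"subset not within tree leaves: {sorted(subset - leaves)}")
    if subset == leaves:
        return True
    for node in tree_rooted.postorder():
        node_leaves = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if node_leaves == subset:
            return True
    return False


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


def tip_to_tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length matrix between all pairs of leaves (additivity checks)."""
    return tree.tip_tip_distances()
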