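"""Ward hierarchical clustering of the binary allele-presence encoding.

Agglomeration uses Euclidean distances between 0/1 rows and Ward's
minimum-variance criterion via the Lance-Williams update (Ward.D2
semantics, identical heights to scipy's ``linkage(method="ward")`` on
tie-free data).  Because presence/absence encodings of collections with
clones produce many exactly tied merge costs, ties are broken
deterministically by the lexicographically smallest sorted member-id
tuple, which makes every node's member set invariant under permutations of
the input row order.

Node support is estimated by bootstrap resampling of the binary columns
(allele presence characters): a node's support is the fraction of replicate
trees containing a node with the identical member set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import BinaryMatrix

__all__ = [
    "DendrogramNode",
    "ward_cluster",
    "bootstrap_support",
    "cut_clusters",
    "to_newick",
]


@dataclass
class DendrogramNode:
    members: tuple[str, ...]          # sorted accession ids
    height: float = 0.0
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self):
        yield self
        if self.children:
            for c in self.children:
                yield from c.walk()

    def internal_member_sets(self) -> set[tuple[str, ...]]:
        return {
            n.members for n in self.walk()
            if not n.is_leaf and len(n.members) < len(self.members)
        }


def _ward_merge(matrix: np.ndarray, row_ids: list[str]) -> DendrogramNode:
    n = len(row_ids)
    x = matrix.astype(float)
    # squared Euclidean distances; Lance-Williams keeps d^2 updated
    g = x @ x.T
    sq = np.maximum(np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g, 0.0)
    d2 = np.full((n, n), np.inf)
    iu = np.triu_indices(n, 1)
    d2[iu] = sq[iu]
    nodes: list[DendrogramNode | None] = [
        DendrogramNode((rid,)) for rid in row_ids
    ]
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    for _ in range(n - 1):
        vmin = d2.min()
        ties = np.argwhere(np.abs(d2 - vmin) <= 1e-12 * max(vmin, 1.0))
        # tie-break: lexicographically smallest merged member tuple
        best_pair, best_key = None, None
        for i, j in ties:
            key = tuple(sorted(nodes[i].members + nodes[j].members))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (int(i), int(j))
        i, j = best_pair
        node = DendrogramNode(
            best_key, float(np.sqrt(max(vmin, 0.0))), (nodes[i], nodes[j])
        )
        ni, nj = sizes[i], sizes[j]
        nk = sizes
        dik = np.minimum(d2[i, :], d2[:, i])
        djk = np.minimum(d2[j, :], d2[:, j])
        upd = ((ni + nk) * dik + (nj + nk) * djk - nk * vmin) / \
            (ni + nj + nk)
        # merged cluster replaces slot i; slot j retired
        alive[j] = False
        mask = alive.copy()
        mask[i] = False
        d2[i, :] = np.inf
        d2[:, i] = np.inf
        idx = np.where(mask)[0]
        lo = idx[idx < i]
        hi = idx[idx > i]
        d2[lo, i] = upd[lo]
        d2[i, hi] = upd[hi]
        d2[j, :] = np.inf
        d2[:, j] = np.inf
        sizes[i] = ni + nj
        nodes[i] = node
        nodes[j] = None
    return nodes[int(np.where(alive)[0][0])]


def ward_cluster(matrix: BinaryMatrix) -> DendrogramNode:
    """Ward dendrogram of the rows of a binary presence/absence matrix."""
    if len(matrix.rows) < 2:
        raise ValueError("need at least 2 rows to cluster")
    # sort rows by id so the result cannot depend on input order
    order = np.argsort(matrix.rows)
    ids = [matrix.rows[i] for i in order]
    return _ward_merge(matrix.values[order], ids)


def bootstrap_support(matrix: BinaryMatrix, n_boot: int = 1000,
                      seed: int | None = 0) -> DendrogramNode:
    """Attach column-bootstrap supports to the reference Ward tree."""
    root = ward_cluster(matrix)
    if n_boot <= 0:
        return root
    targets = root.internal_member_sets()
    hits = {t: 0 for t in targets}
    rng = np.random.default_rng(seed)
    m = matrix.values.shape[1]
    order = np.argsort(matrix.rows)
    ids = [matrix.rows[i] for i in order]
    base = matrix.values[order]
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        rep_root = _ward_merge(base[:, cols], ids)
        rep_sets = rep_root.internal_member_sets()
        for t in targets & rep_sets:
            hits[t] += 1
    for node in root.walk():
        if not node.is_leaf and node.members in hits:
            node.support = hits[node.members] / n_boot
    return root


def cut_clusters(root: DendrogramNode, k: int | None = None,
                 height: float | None = None) -> dict[str, int]:
    """Cut the tree into clusters; returns accession id -> cluster label.

    Either ``k`` exact clusters (repeatedly splitting the subtree with the
    highest merge, ties by smallest member tuple) or all merges strictly
    above ``height`` broken.  Labels are assigned in order of each
    cluster's smallest member id.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    subtrees = [root]
    if k is not None:
        if k < 1 or k > len(root.members):
            raise ValueError(f"k={k} out of range")
        while len(subtrees) < k:
            cand = max(
                (t for t in subtrees if not t.is_leaf),
                key=lambda t: (t.height, tuple(t.members)),
            )
            subtrees.remove(cand)
            subtrees.extend(cand.children)
    else:
        frontier = [root]
        subtrees = []
        while frontier:
            t = frontier.pop()
            if not t.is_leaf and t.height > height:
                frontier.extend(t.children)
            else:
                subtrees.append(t)
    subtrees.sort(key=lambda t: t.members[0])
    labels = {}
    for ci, t in enumerate(subtrees, start=1):
        for acc in t.members:
            labels[acc] = ci
    return labels


def _newick(node: DendrogramNode, parent_height: float) -> str:
    length = max(parent_height - node.height, 0.0)
    if node.is_leaf:
        name = node.members[0].replace(" ", "_")
        return f"{name}:{length:g}"
    left = _newick(node.children[0], node.height)
    right = _newick(node.children[1], node.height)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({left},{right}){label}:{length:g}"


def to_newick(root: DendrogramNode) -> str:
    """Newick string with merge-height branch lengths and support labels."""
    left = _newick(root.children[0], root.height) if root.children else \
        root.members[0]
    if root.is_leaf:
        return f"{root.members[0]};"
    right = _newick(root.children[1], root.height)
    label = "" if root.support is None else f"{root.support:g}"
    return f"({left},{right}){label};"
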