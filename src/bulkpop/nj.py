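"""Neighbor-joining tree construction (Saitou-Nei agglomeration).

At each step the pair minimizing the Q-criterion

    Q(i, j) = (n − 2) d(i, j) − Σ_k d(i, k) − Σ_k d(j, k)

is joined; ties break toward the lexicographically smallest pair of node
labels (internal nodes are labeled by their smallest descendant leaf), so
the output is deterministic. Negative branch lengths are clamped to zero
with the deficit transferred to the sibling branch, preserving the joined
pair's path length. On an additive input matrix the tree's path-length
matrix reproduces the input exactly.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = ["neighbor_joining", "tree_path_lengths"]


def _clamp(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix (n ≥ 3)."""
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    keys: list[str] = [str(i) for i in dm.ids]  # smallest descendant leaf

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = 0
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    pair = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair < best:
                        best, bi, bj = pair, i, j
        i, j = bi, bj
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        du = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    a, b = nodes
    final = max(d[0, 1], 0.0)
    if len(a.children) == 0 and len(b.children) > 0:
        a, b = b, a
    b.length = final
    a.append(b)
    a.length = None
    return a


def tree_path_lengths(tree: TreeNode, ids: list[str] | None = None) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    dm = tree.tip_tip_distances()
    if ids is not None:
        dm = dm.filter(ids)
    return dm
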