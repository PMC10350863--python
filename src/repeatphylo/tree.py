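"""Neighbor-joining tree inference and rooting.

Implements the Saitou & Nei agglomeration directly: at each step the
pair (i, j) minimising

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j,    r_i = sum_k d(i, k)

is joined; branch lengths to the new node are

    v_i = d(i, j)/2 + (r_i - r_j) / (2 (n - 2)),    v_j = d(i, j) - v_i

and the reduced matrix uses d(u, k) = (d(i, k) + d(j, k) - d(i, j))/2.
On an additive matrix this reconstructs the generating tree exactly
(path lengths reproduce the input distances). Ties in Q are broken by
the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf name), so the result is deterministic.

Trees are :class:`skbio.TreeNode` objects; Newick I/O, midpoint
rooting and path-length queries go through scikit-bio.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "midpoint_root",
    "read_newick",
    "write_newick",
    "to_newick",
]


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree from a species distance matrix.

    Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister branch, so all output lengths are
    non-negative while leaf-to-leaf path lengths are preserved where
    possible. The returned tree has a trifurcating (unrooted) root for
    more than three taxa.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(matrix.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    # a cluster's tie-break label is its smallest leaf name
    keys: list[str] = list(labels)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None  # (q, key_small, key_big, i, j)
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                ka, kb = sorted((keys[i], keys[j]))
                cand = (q, ka, kb)
                if best is None or cand < best[:3]:
                    best = (q, ka, kb, i, j)
        _, _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp_pair(vi, vj)

        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = vi, vj
        parent.extend([a, b])

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # terminal three-point formulas
    (da_b, da_c, db_c) = d[0, 1], d[0, 2], d[1, 2]
    va = 0.5 * (da_b + da_c - db_c)
    vb = 0.5 * (da_b + db_c - da_c)
    vc = 0.5 * (da_c + db_c - da_b)
    root = TreeNode()
    for node, v in zip(nodes, (va, vb, vc)):
        node.length = max(v, 0.0)
        root.append(node)
    return root


def _clamp_pair(vi: float, vj: float) -> tuple[float, float]:
    """Clamp a negative estimate to 0, moving the deficit to its sister."""
    if vi < 0:
        vj = max(vj + vi, 0.0)
        vi = 0.0
    elif vj < 0:
        vi = max(vi + vj, 0.0)
        vj = 0.0
    return vi, vj


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Leaf-to-leaf path lengths are preserved; the unrooted topology is
    unchanged. Raises if every branch length is zero (the midpoint is
    then undefined).
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    work = tree.copy()
    for node in work.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    if work.tip_tip_distances().data.max() == 0.0:
        raise ValueError("all leaf-to-leaf distances are zero; midpoint undefined")
    if len(tips) == 2:
        first, second = work.tips()
        total = first.length + second.length
        root = TreeNode()
        root.extend([
            TreeNode(name=first.name, length=total / 2.0),
            TreeNode(name=second.name, length=total / 2.0),
        ])
        return root
    rooted = work.root_at_midpoint()
    return rooted


def read_newick(source: str | Path) -> TreeNode:
    """Read a Newick tree from a path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.rstrip().endswith(";")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return TreeNode.read(_io.StringIO(text))


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths at 6 significant digits."""
    out = _io.StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
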