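"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations: a pure-Python affine-gap
Smith-Waterman, exhaustive Dollo labeling enumeration and exhaustive
split enumeration. They share no code with the package.
"""

from __future__ import annotations

from itertools import product


def smith_waterman_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
) -> int:
    """Optimal local alignment score, affine gaps (Gotoh), pure Python.

    Gap of length L costs gap_open + (L-1) * gap_extend. 'N' scores as a
    mismatch against everything, including 'N'.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    best = 0
    # H: best ending in match/mismatch; E: gap in a (consume b); F: gap in b
    H_prev = [0] * (m + 1)
    E_prev = [NEG] * (m + 1)
    F_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        H = [0] * (m + 1)
        E = [NEG] * (m + 1)
        F = [NEG] * (m + 1)
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            E[j] = max(H[j - 1] + gap_open, E[j - 1] + gap_extend)
            F[j] = max(H_prev[j] + gap_open, F_prev[j] + gap_extend)
            H[j] = max(0, H_prev[j - 1] + s, E[j], F[j])
            if H[j] > best:
                best = H[j]
        H_prev, E_prev, F_prev = H, E, F
    return best


def dollo_min_losses(pattern: set[str], tree) -> int:
    """Minimum losses under a single gain, by exhaustive labeling.

    Enumerates every 0/1 assignment to internal nodes of a rooted
    skbio TreeNode (leaf states fixed by the pattern); a gain is a
    0->1 change on an edge, or state 1 at the top of the stem; exactly
    one gain is allowed; losses are 1->0 changes. Exponential - use on
    small trees only.
    """
    internal = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    leaves = [n for n in tree.tips()]
    best = None
    for states in product((0, 1), repeat=len(internal)):
        label = {id(n): s for n, s in zip(internal, states)}
        for leaf in leaves:
            label[id(leaf)] = 1 if leaf.name in pattern else 0
        gains = label[id(tree)]  # a root in state 1 was gained on the stem
        losses = 0
        ok = True
        for node in tree.traverse(include_self=True):
            for child in node.children:
                a, b = label[id(node)], label[id(child)]
                if a == 0 and b == 1:
                    gains += 1
                elif a == 1 and b == 0:
                    losses += 1
            if gains > 1:
                ok = False
                break
        if ok and gains == 1 and (best is None or losses < best):
            best = losses
    assert best is not None, "pattern must be realizable with one gain"
    return best


def nontrivial_splits(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, exhaustively.

    Each internal edge induces a split; a split is represented by the
    side not containing the lexicographically smallest leaf, so the two
    orientations coincide.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    anchor = min(all_leaves)
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def rf_distance_bruteforce(t1, t2) -> int:
    s1, s2 = nontrivial_splits(t1), nontrivial_splits(t2)
    return len(s1 ^ s2)
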