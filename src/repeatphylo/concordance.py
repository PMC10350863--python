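"""Concordance between repeat sharing and a reference phylogeny.

Two questions are answered here. First, does the repeat-derived NJ
tree match the reference topology (Robinson–Foulds distance over
unrooted splits)? Second, which individual repeat classes are shared
in a way the reference tree cannot explain without extra events?

The per-class criterion is Dollo parsimony: a repeat arises once (it
must be amplified from a single copy before it is detectable, so
independent identical gains are implausible) and may be lost any
number of times. A sharing pattern that forms a clade of the rooted
reference tree costs zero losses; a pattern shared by non-sister
species while absent from their sisters costs at least one loss and is
flagged *discordant* — the candidate signal for horizontal transfer or
detection-threshold artefacts.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd
from skbio import TreeNode

from .patterns import PresenceMatrix, pattern_label

__all__ = [
    "rf_distance",
    "dollo_cost",
    "flag_discordant",
    "pairwise_exclusive_shared",
    "pairwise_shared_any",
]


def _tip_names(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree.

    Both trees are treated as unrooted; they must share an identical
    leaf set. Zero iff the (unrooted) topologies agree.
    """
    n1, n2 = _tip_names(t1), _tip_names(t2)
    if n1 != n2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(n1 - n2)}, "
            f"only in second {sorted(n2 - n1)}"
        )
    return int(t1.compare_rfd(t2, rooted=False))


def _clades(tree: TreeNode) -> set[frozenset[str]]:
    """Tip sets of every node of a rooted tree (leaves and root included)."""
    out: set[frozenset[str]] = set()
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            out.add(frozenset([node.name]))
        else:
            out.add(frozenset(t.name for t in node.tips()))
    return out


def dollo_cost(pattern: Iterable[str], tree: TreeNode) -> int:
    """Minimum loss count for a pattern under single-gain (Dollo) parsimony.

    The gain is placed on the branch above the most recent common
    ancestor of the pattern; each maximal subtree below that ancestor
    containing no pattern member costs one loss on its stem.
    """
    pattern = set(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    tips = _tip_names(tree)
    unknown = pattern - tips
    if unknown:
        raise ValueError(f"pattern contains unknown leaves: {sorted(unknown)}")
    if len(pattern) == 1:
        return 0
    mrca = tree.lca([t for t in tree.tips() if t.name in pattern])

    def losses(node: TreeNode) -> int:
        if node.is_tip():
            return 0 if node.name in pattern else 1
        total = 0
        for child in node.children:
            below = {t.name for t in child.tips()} if not child.is_tip() else {child.name}
            if below & pattern:
                total += losses(child)
            else:
                total += 1
        return total

    return losses(mrca)


def flag_discordant(matrix: PresenceMatrix, tree: TreeNode) -> pd.DataFrame:
    """Per-class concordance report against a rooted reference tree.

    A class is discordant iff its species pattern has size >= 2 and is
    not the leaf set of any node of the reference tree (not a clade).
    Singleton patterns and the full species set are never discordant.
    Columns: class_id, pattern, size, dollo_losses, discordant.
    """
    tips = _tip_names(tree)
    if set(matrix.species) != tips:
        raise ValueError(
            f"presence-matrix species {sorted(matrix.species)} do not match "
            f"tree leaves {sorted(tips)}"
        )
    clades = _clades(tree)
    rows = []
    species = matrix.species
    for cid, row, size in zip(matrix.class_ids, matrix.presence, matrix.sizes):
        pattern = frozenset(sp for sp, here in zip(species, row) if here)
        losses = dollo_cost(pattern, tree)
        discordant = len(pattern) >= 2 and pattern not in clades
        rows.append(
            {
                "class_id": cid,
                "pattern": pattern_label(pattern),
                "size": int(size),
                "dollo_losses": losses,
                "discordant": discordant,
            }
        )
    return pd.DataFrame(
        rows, columns=["class_id", "pattern", "size", "dollo_losses", "discordant"]
    )


def _pair_table(matrix: PresenceMatrix, exclusive: bool) -> pd.DataFrame:
    if len(matrix.species) < 2:
        raise ValueError("need at least 2 species")
    counts = {pair: 0 for pair in combinations(sorted(matrix.species), 2)}
    species = matrix.species
    for row in matrix.presence:
        present = sorted(sp for sp, here in zip(species, row) if here)
        if exclusive:
            if len(present) == 2:
                counts[tuple(present)] += 1
        else:
            for pair in combinations(present, 2):
                counts[pair] += 1
    return pd.DataFrame(
        [(a, b, n) for (a, b), n in counts.items()],
        columns=["species_a", "species_b", "count"],
    )


def pairwise_exclusive_shared(matrix: PresenceMatrix) -> pd.DataFrame:
    """Classes present in *exactly* each species pair (zeros included)."""
    return _pair_table(matrix, exclusive=True)


def pairwise_shared_any(matrix: PresenceMatrix) -> pd.DataFrame:
    """Classes present in each species pair, regardless of other species."""
    return _pair_table(matrix, exclusive=False)
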