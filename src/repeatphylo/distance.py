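"""Shared-repeat distances between species.

The presence/absence of each repeat class is treated as an independent
binary trait. For species *i* and *j*, with N_i and N_j repeat classes
each, N_shared classes present in both and N_common = N_i + N_j -
N_shared classes present in either (the pooled repeat library of the
pair), the distance is

    d_ij = 1 - N_shared / N_common        ("union" variant, Jaccard)

or, as a configurable alternative,

    d_ij = 1 - 2 N_shared / (N_i + N_j)   ("mean" variant, Sorensen/Dice)

Class abundances are deliberately not taken into account. The union
variant is a true metric (satisfies the triangle inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import PresenceMatrix

__all__ = [
    "PairCounts",
    "DistanceMatrix",
    "pair_counts",
    "repeat_distance",
    "distance_matrix",
]

VARIANTS = ("union", "mean")


@dataclass(frozen=True)
class PairCounts:
    """Presence counts for one species pair."""

    species_i: str
    species_j: str
    N_i: int
    N_j: int
    N_shared: int

    def __post_init__(self) -> None:
        if not 0 <= self.N_shared <= min(self.N_i, self.N_j):
            raise ValueError(
                f"inconsistent counts: N_shared={self.N_shared}, "
                f"N_i={self.N_i}, N_j={self.N_j}"
            )

    @property
    def N_common(self) -> int:
        """Classes in the pooled library of the pair (union)."""
        return self.N_i + self.N_j - self.N_shared


@dataclass
class DistanceMatrix:
    """Symmetric species distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("species").to_csv(
            path, sep="\t", float_format="%.6f"
        )

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def pair_counts(matrix: PresenceMatrix, i: str, j: str) -> PairCounts:
    """Tally N_i, N_j and N_shared from two presence columns."""
    col_i = matrix.column(i)
    col_j = matrix.column(j)
    return PairCounts(
        species_i=i,
        species_j=j,
        N_i=int(col_i.sum()),
        N_j=int(col_j.sum()),
        N_shared=int((col_i & col_j).sum()),
    )


def repeat_distance(counts: PairCounts, variant: str = "union") -> float:
    """Distance between one species pair from its presence counts.

    ``union``: 1 - N_shared/N_common (Jaccard); ``mean``:
    1 - 2 N_shared/(N_i + N_j) (Sorensen). Undefined (error) when the
    two species share an empty pooled library.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if counts.N_common == 0:
        raise ValueError(
            f"distance undefined: {counts.species_i} and {counts.species_j} "
            "have no retained repeat classes"
        )
    if variant == "union":
        return 1.0 - counts.N_shared / counts.N_common
    return 1.0 - 2.0 * counts.N_shared / (counts.N_i + counts.N_j)


def distance_matrix(matrix: PresenceMatrix, variant: str = "union") -> DistanceMatrix:
    """All-pairs shared-repeat distance matrix over the species set."""
    if len(matrix.species) < 3:
        raise ValueError("need at least 3 species for a useful distance matrix")
    empty = [sp for sp in matrix.species if not matrix.column(sp).any()]
    if empty:
        raise ValueError(f"species absent from every retained class: {empty}")
    n = len(matrix.species)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = repeat_distance(
                pair_counts(matrix, matrix.species[a], matrix.species[b]), variant
            )
            values[a, b] = values[b, a] = d
    return DistanceMatrix(labels=list(matrix.species), values=values)
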