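"""Repeat classes and cross-species sharing patterns.

Contigs are nodes of an undirected homology graph whose edges are the
passing similarity hits; each connected component is one *repeat class*
— a set of contigs treated as one homologous repeat family across
species. A class's occurrence in a genome is then a binary trait: the
presence/absence matrix over (classes x species) is the raw material
for the sharing-pattern table and the shared-repeat distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import RepeatContig, RepeatLibrary, split_tagged_id

__all__ = [
    "RepeatClass",
    "PresenceMatrix",
    "build_classes",
    "filter_classes",
    "presence_matrix",
    "tabulate_patterns",
    "rank_abundance",
]


@dataclass
class RepeatClass:
    """A connected component of the repeat-homology graph."""

    class_id: int
    member_ids: frozenset[str]
    species_set: frozenset[str]
    total_abundance_by_species: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class PresenceMatrix:
    """Boolean classes-x-species matrix with per-class sizes."""

    class_ids: list[int]
    species: list[str]
    presence: np.ndarray  # bool, shape (n_classes, n_species)
    sizes: np.ndarray  # int, shape (n_classes,)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.presence.shape != (len(self.class_ids), len(self.species)):
            raise ValueError("presence shape does not match labels")
        if self.presence.size and not self.presence.any(axis=1).all():
            raise ValueError("every class must be present in at least one species")

    def column(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.presence[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int), index=self.class_ids, columns=self.species
        ).rename_axis("class_id")


def build_classes(
    contigs: Sequence[RepeatContig], hits: Iterable
) -> list[RepeatClass]:
    """Cluster contigs into repeat classes by single linkage over hits.

    Every contig is a node; every hit an undirected edge. Connected
    components become classes; contigs with no passing hit form
    singleton classes. The partition is invariant to hit and contig
    order: classes are numbered by their lexicographically smallest
    member id.
    """
    by_id = {c.contig_id: c for c in contigs}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for h in hits:
        for cid in (h.query_id, h.subject_id):
            if cid not in by_id:
                raise ValueError(f"hit references unknown contig id {cid!r}")
        graph.add_edge(h.query_id, h.subject_id)

    components = sorted(nx.connected_components(graph), key=min)
    classes: list[RepeatClass] = []
    for k, comp in enumerate(components):
        members = frozenset(comp)
        abundance: dict[str, float] = {}
        for cid in members:
            c = by_id[cid]
            abundance[c.species] = abundance.get(c.species, 0.0) + c.abundance
        classes.append(
            RepeatClass(
                class_id=k,
                member_ids=members,
                species_set=frozenset(abundance),
                total_abundance_by_species=abundance,
            )
        )
    return classes


def filter_classes(
    classes: Sequence[RepeatClass],
    min_size: int = 5,
    min_abundance: float = 1e-4,
) -> list[RepeatClass]:
    """Apply the size and abundance retention filters.

    A class is retained when it has at least ``min_size`` member contigs
    (counted across all species pooled) and its summed abundance reaches
    ``min_abundance`` — 0.01 % of a species' reads by default — in at
    least one species. The abundance test is skipped when no contig in
    the input carries abundance information.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    have_abundance = any(
        a > 0 for cls in classes for a in cls.total_abundance_by_species.values()
    )
    out = []
    for cls in classes:
        if cls.size < min_size:
            continue
        if have_abundance:
            peak = max(cls.total_abundance_by_species.values(), default=0.0)
            if peak < min_abundance:
                continue
        out.append(cls)
    return out


def presence_matrix(
    classes: Sequence[RepeatClass], species_order: Sequence[str]
) -> PresenceMatrix:
    """Binary classes-x-species matrix in the given species order."""
    order = list(species_order)
    known = set(order)
    for cls in classes:
        missing = cls.species_set - known
        if missing:
            raise ValueError(
                f"class {cls.class_id} has species {sorted(missing)} "
                f"absent from species_order"
            )
    presence = np.zeros((len(classes), len(order)), dtype=bool)
    for i, cls in enumerate(classes):
        for sp in cls.species_set:
            presence[i, order.index(sp)] = True
    return PresenceMatrix(
        class_ids=[cls.class_id for cls in classes],
        species=order,
        presence=presence,
        sizes=np.array([cls.size for cls in classes], dtype=int),
    )


def pattern_label(species: Iterable[str]) -> str:
    return "+".join(sorted(species))


def tabulate_patterns(matrix: PresenceMatrix) -> pd.DataFrame:
    """Count repeat classes per observed species subset.

    Returns a table with one row per distinct presence pattern (species
    subset), its class count and its proportion of all retained classes
    — the cross-species sharing spectrum, from species-specific
    singleton patterns up to the full-set pattern. Rows are sorted by
    descending count, then label.
    """
    counts: Counter[str] = Counter()
    for row in matrix.presence:
        counts[pattern_label(np.array(matrix.species)[row])] += 1
    total = sum(counts.values())
    table = pd.DataFrame(
        [(label, n, n / total) for label, n in counts.items()],
        columns=["pattern", "count", "proportion"],
    )
    return table.sort_values(
        ["count", "pattern"], ascending=[False, True], ignore_index=True
    )


def rank_abundance(
    source: RepeatLibrary | dict[str, float]
) -> list[tuple[str, float]]:
    """Labels with abundances, sorted descending; ties broken by label."""
    if isinstance(source, RepeatLibrary):
        items = [(c.contig_id, c.abundance) for c in source]
    else:
        items = list(source.items())
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))
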