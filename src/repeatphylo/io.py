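"""Reading, writing and species tagging of repeat-contig libraries.

Repeat contigs are consensus sequences of repeat families recovered
per species (one FASTA file per species). Before cross-species
comparison every contig id is prefixed with its species tag so that a
pooled library keeps ids unique and each id remains decomposable into
``(species, original_id)``.

Abundance is the fraction of a species' reads assigned to a contig. It
is optional metadata used only for filtering and rank-abundance plots;
the shared-repeat distances deliberately ignore it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RepeatContig",
    "RepeatLibrary",
    "SEPARATOR",
    "load_library",
    "load_abundance_table",
    "pool_with_prefixes",
    "split_tagged_id",
    "read_hits_table",
    "write_hits_table",
    "write_pattern_table",
    "read_pattern_table",
    "write_library_fasta",
]

#: Default separator between the species tag and the original contig id.
#: Double underscore: single underscores are common inside contig ids,
#: so splitting on the *first* "__" is unambiguous.
SEPARATOR = "__"

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class RepeatContig:
    """One repeat consensus sequence.

    Parameters
    ----------
    contig_id : str
        Identifier, unique within its library (and, once tagged, within
        the pooled collection).
    species : str
        Species tag.
    sequence : str
        Nucleotide sequence over ``{A, C, G, T, N}``, stored uppercase.
    abundance : float
        Fraction of the species' reads assigned to this repeat, in
        ``[0, 1]``; 0 when unknown.
    """

    contig_id: str
    species: str
    sequence: str
    abundance: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"contig {self.contig_id!r}: illegal character "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(
                f"contig {self.contig_id!r}: abundance {self.abundance} outside [0, 1]"
            )


@dataclass
class RepeatLibrary:
    """An ordered collection of contigs from one species."""

    species: str
    contigs: list[RepeatContig] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(
                f"library {self.species!r}: duplicate contig ids {sorted(dupes)}"
            )
        for c in self.contigs:
            if c.species != self.species:
                raise ValueError(
                    f"library {self.species!r}: contig {c.contig_id!r} "
                    f"tagged {c.species!r}"
                )

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)


def load_abundance_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (id, abundance) TSV into a mapping."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = float(row[1])
    return out


def load_library(
    path: str | Path,
    species_tag: str,
    abundance_source: Mapping[str, float] | str | Path | None = None,
) -> RepeatLibrary:
    """Load one species' repeat contigs from FASTA.

    Parameters
    ----------
    path : path
        FASTA file of repeat consensus contigs.
    species_tag : str
        Non-empty tag; must not contain the separator ``"__"``.
    abundance_source : mapping or path, optional
        Per-id read fractions, joined by record id. Ids absent from the
        table get abundance 0.

    Returns
    -------
    RepeatLibrary
        One :class:`RepeatContig` per record, sequences uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    if not species_tag:
        raise ValueError("species_tag must be non-empty")
    if SEPARATOR in species_tag:
        raise ValueError(
            f"species_tag {species_tag!r} contains the separator {SEPARATOR!r}"
        )
    if isinstance(abundance_source, (str, Path)):
        abundance_source = load_abundance_table(abundance_source)
    abundance_source = abundance_source or {}

    contigs: list[RepeatContig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate record id {record.id!r}")
        seen.add(record.id)
        contigs.append(
            RepeatContig(
                contig_id=record.id,
                species=species_tag,
                sequence=str(record.seq).upper(),
                abundance=float(abundance_source.get(record.id, 0.0)),
            )
        )
    if not contigs:
        raise ValueError(f"{path}: empty FASTA file")
    return RepeatLibrary(species=species_tag, contigs=contigs)


def pool_with_prefixes(
    libraries: Sequence[RepeatLibrary], separator: str = SEPARATOR
) -> list[RepeatContig]:
    """Concatenate libraries, prefixing every contig id with its species tag.

    Order is preserved: libraries in the given order, contigs in
    within-library order. The mapping ``(species, contig_id) -> tagged id``
    is injective, and ``split_tagged_id`` inverts it.
    """
    tags = [lib.species for lib in libraries]
    if len(set(tags)) != len(tags):
        dupes = sorted({t for t in tags if tags.count(t) > 1})
        raise ValueError(f"duplicate species tags: {dupes}")
    for t in tags:
        if separator in t:
            raise ValueError(f"species tag {t!r} contains separator {separator!r}")
    pooled = [
        RepeatContig(
            contig_id=f"{c.species}{separator}{c.contig_id}",
            species=c.species,
            sequence=c.sequence,
            abundance=c.abundance,
        )
        for lib in libraries
        for c in lib
    ]
    return pooled


def split_tagged_id(tagged_id: str, separator: str = SEPARATOR) -> tuple[str, str]:
    """Recover ``(species, original_id)`` from a pooled contig id."""
    species, sep, rest = tagged_id.partition(separator)
    if not sep or not species or not rest:
        raise ValueError(f"id {tagged_id!r} is not of the form species{separator}id")
    return species, rest


# --- 12-column tabular hits (BLAST outfmt-6 convention) -----------------

_HITS_COLUMNS = [
    "query_id",
    "subject_id",
    "identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bit_score",
]


def read_hits_table(path: str | Path) -> list:
    """Read an all-vs-all hits file in the 12-column tabular convention.

    Columns: query id, subject id, percent identity, alignment length,
    mismatches, gap opens, query start/end, subject start/end
    (1-based inclusive; subject start > end marks a minus-strand hit),
    e-value, bit score. Percent identity is converted to a fraction.
    """
    from .search import SimilarityHit  # local import to avoid a cycle

    hits = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(row)}"
                )
            try:
                pid = float(row[2])
                aln_length = int(row[3])
                qs, qe, ss, se = (int(x) for x in row[6:10])
                score = float(row[11])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
            if not 0.0 <= pid <= 100.0:
                raise ValueError(
                    f"{path}: line {lineno}: percent identity {pid} outside [0, 100]"
                )
            hits.append(
                SimilarityHit(
                    query_id=row[0],
                    subject_id=row[1],
                    identity=pid / 100.0,
                    aln_length=aln_length,
                    query_span=(qs, qe),
                    subject_span=(ss, se),
                    score=score,
                )
            )
    return hits


def write_hits_table(hits: Iterable, path: str | Path) -> None:
    """Write hits in the 12-column tabular convention (see read_hits_table).

    Mismatches and gap-open counts are not tracked by the internal
    aligner and are written as 0; the e-value column is written as
    ``-1`` (not computed).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity * 100.0:.4f}",
                    h.aln_length,
                    0,
                    0,
                    h.query_span[0],
                    h.query_span[1],
                    h.subject_span[0],
                    h.subject_span[1],
                    -1,
                    f"{h.score:g}",
                ]
            )


def write_pattern_table(patterns: pd.DataFrame, path: str | Path) -> None:
    """Write a sharing-pattern table as TSV.

    One row per observed species subset: subset label (tags joined by
    ``+``), class count, proportion of all retained classes.
    """
    patterns.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pattern_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_pattern_table`."""
    return pd.read_csv(
        path, sep="\t", dtype={"pattern": str, "count": int, "proportion": float}
    )


def write_library_fasta(library: RepeatLibrary, path: str | Path) -> None:
    """Write one species' contigs as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for c in library:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")
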