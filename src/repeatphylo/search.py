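"""All-vs-all local similarity search over pooled repeat contigs.

Homology between repeat contigs is established by pairwise local
alignment: a pair is linked when its best local alignment reaches a
minimum identity (default 80 %, gaps counted as alignment columns) over
a minimum fraction of the shorter sequence (default 50 %). An exact
shared k-mer on either strand gates which pairs are aligned at all, so
the search stays near-linear in the number of unrelated contigs.

The alignment engine is Biopython's C implementation of the Gotoh
affine-gap local aligner; candidate pairing, strand handling and the
identity/coverage accounting live here. ``N`` bases never count as
matches and score as mismatches against everything, including ``N``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["SimilarityHit", "SearchParams", "align_pair", "all_vs_all"]

_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment match between two contigs.

    ``identity`` is matched columns / total alignment columns (gap
    columns included, ``N`` never matches). Spans are 1-based inclusive;
    a subject span with start > end marks a minus-strand match.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit on {self.query_id!r}")


@dataclass(frozen=True)
class SearchParams:
    """Thresholds and scores of the similarity search.

    min_identity : fraction of alignment columns that must match
        (inclusive; default 0.80, the similarity threshold used for
        repeat-class definition).
    min_coverage : fraction of the shorter sequence the alignment must
        span (inclusive; default 0.50). Without a span requirement,
        short spurious matches would merge unrelated classes.
    seed_k : exact k-mer length used to pair candidates (default 13).
    match/mismatch/gap scores : +1/-1, gap open -2, gap extend -1.
    """

    min_identity: float = 0.80
    min_coverage: float = 0.50
    seed_k: int = 13
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = (
                params.match_score if (a == b and a != "N") else params.mismatch_score
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _evaluate(alignment, a: str, b: str) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """Matched columns, total columns, and 1-based spans of a local alignment."""
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        for x, y in zip(a[a0:a1], b[b0:b1]):
            columns += 1
            if x == y and x != "N":
                matches += 1
        prev_a_end, prev_b_end = a1, b1
    a_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return matches, columns, a_span, b_span


def align_pair(
    a: str,
    b: str,
    params: SearchParams | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    both_strands: bool = True,
    _aligner: Align.PairwiseAligner | None = None,
) -> SimilarityHit | None:
    """Best passing local alignment between two sequences, or ``None``.

    The highest-scoring local alignment (optionally on either strand of
    ``b``) is kept if it passes ``min_identity`` and ``min_coverage``,
    both inclusive. For a minus-strand match the subject span is
    reported on the original ``b`` coordinates with start > end.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or SearchParams()
    aligner = _aligner if _aligner is not None else _make_aligner(params)

    best: SimilarityHit | None = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        b_oriented = b if strand == "+" else reverse_complement(b)
        alignments = aligner.align(a, b_oriented)
        try:
            alignment = alignments[0]
        except IndexError:
            continue
        if alignment.score <= 0:
            continue
        matches, columns, a_span, b_span = _evaluate(alignment, a, b_oriented)
        if columns == 0:
            continue
        identity = matches / columns
        cov_a = (a_span[1] - a_span[0] + 1) / len(a)
        cov_b = (b_span[1] - b_span[0] + 1) / len(b)
        coverage = cov_a if len(a) <= len(b) else cov_b
        if identity < params.min_identity or coverage < params.min_coverage:
            continue
        if strand == "-":
            # map back to plus-strand coordinates of b, inverted
            b_span = (len(b) - b_span[0] + 1, len(b) - b_span[1] + 1)
        hit = SimilarityHit(
            query_id=query_id,
            subject_id=subject_id,
            identity=identity,
            aln_length=columns,
            query_span=a_span,
            subject_span=b_span,
            score=float(alignment.score),
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def _kmer_index(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(contigs: Sequence, params: SearchParams | None = None) -> list[SimilarityHit]:
    """Seeded all-vs-all search over a pooled contig collection.

    Every unordered pair sharing at least one exact ``seed_k``-mer (on
    either strand) is aligned with :func:`align_pair`; passing hits are
    emitted once per pair, with ids in lexicographic (query, subject)
    order. Intra-species pairs are included — the repeat-class graph
    does not care which species an edge connects.
    """
    params = params or SearchParams()
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids in pooled collection: {dupes}")

    seqs = {c.contig_id: c.sequence for c in contigs}
    k = params.seed_k
    index: dict[str, set[str]] = defaultdict(set)
    for cid, seq in seqs.items():
        for kmer in _kmer_index(seq, k):
            index[kmer].add(cid)
        for kmer in _kmer_index(reverse_complement(seq), k):
            index[kmer].add(cid)

    candidates: set[tuple[str, str]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        ordered = sorted(members)
        for i, qid in enumerate(ordered):
            for sid in ordered[i + 1 :]:
                candidates.add((qid, sid))

    aligner = _make_aligner(params)
    hits: list[SimilarityHit] = []
    for qid, sid in sorted(candidates):
        hit = align_pair(
            seqs[qid],
            seqs[sid],
            params,
            query_id=qid,
            subject_id=sid,
            _aligner=aligner,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def all_pairs_exhaustive(
    contigs: Sequence, params: SearchParams | None = None
) -> list[SimilarityHit]:
    """All-vs-all search without the k-mer gate (every pair aligned).

    Quadratic in the collection size; used to audit the seeded search's
    completeness on small collections.
    """
    params = params or SearchParams()
    aligner = _make_aligner(params)
    seqs = {c.contig_id: c.sequence for c in contigs}
    ordered = sorted(seqs)
    hits: list[SimilarityHit] = []
    for i, qid in enumerate(ordered):
        for sid in ordered[i + 1 :]:
            hit = align_pair(
                seqs[qid], seqs[sid], params, query_id=qid, subject_id=sid,
                _aligner=aligner,
            )
            if hit is not None:
                hits.append(hit)
    return hits
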