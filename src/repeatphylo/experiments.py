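"""Replicated simulation experiments over the analysis pipeline.

Drivers that run the simulator through the full clustering → presence →
distance → neighbor-joining → concordance chain and aggregate results
over seeded replicates: topology-recovery rates, sharing-pattern
spectra, and horizontal-transfer detection statistics. Used by the
analysis scripts, the test suite and the reproduction script alike.

All experiments run the pipeline with ``min_size=1``: the simulator
emits one consensus contig per family per species (as read-clustering
does per repeat class), so the ≥5-member class filter that applies to
raw contig collections would be meaningless here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .concordance import flag_discordant, rf_distance
from .distance import distance_matrix
from .io import pool_with_prefixes
from .patterns import (
    PresenceMatrix,
    RepeatClass,
    build_classes,
    filter_classes,
    pattern_label,
    presence_matrix,
)
from .search import SearchParams, all_vs_all
from .simulate import SimParams, SimTruth, regime_presets, simulate_repeatome
from .tree import neighbor_joining, read_newick

__all__ = [
    "QuartetRun",
    "run_sim_pipeline",
    "REFERENCE_QUARTET",
    "regime_replicates",
    "RegimeSummary",
    "summarize_regime",
    "ht_detection",
    "shallow_quartet_params",
    "AUDIT_SEARCH_PARAMS",
    "seeded_search_audit",
]

#: The generating quartet topology of both regime presets, rooted.
REFERENCE_QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


@dataclass
class QuartetRun:
    """One simulated dataset pushed through the pipeline."""

    truth: SimTruth
    classes: list[RepeatClass]
    matrix: PresenceMatrix
    recovered: dict[str, bool]  # metric variant -> NJ split equals truth split
    report: object  # concordance DataFrame against the generating tree


def run_sim_pipeline(
    params: SimParams,
    search: SearchParams | None = None,
    min_size: int = 1,
    reference: str | None = None,
) -> QuartetRun:
    """Simulate one repeatome and run the full analysis chain on it.

    The NJ tree is inferred under both distance variants and compared
    (Robinson–Foulds) with the generating topology; the concordance
    report is computed against the rooted generating tree.
    """
    libraries, truth = simulate_repeatome(params)
    species = sorted(libraries)
    pooled = pool_with_prefixes([libraries[s] for s in species])
    hits = all_vs_all(pooled, search)
    classes = filter_classes(build_classes(pooled, hits), min_size=min_size)
    matrix = presence_matrix(classes, species)
    ref = read_newick(reference or truth.newick)

    recovered = {}
    for variant in ("union", "mean"):
        tree = neighbor_joining(distance_matrix(matrix, variant))
        recovered[variant] = rf_distance(tree, ref) == 0
    report = flag_discordant(matrix, ref)
    return QuartetRun(
        truth=truth, classes=classes, matrix=matrix, recovered=recovered,
        report=report,
    )


def regime_replicates(
    preset: str, n_replicates: int, base_seed: int = 0, ht_rate: float = 0.0
) -> list[QuartetRun]:
    """Seeded replicate runs of one regime preset through the pipeline."""
    return [
        run_sim_pipeline(regime_presets(preset, seed=base_seed + k, ht_rate=ht_rate))
        for k in range(n_replicates)
    ]


@dataclass
class RegimeSummary:
    """Aggregates over a set of replicate runs."""

    n_replicates: int
    recovery: dict[str, int]  # variant -> replicates with the true split
    pattern_counts: Counter = field(default_factory=Counter)
    n_classes: int = 0
    n_discordant: int = 0

    @property
    def modal_pattern(self) -> str:
        return self.pattern_counts.most_common(1)[0][0]

    @property
    def discordant_fraction(self) -> float:
        return self.n_discordant / self.n_classes if self.n_classes else 0.0

    def recovery_rate(self, variant: str) -> float:
        return self.recovery[variant] / self.n_replicates


def summarize_regime(runs: list[QuartetRun]) -> RegimeSummary:
    summary = RegimeSummary(
        n_replicates=len(runs), recovery={"union": 0, "mean": 0}
    )
    for run in runs:
        for variant, ok in run.recovered.items():
            summary.recovery[variant] += int(ok)
        species = np.array(run.matrix.species)
        for row in run.matrix.presence:
            summary.pattern_counts[pattern_label(species[row])] += 1
        summary.n_classes += len(run.report)
        summary.n_discordant += int(run.report["discordant"].sum())
    return summary


def ht_detection(runs: list[QuartetRun], reference: str = REFERENCE_QUARTET):
    """Sensitivity of discordance flagging for cross-split transfers.

    Over truth families with at least one horizontal transfer across
    the root split *whose true tip pattern is itself discordant* (a
    non-clade of the reference tree — families whose transferred copy
    died out again carry no signal), counts how many end up in a
    pipeline class flagged discordant. Returns (flagged, eligible).
    """
    ref = read_newick(reference)
    clades: set[frozenset[str]] = set()
    for node in ref.postorder(include_self=True):
        if node.is_tip():
            clades.add(frozenset([node.name]))
        else:
            clades.add(frozenset(t.name for t in node.tips()))

    flagged_n = 0
    eligible = 0
    for run in runs:
        contig_class = {
            cid: cls.class_id for cls in run.classes for cid in cls.member_ids
        }
        flagged = set(run.report.loc[run.report["discordant"], "class_id"])
        by_family: dict[int, set[int]] = {}
        for (sp, cid), fid in run.truth.contig_to_family.items():
            cls = contig_class.get(f"{sp}__{cid}")
            if cls is not None:
                by_family.setdefault(fid, set()).add(cls)
        for fam in run.truth.cross_split_transfer_families():
            pattern = frozenset(fam.tip_presence)
            if len(pattern) < 2 or pattern in clades:
                continue
            eligible += 1
            if by_family.get(fam.family_id, set()) & flagged:
                flagged_n += 1
    return flagged_n, eligible


# --- seeding-completeness audit -----------------------------------------


def shallow_quartet_params(seed: int) -> SimParams:
    """A shallow quartet whose family divergence guarantees seed hits.

    With substitution rate 0.008/site and tree depth 0.5, any two tip
    copies of a family differ by ~1 % of sites, so every homologous
    pair necessarily contains a long exact match: by pigeonhole, an
    alignment of L columns with m error columns has an exact run of at
    least (L - m)/(m + 1) matches, far above the 9-mer seed used by
    :data:`AUDIT_SEARCH_PARAMS`. Under these conditions the seeded
    search is provably as complete as exhaustive all-pairs alignment.
    """
    return SimParams(
        tree="((A:0.25,B:0.25):0.25,(C:0.25,D:0.25):0.25):0.5;",
        gain_rate=6.0,
        loss_rate=0.02,
        subst_rate=0.008,
        indel_rate=0.0003,
        ht_rate=0.0,
        seq_length_range=(150, 300),
        copy_number_range=(100, 200),
        detection_min_copies=1,
        seed=seed,
    )


AUDIT_SEARCH_PARAMS = SearchParams(seed_k=9)


def seeded_search_audit(seed: int):
    """Run the seeded search and the exhaustive all-pairs search on one
    shallow-quartet dataset; returns (pooled, truth, seeded, exhaustive)."""
    from .search import all_pairs_exhaustive

    libraries, truth = simulate_repeatome(shallow_quartet_params(seed))
    pooled = pool_with_prefixes([libraries[s] for s in sorted(libraries)])
    seeded = all_vs_all(pooled, AUDIT_SEARCH_PARAMS)
    exhaustive = all_pairs_exhaustive(pooled, AUDIT_SEARCH_PARAMS)
    return pooled, truth, seeded, exhaustive
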