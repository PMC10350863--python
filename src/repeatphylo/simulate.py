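"""Forward simulator of repeat-family evolution along a known phylogeny.

Families of repeated DNA originate as Poisson events on the branches of
a rooted time-scaled tree (including a stem branch above the root, so
ancestral families shared by every species can exist). Each family's
consensus sequence then evolves independently down every lineage by
substitutions and indels; per-lineage loss and, optionally, horizontal
transfer into a contemporaneous lineage are Poisson events as well. At
each tip every surviving family is emitted as one consensus contig —
mirroring read-clustering output, which yields one representative per
repeat class per species — provided its drawn genomic copy number
reaches the detection threshold (a repeat must be amplified to roughly
50+ copies per haploid genome before low-coverage clustering can see
it).

The ground truth (event log, true presence at tips, contig-to-family
map) is returned alongside the libraries so the whole downstream
pipeline can be validated without external data.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import TreeNode

from .io import RepeatContig, RepeatLibrary, write_library_fasta
from .tree import read_newick, to_newick

__all__ = [
    "SimParams",
    "SimTruth",
    "FamilyRecord",
    "simulate_repeatome",
    "regime_presets",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Parameters of the repeatome simulator.

    Rates are per unit branch-length time: ``gain_rate`` family
    originations per lineage, ``loss_rate`` per family, ``subst_rate``
    and ``indel_rate`` per site, ``ht_rate`` horizontal transfers per
    family (0 disables). ``tree`` is a rooted Newick string or TreeNode
    whose root branch length, if any, is the stem on which ancestral
    families can arise.
    """

    tree: str | TreeNode
    gain_rate: float = 10.0
    loss_rate: float = 0.06
    subst_rate: float = 0.004
    indel_rate: float = 0.0004
    indel_mean_len: float = 3.0
    ht_rate: float = 0.0
    seq_length_range: tuple[int, int] = (150, 2000)
    copy_number_range: tuple[int, int] = (25, 2500)
    detection_min_copies: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gain_rate", "loss_rate", "subst_rate", "indel_rate", "ht_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.seq_length_range
        if not (0 < lo <= hi):
            raise ValueError("seq_length_range must be a non-empty positive interval")
        lo, hi = self.copy_number_range
        if not (0 < lo <= hi):
            raise ValueError("copy_number_range must be a non-empty positive interval")
        if self.detection_min_copies < 1:
            raise ValueError("detection_min_copies must be >= 1")


@dataclass
class FamilyRecord:
    """Ground-truth event log of one repeat family."""

    family_id: int
    origin_branch: str
    origin_time: float
    founder_length: int
    losses: list[tuple[str, float]] = field(default_factory=list)
    transfers: list[tuple[str, str, float]] = field(default_factory=list)  # donor, recipient, time
    tip_presence: set[str] = field(default_factory=set)
    emitted_presence: set[str] = field(default_factory=set)


@dataclass
class SimTruth:
    """Ground truth of one simulated repeatome."""

    newick: str
    families: list[FamilyRecord]
    contig_to_family: dict[tuple[str, str], int]  # (species, contig_id) -> family
    root_sides: dict[str, str]  # branch name -> root-child subtree label ("" = stem/root)

    def true_presence_matrix(self) -> dict[int, frozenset[str]]:
        return {f.family_id: frozenset(f.tip_presence) for f in self.families}

    def cross_split_transfer_families(self) -> list[FamilyRecord]:
        """Families with >=1 transfer between the two sides of the root split."""
        out = []
        for fam in self.families:
            for donor, recipient, _t in fam.transfers:
                a = self.root_sides.get(donor, "")
                b = self.root_sides.get(recipient, "")
                if a and b and a != b:
                    out.append(fam)
                    break
        return out

    def to_json(self) -> str:
        payload = {
            "newick": self.newick,
            "families": [
                {
                    "family_id": f.family_id,
                    "origin_branch": f.origin_branch,
                    "origin_time": f.origin_time,
                    "founder_length": f.founder_length,
                    "losses": [[b, t] for b, t in f.losses],
                    "transfers": [[d, r, t] for d, r, t in f.transfers],
                    "tip_presence": sorted(f.tip_presence),
                    "emitted_presence": sorted(f.emitted_presence),
                }
                for f in self.families
            ],
            "contig_to_family": {
                f"{sp}\t{cid}": fam for (sp, cid), fam in self.contig_to_family.items()
            },
            "root_sides": self.root_sides,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------


class _Branch:
    __slots__ = ("name", "t_start", "t_end", "children", "is_tip", "side")

    def __init__(self, name, t_start, t_end, children, is_tip, side):
        self.name = name
        self.t_start = t_start
        self.t_end = t_end
        self.children = children
        self.is_tip = is_tip
        self.side = side


def _prepare_branches(tree: TreeNode) -> tuple[dict[str, _Branch], str]:
    """Time-annotated branches keyed by child-node name; returns (branches, root name)."""
    tree = tree.copy()
    counter = 0
    for node in tree.traverse(include_self=True):
        if not node.is_tip() and not node.name:
            node.name = f"_n{counter}"
            counter += 1
        if node.parent is not None and node.length is None:
            raise ValueError(f"branch above {node.name!r} has no length")
    names = [n.name for n in tree.traverse(include_self=True)]
    if len(set(names)) != len(names):
        raise ValueError("tree node names must be unique")

    stem = tree.length if tree.length is not None else 0.0
    branches: dict[str, _Branch] = {}
    # root-split side labels: name of the root child whose subtree a branch is in
    sides: dict[str, str] = {tree.name: ""}
    for child in tree.children:
        for node in child.traverse(include_self=True):
            sides[node.name] = child.name

    def visit(node: TreeNode, t_start: float) -> None:
        length = stem if node.parent is None else node.length
        t_end = t_start + length
        branches[node.name] = _Branch(
            name=node.name,
            t_start=t_start,
            t_end=t_end,
            children=[c.name for c in node.children],
            is_tip=node.is_tip(),
            side=sides[node.name],
        )
        for c in node.children:
            visit(c, t_end)

    visit(tree, 0.0)
    return branches, tree.name


def _evolve(seq: list[str], dt: float, params: SimParams, rng: np.random.Generator) -> None:
    """Mutate a sequence in place over an elapsed time dt."""
    if dt <= 0:
        return
    L = len(seq)
    n_sub = rng.poisson(params.subst_rate * L * dt)
    if n_sub:
        for pos in rng.integers(0, L, size=n_sub):
            cur = seq[pos]
            choices = [b for b in "ACGT" if b != cur]
            seq[pos] = choices[rng.integers(0, 3)]
    n_indel = rng.poisson(params.indel_rate * L * dt)
    for _ in range(n_indel):
        length = int(rng.geometric(1.0 / params.indel_mean_len))
        if rng.random() < 0.5 and len(seq) > length:  # deletion, keep seq non-empty
            pos = int(rng.integers(0, len(seq) - length + 1))
            del seq[pos : pos + length]
        else:  # insertion
            pos = int(rng.integers(0, len(seq) + 1))
            seq[pos:pos] = list(_BASES[rng.integers(0, 4, size=length)])


def _exp_or_inf(rate: float, rng: np.random.Generator) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def _simulate_family(
    fam: FamilyRecord,
    founder: list[str],
    branches: Mapping[str, _Branch],
    params: SimParams,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Event-driven descent of one family; returns tip name -> sequence."""
    copies: dict[str, dict] = {}
    versions: dict[str, int] = {}
    heap: list[tuple[float, int, str, int, str]] = []
    counter = 0
    tip_seqs: dict[str, list[str]] = {}

    def schedule(branch_name: str) -> None:
        nonlocal counter
        copy = copies[branch_name]
        b = branches[branch_name]
        events = [
            (copy["loss_t"], "loss"),
            (copy["next_ht"], "transfer"),
            (b.t_end, "node"),
        ]
        t, kind = min(events, key=lambda e: e[0])
        counter += 1
        heapq.heappush(heap, (t, counter, branch_name, versions[branch_name], kind))

    def birth(branch_name: str, t: float, seq: list[str]) -> None:
        # a transfer into an occupied lineage overwrites the resident copy
        versions[branch_name] = versions.get(branch_name, 0) + 1
        copies[branch_name] = {
            "seq": seq,
            "t": t,
            "loss_t": t + _exp_or_inf(params.loss_rate, rng),
            "next_ht": t + _exp_or_inf(params.ht_rate, rng),
        }
        schedule(branch_name)

    birth(fam.origin_branch, fam.origin_time, founder)

    while heap:
        t, _c, bname, version, kind = heapq.heappop(heap)
        if versions.get(bname) != version or bname not in copies:
            continue  # stale: copy was overwritten or removed
        copy = copies[bname]
        _evolve(copy["seq"], t - copy["t"], params, rng)
        copy["t"] = t
        if kind == "loss":
            fam.losses.append((bname, t))
            del copies[bname]
        elif kind == "node":
            b = branches[bname]
            del copies[bname]
            if b.is_tip:
                fam.tip_presence.add(bname)
                tip_seqs[bname] = copy["seq"]
            else:
                for child in b.children:
                    birth(child, t, list(copy["seq"]))
        else:  # transfer
            recipients = [
                name
                for name, b in branches.items()
                if name != bname and b.t_start < t < b.t_end
            ]
            if recipients:
                recipient = sorted(recipients)[rng.integers(0, len(recipients))]
                fam.transfers.append((bname, recipient, t))
                birth(recipient, t, list(copy["seq"]))
            copy["next_ht"] = t + _exp_or_inf(params.ht_rate, rng)
            schedule(bname)
    return tip_seqs


def simulate_repeatome(
    params: SimParams,
) -> tuple[dict[str, RepeatLibrary], SimTruth]:
    """Simulate per-tip repeat libraries and their ground truth.

    Fully reproducible from ``params.seed``. Libraries are keyed by tip
    name; contig ids are ``c0000``-style, sequential per species, and
    the truth object maps ``(species, contig_id)`` back to families.
    """
    tree = params.tree if isinstance(params.tree, TreeNode) else read_newick(params.tree)
    branches, root_name = _prepare_branches(tree)
    rng = np.random.default_rng(params.seed)

    # family origination: Poisson on every branch, in deterministic order
    gains: list[tuple[str, float]] = []
    for bname in sorted(branches):
        b = branches[bname]
        length = b.t_end - b.t_start
        if length <= 0:
            continue
        n = rng.poisson(params.gain_rate * length)
        times = np.sort(rng.uniform(b.t_start, b.t_end, size=n))
        gains.extend((bname, float(t)) for t in times)
    gains.sort(key=lambda g: (g[1], g[0]))

    families: list[FamilyRecord] = []
    tip_sequences: dict[int, dict[str, list[str]]] = {}
    lo, hi = params.seq_length_range
    for fid, (bname, t0) in enumerate(gains):
        founder_len = int(rng.integers(lo, hi + 1))
        founder = list(_BASES[rng.integers(0, 4, size=founder_len)])
        fam = FamilyRecord(
            family_id=fid,
            origin_branch=bname,
            origin_time=t0,
            founder_length=founder_len,
        )
        tip_sequences[fid] = _simulate_family(fam, founder, branches, params, rng)
        families.append(fam)

    # emission at the tips: copy-number draw and detection threshold
    tips = sorted(name for name, b in branches.items() if b.is_tip)
    cn_lo, cn_hi = params.copy_number_range
    libraries: dict[str, RepeatLibrary] = {}
    contig_to_family: dict[tuple[str, str], int] = {}
    for tip in tips:
        emitted: list[tuple[int, str, int]] = []  # (family, seq, copy number)
        for fam in families:
            if tip not in fam.tip_presence:
                continue
            cn = int(rng.integers(cn_lo, cn_hi + 1))
            if cn < params.detection_min_copies:
                continue
            emitted.append((fam.family_id, "".join(tip_sequences[fam.family_id][tip]), cn))
            fam.emitted_presence.add(tip)
        total_weight = sum(cn * len(seq) for _f, seq, cn in emitted)
        contigs = []
        for k, (fid, seq, cn) in enumerate(emitted):
            cid = f"c{k:04d}"
            contigs.append(
                RepeatContig(
                    contig_id=cid,
                    species=tip,
                    sequence=seq,
                    abundance=cn * len(seq) / total_weight if total_weight else 0.0,
                )
            )
            contig_to_family[(tip, cid)] = fid
        libraries[tip] = RepeatLibrary(species=tip, contigs=contigs)

    truth = SimTruth(
        newick=to_newick(tree),
        families=families,
        contig_to_family=contig_to_family,
        root_sides={name: b.side for name, b in branches.items()},
    )
    _verify_truth(truth, branches)
    return libraries, truth


def _verify_truth(truth: SimTruth, branches: Mapping[str, _Branch]) -> None:
    """Replay the event log and check it reproduces the recorded tip presence."""
    recon = reconstruct_presence(truth, branches)
    for fam in truth.families:
        if recon[fam.family_id] != fam.tip_presence:
            raise AssertionError(
                f"family {fam.family_id}: event log reconstructs {recon[fam.family_id]}, "
                f"simulator recorded {fam.tip_presence}"
            )


def reconstruct_presence(
    truth: SimTruth, branches: Mapping[str, _Branch] | None = None
) -> dict[int, set[str]]:
    """Tip presence of every family, rebuilt from the event log alone.

    Sweeps each branch's acquisition (gain, inheritance, transfer-in)
    and loss events in time order; presence at a tip means the last
    acquisition on the root-to-tip path has no later loss before the
    tip. Independent of the sequence-level simulation details.
    """
    if branches is None:
        branches, _root = _prepare_branches(read_newick(truth.newick))
    out: dict[int, set[str]] = {}
    for fam in truth.families:
        acquisitions: dict[str, list[float]] = {fam.origin_branch: [fam.origin_time]}
        for _donor, recipient, t in fam.transfers:
            acquisitions.setdefault(recipient, []).append(t)
        losses: dict[str, list[float]] = {}
        for bname, t in fam.losses:
            losses.setdefault(bname, []).append(t)

        present_tips: set[str] = set()
        root = next(b for b in branches.values() if b.t_start == 0.0)

        def sweep(bname: str, inherited: bool) -> None:
            b = branches[bname]
            events = [(t, "acq") for t in acquisitions.get(bname, [])]
            events += [(t, "loss") for t in losses.get(bname, [])]
            events.sort()
            state = inherited
            for _t, kind in events:
                state = kind == "acq"
            if state:
                if b.is_tip:
                    present_tips.add(bname)
                for child in b.children:
                    sweep(child, True)
            else:
                for child in b.children:
                    if any(
                        acquisitions.get(d, [])
                        for d in _descendants(child, branches)
                    ):
                        sweep(child, False)

        sweep(root.name, False)
        out[fam.family_id] = present_tips
    return out


def _descendants(bname: str, branches: Mapping[str, _Branch]) -> list[str]:
    out = [bname]
    for child in branches[bname].children:
        out.extend(_descendants(child, branches))
    return out


# ---------------------------------------------------------------------------


_YOUNG_TREE = "((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5):1.0;"
_ANCIENT_TREE = "((A:10,B:10):10,(C:10,D:10):10):20.0;"


def regime_presets(name: str, seed: int = 0, ht_rate: float = 0.0) -> SimParams:
    """Study-condition presets for the two species-flock regimes.

    ``young_flock``: quartet ((A,B),(C,D)) with MRCA depth 1 time unit
    (a ~3 My flock analogue) and a stem of equal depth — most families
    predate the radiation and survive everywhere, so the all-four
    pattern dominates. ``ancient_flock``: the same topology and
    per-time rates with every branch 20x longer (~60 My analogue) —
    ancestral families are mostly lost and recent, species-specific
    families dominate. Both share gain 10, loss 0.06, substitution
    0.004 and indel 0.0004 per unit time, contig-like founder lengths
    of 120-250 bp and a 50-copy detection threshold.
    """
    common = dict(
        gain_rate=10.0,
        loss_rate=0.06,
        subst_rate=0.004,
        indel_rate=0.0004,
        ht_rate=ht_rate,
        seq_length_range=(120, 250),
        copy_number_range=(25, 2500),
        detection_min_copies=50,
        seed=seed,
    )
    if name == "young_flock":
        return SimParams(tree=_YOUNG_TREE, **common)
    if name == "ancient_flock":
        return SimParams(tree=_ANCIENT_TREE, **common)
    raise ValueError(f"unknown preset {name!r}; expected young_flock or ancient_flock")


def write_simulation(
    libraries: Mapping[str, RepeatLibrary], truth: SimTruth, outdir: str | Path
) -> list[Path]:
    """Write per-species FASTA, abundance TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for species in sorted(libraries):
        lib = libraries[species]
        fasta = outdir / f"{species}.fasta"
        write_library_fasta(lib, fasta)
        written.append(fasta)
        abund = outdir / f"{species}.abundance.tsv"
        with open(abund, "w") as fh:
            for c in lib:
                fh.write(f"{c.contig_id}\t{c.abundance:.8g}\n")
        written.append(abund)
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    written.append(truth_path)
    return written
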