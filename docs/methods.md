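# Methods

## The analysis model

The pipeline treats a genome's repeatome as a set of repeat classes
and each class's presence in a species as one binary character.
Classes are built by single-linkage clustering (connected components)
over pairwise local-alignment hits between pooled, species-tagged
consensus contigs. Single linkage mirrors how all-vs-all sequence
search naturally merges libraries: any chain of ≥ 80 %-identity
overlaps joins two contigs into the same class, and no stricter
criterion (e.g. complete linkage) is imposed. The cost of that choice
is the usual one — a single spurious bridge can merge two families;
the coverage requirement (below) exists to make such bridges rare.

### Similarity search

The aligner is a seeded local search. Candidate pairs must share one
exact k-mer (default k = 13) on either strand; candidates are aligned
with an affine-gap local aligner (match +1, mismatch −1, gap open −2,
gap extend −1; Biopython's C implementation of Gotoh's algorithm). A
hit passes when

* identity ≥ 0.80 — identity is matched columns divided by **all**
  alignment columns, gap columns included, and `N` never matches.
  Counting gap columns in the denominator is the stricter of the
  plausible conventions; the threshold is inclusive (a pair at exactly
  80 % passes).
* coverage ≥ 0.50 of the shorter sequence. All-vs-all search
  conventions leave the overlap requirement open; without one, short
  high-identity matches (e.g. shared simple-sequence stretches) would
  merge unrelated classes. Exposed as `--min-coverage`.

Both strands are searched because repeat orientation in assemblies is
arbitrary; minus-strand hits carry an inverted subject interval, as in
the 12-column tabular convention used for import/export. E-values are
not computed — identity and coverage are the acceptance criteria.

Seeding is a completeness/speed trade, not an approximation knob: a
homologous pair is missed only if its best alignment contains no exact
run of k matches. By pigeonhole, an alignment of L columns with m
non-match columns contains a run of at least (L − m)/(m + 1) matches,
so for the divergences at which classes are meaningful (≤ 10–20 %)
misses are rare, and for the audit conditions used in the test suite
(~1 % divergence, k = 9, L ≥ 150) they are impossible for all
practical purposes (the audit asserts exact agreement with exhaustive
all-pairs alignment).

### Filters

* **size ≥ 5** members (pooled across species), matching the practice
  of discarding tiny read-cluster groups. The simulator emits one
  consensus contig per family per species, so a quartet class has at
  most 4 members; simulation-driven experiments therefore run with
  `min_size = 1`, and the ≥ 5 rule is exercised on constructed inputs.
* **abundance ≥ 10⁻⁴** (0.01 % of a species' reads) in at least one
  species, skipped when abundances are unknown. Interpreted
  per-species because read-fraction thresholds are applied within each
  species' clustering run.

### Distance, tree, concordance

For species *i*, *j*: `d_ij = 1 − N_shared/N_common` with `N_common`
the size of the pooled (union) class set of the pair — the Jaccard
distance on presence sets, a true metric. Because the printed
definition of the denominator admits a second reading, the Sørensen
form `1 − 2·N_shared/(N_i + N_j)` is available as `variant="mean"`;
both coincide at 0 (identical repertoires) and 1 (disjoint), and on
every simulated dataset examined they produce the same NJ topology.
Abundances are never used in distances.

Neighbor joining follows the canonical agglomeration: minimise
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, branch lengths
`v_i = d(i,j)/2 + (r_i − r_j)/(2(n−2))`, reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, closed three-point formulas at
n = 3. Ties in Q are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), making
the output deterministic; negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch, preserving
leaf-to-leaf path lengths. On additive inputs the implementation
reproduces the generating tree and its path lengths to 1e-9 (tested),
and it is cross-checked against an independent NJ implementation on
noisy inputs. Midpoint rooting and Robinson–Foulds distances are
delegated to scikit-bio (RF is computed on unrooted splits).

Per-class concordance uses Dollo parsimony: repeats arise once (a
repeat must amplify from a single copy to detectability, so repeated
independent origination of the *same* family is implausible) and may
be lost repeatedly. The gain is placed at the MRCA of the pattern;
losses are the maximal pattern-free subtrees below it. A class is
**discordant** iff its pattern has ≥ 2 species and is not the leaf set
of any node of the rooted reference tree; singletons and the full set
are never discordant. This formalises "shared by non-sisters, absent
in the sisters" exactly on quartets and generalises to n taxa. An
unrooted reference tree is midpoint-rooted first. Because two figures'
worth of pairwise-sharing conventions are possible, both pair tables
are emitted: classes present in *exactly* a pair, and classes present
in a pair regardless of other species.

## The simulator

Families originate as Poisson events (rate `gain_rate` per lineage per
unit time) on the branches of a rooted, time-scaled tree, including a
stem branch above the root (families shared by all tips must predate
the radiation). Sequences start as uniform-random DNA of length
`seq_length_range` and evolve independently down each lineage:
substitutions at `subst_rate`/site, indels at `indel_rate`/site with
geometric lengths (mean 3), insertion content random. Loss is a
per-family Poisson process; horizontal transfer (optional) copies the
donor's current sequence into a uniformly chosen contemporaneous
lineage, replacing any resident copy. At each tip a surviving family
draws a genomic copy number uniformly from `copy_number_range` and is
emitted — one consensus contig per family per species, as
read-clustering yields one representative per repeat class — only if
the draw reaches `detection_min_copies` (default 50, reflecting the
~50–100 copies/haploid genome sensitivity floor of low-coverage repeat
detection). Abundance is copy-number × length, normalised per tip.
Everything is reproducible from a single integer seed, and an internal
replay of the event log must reproduce the recorded tip presence.

What the simulator does **not** model: read-level data and coverage
noise, within-genome copy heterogeneity and concerted evolution,
selection, bursts of amplification, chimeric contigs, annotation
classes (LTR/rDNA/SSR). Passing tests therefore demonstrate the
analysis logic under clean family structure — not robustness to
assembly artefacts of real libraries.

### Regime presets

Both presets share the quartet ((A,B),(C,D)) with equal branch
lengths, a stem equal to the tree depth, and rates per unit time:
gain 10 /lineage, loss 0.06 /family, substitutions 4e-3 /site, indels
4e-4 /site, founder lengths 120–250 bp, copy numbers 25–2500,
detection threshold 50 copies. `young_flock` has MRCA depth 1 (a ~3 My
flock analogue); `ancient_flock` is the same tree scaled 20× (~60 My),
same per-time rates — age is the only difference between the regimes.

The rates are a calibration: no quantitative gain/loss rates exist for
the motivating systems, so values were chosen (once) to reproduce the
qualitative contrast the presets exist to emulate, with the loss rate
as the pivotal quantity. With depth × loss = 0.06 a stem-born family
survives everywhere and the all-four pattern dominates the young
flock; at 20× depth (depth × loss = 1.2) ancestral families are almost
all lost and terminal-branch gains make species-specific classes
modal. The same number also keeps loss-generated non-clade patterns
(plus ~1 % detection dropout) below 5 % of classes in both regimes, so
that discordance flags stay interpretable as transfer signal. Founder
lengths of 120–250 bp keep the 100-replicate experiments fast; they
sit at the short end of real repeat-contig lengths, which span up to a
few kb (the generic `SimParams` default is 150–2000 bp).

## Problem sizes and numerics

* Regime experiments: 100 pipeline replicates per preset (≈ 40–600
  classes per replicate), both distance variants; HT detection uses 50
  replicates of the young preset with `ht_rate = 0.08`.
* Seeding audit: 20 shallow-quartet datasets (≤ 200 contigs each),
  seeded search vs exhaustive all-pairs alignment, plus adjusted Rand
  index ≥ 0.95 between recovered classes and true families.
* NJ validation: 100 random binary trees (4–8 leaves, lengths
  U(0.1, 2)); distances reproduced to 1e-9. Metric properties: 1000
  random presence matrices.
* Dollo flagging: exhaustive single-gain labeling oracle on random
  trees up to 8 leaves, 1000 random patterns.
* Distance edge cases: a species pair with an empty pooled class set
  has no defined distance (error); a species absent from every class
  blocks matrix construction. Equal-distance NJ inputs resolve by the
  deterministic tie rule and may legitimately contain zero-length
  internal branches.

## Known limitations

* Single-linkage classes inherit blast-style chaining: at divergences
  near the identity threshold a family can split, and a shared
  low-complexity stretch longer than the coverage floor can merge two
  families.
* Dollo-based discordance cannot distinguish horizontal transfer from
  incomplete lineage sorting, hybridisation, or detection dropout; the
  flag marks candidates, not verdicts.
* The shared-repeat distance is not linear in time (presence/absence
  saturates), so branch lengths of the repeat tree are not comparable
  to sequence-based branch lengths; only the topology is used.
* With fewer than three species the distance matrix/tree stages refuse
  to run; two-species comparisons are limited to the pair tables.
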