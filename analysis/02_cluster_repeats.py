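#!/usr/bin/env python
"""Pool the species libraries and cluster contigs into repeat classes.

For each simulated regime: tag every contig with its species prefix,
run the all-vs-all similarity search (80 % identity over at least half
of the shorter contig, both strands), build connected-component repeat
classes, and tabulate the cross-species sharing patterns. Writes
hits.tsv, presence.tsv and patterns.tsv next to each regime's data and
prints the sharing spectrum — the young flock should be dominated by
the all-four pattern, the ancient flock by species-specific classes.
"""

import argparse
import sys
from pathlib import Path

import repeatphylo as rp


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path,
                        default=Path(__file__).resolve().parent.parent / "results" / "data")
    args = parser.parse_args()

    for regime in ("young_flock", "ancient_flock"):
        indir = args.datadir / regime
        if not indir.exists():
            print(f"{indir} missing - run 01_simulate_flocks.py first",
                  file=sys.stderr)
            return 1
        species = sorted(p.stem for p in indir.glob("*.fasta"))
        libraries = [
            rp.load_library(indir / f"{sp}.fasta", sp,
                            indir / f"{sp}.abundance.tsv")
            for sp in species
        ]
        pooled = rp.pool_with_prefixes(libraries)
        hits = rp.all_vs_all(pooled)
        rp.write_hits_table(hits, indir / "hits.tsv")
        # one consensus contig per family per species: the >=5-member
        # filter that applies to raw read-cluster output is meaningless
        # here, so retain classes of any size
        classes = rp.filter_classes(rp.build_classes(pooled, hits), min_size=1)
        matrix = rp.presence_matrix(classes, species)
        matrix.to_frame().to_csv(indir / "presence.tsv", sep="\t")
        table = rp.tabulate_patterns(matrix)
        rp.write_pattern_table(table, indir / "patterns.tsv")
        top = ", ".join(
            f"{r.pattern}: {r.count} ({100 * r.proportion:.0f}%)"
            for r in table.head(4).itertuples()
        )
        print(f"{regime}: {len(pooled)} contigs, {len(hits)} hits, "
              f"{len(classes)} classes; top patterns: {top}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
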