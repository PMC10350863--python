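"""End-to-end orchestration of the comparative-repeatome analysis.

Stages: load per-species libraries → pool with species prefixes →
all-vs-all similarity search (or import of an external hits table) →
repeat-class construction and filtering → presence matrix → sharing
patterns → shared-repeat distance matrix → neighbor joining + midpoint
rooting → (optionally) concordance against a reference phylogeny.
Every intermediate artifact is written to the output directory along
with a JSON manifest that records parameters, inputs and outputs, so
an identical configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import concordance as conc
from . import distance as dist
from . import patterns as pat
from . import io as rio
from . import tree as rtree
from .search import SearchParams, all_vs_all

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("repeatphylo")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``libraries`` maps species tag -> FASTA path (>= 3 species for tree
    inference); in-memory libraries may be passed instead via
    ``run_pipeline(config, libraries=...)``. ``hits_path`` short-cuts
    the internal search with an external 12-column hits table.
    """

    libraries: dict[str, str] = field(default_factory=dict)
    abundances: dict[str, str] = field(default_factory=dict)
    search: SearchParams = field(default_factory=SearchParams)
    min_size: int = 5
    min_abundance: float = 1e-4
    variant: str = "union"
    reference_tree: str | None = None
    hits_path: str | None = None
    outdir: str = "repeatphylo_out"

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig, libraries=None) -> dict:
    """Run every stage; returns a result bundle (also written to disk).

    The bundle maps stage names to in-memory results and ``artifacts``
    to the files written. On a stage failure the partial outputs stay
    on disk next to a ``FAILED`` marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    bundle: dict = {"artifacts": artifacts}
    t_start = time.time()
    stage = "setup"

    def tick(name: str):
        nonlocal stage
        stage = name
        log.info("stage %s ...", name)

    try:
        tick("load")
        if libraries is None:
            if len(config.libraries) < 1:
                raise ValueError("no input libraries configured")
            libraries = [
                rio.load_library(path, tag, config.abundances.get(tag))
                for tag, path in config.libraries.items()
            ]
        else:
            libraries = list(libraries)
        species = [lib.species for lib in libraries]
        if len(species) < 3:
            raise ValueError(
                f"tree_inference requires >= 3 species, got {len(species)}"
            )

        tick("pool")
        pooled = rio.pool_with_prefixes(libraries)

        tick("search")
        if config.hits_path:
            hits = rio.read_hits_table(config.hits_path)
        else:
            hits = all_vs_all(pooled, config.search)
        hits_file = outdir / "hits.tsv"
        rio.write_hits_table(hits, hits_file)
        artifacts["hits"] = str(hits_file)

        tick("cluster")
        classes = pat.build_classes(pooled, hits)
        retained = pat.filter_classes(classes, config.min_size, config.min_abundance)
        if not retained:
            raise ValueError("no repeat classes retained after filtering")
        bundle["classes"] = retained

        tick("presence")
        matrix = pat.presence_matrix(retained, species)
        bundle["presence"] = matrix
        presence_file = outdir / "presence.tsv"
        matrix.to_frame().to_csv(presence_file, sep="\t")
        artifacts["presence"] = str(presence_file)

        tick("patterns")
        table = pat.tabulate_patterns(matrix)
        bundle["patterns"] = table
        patterns_file = outdir / "patterns.tsv"
        rio.write_pattern_table(table, patterns_file)
        artifacts["patterns"] = str(patterns_file)

        tick("distance")
        dm = dist.distance_matrix(matrix, config.variant)
        bundle["distance"] = dm
        dm_file = outdir / "distances.tsv"
        dm.write_tsv(dm_file)
        artifacts["distance"] = str(dm_file)

        tick("tree")
        nj_tree = rtree.neighbor_joining(dm)
        rooted = rtree.midpoint_root(nj_tree)
        bundle["nj_tree"] = nj_tree
        bundle["rooted_tree"] = rooted
        tree_file = outdir / "nj_tree.nwk"
        rtree.write_newick(rooted, tree_file)
        artifacts["tree"] = str(tree_file)

        if config.reference_tree:
            tick("concordance")
            ref = rtree.read_newick(config.reference_tree)
            if len(ref.children) > 2:  # unrooted reference: midpoint-root it first
                ref = rtree.midpoint_root(ref)
            report = conc.flag_discordant(matrix, ref)
            bundle["concordance"] = report
            bundle["rf_distance"] = conc.rf_distance(nj_tree, ref)
            report_file = outdir / "concordance.tsv"
            report.to_csv(report_file, sep="\t", index=False)
            artifacts["concordance"] = str(report_file)
            for name, fn in (
                ("pair_exclusive", conc.pairwise_exclusive_shared),
                ("pair_any", conc.pairwise_shared_any),
            ):
                pair_file = outdir / f"{name}.tsv"
                fn(matrix).to_csv(pair_file, sep="\t", index=False)
                artifacts[name] = str(pair_file)
        else:
            bundle["concordance"] = None

        tick("manifest")
        manifest = {
            "config": config.to_jsonable(),
            "species": species,
            "n_contigs": len(pooled),
            "n_hits": len(hits),
            "n_classes_total": len(classes),
            "n_classes_retained": len(retained),
            "rf_distance": bundle.get("rf_distance"),
            "concordance_run": config.reference_tree is not None,
            "artifacts": artifacts,
            "elapsed_s": round(time.time() - t_start, 3),
        }
        manifest_file = outdir / "manifest.json"
        manifest_file.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        artifacts["manifest"] = str(manifest_file)
        bundle["manifest"] = manifest
        return bundle
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err
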