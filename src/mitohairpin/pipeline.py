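"""End-to-end analysis: scan -> coverage -> poly(A) -> classification -> report.

One call runs every stage on a genome + annotation + alignment bundle and
writes a directory of TSV/BED/bedGraph/JSON outputs plus a summary JSON of
headline counts.  Outputs are deterministic for identical inputs and
config; on any stage failure the partially written directory is removed.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import coverage as cov
from . import genome as gm
from . import palindrome as pal
from . import transcripts as tr

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    fasta: str
    annotation: str
    out_dir: str
    dna_sam: str | None = None
    rna_sam: str | None = None
    # scan
    min_stem: int = 10
    max_stem: int = 300
    max_loop: int = 100
    circular_scan: bool = False
    # coverage / drops
    flank: int = 200
    drop_threshold: float = 0.5
    mask_intervals: list = field(default_factory=list)  # [(start, stop)]
    mask_cap: int = 8000
    # poly(A)
    min_tail: int = 4
    min_support: int = 2
    cluster_window: int = 3
    short_utr_max: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        for attr in ("fasta", "annotation"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        for attr in ("dna_sam", "rna_sam"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        pal.ScanParams(self.min_stem, self.max_stem, self.max_loop,
                       circular=self.circular_scan)

    def defaults_dict(self) -> dict:
        d = dict(self.__dict__)
        d["mask_intervals"] = [list(x) for x in self.mask_intervals]
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_report(config: RunConfig) -> dict:
    """Run every applicable stage and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    DNA-only input skips the poly(A)/transcript stages with a notice.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.defaults_dict()}
    stage = "load"
    try:
        genome = gm.CircularSequence.from_fasta(config.fasta)
        table = gm.read_gene_table(
            config.annotation, genome_id=genome.id, genome_length=len(genome)
        )

        stage = "scan"
        params = pal.ScanParams(config.min_stem, config.max_stem, config.max_loop,
                                circular=config.circular_scan)
        repeats = pal.find_inverted_repeats(genome, params)
        regions = pal.merge_hairpin_regions(repeats)
        flagged = pal.annotate_genes_with_repeats(table, regions)
        pal.repeats_to_tsv(repeats, out / "repeats.tsv")
        pal.regions_to_bed(regions, genome.id, out / "hairpin_regions.bed")
        with open(out / "genes_with_repeats.tsv", "w") as fh:
            fh.write("gene\thas_repeat\n")
            for r in flagged:
                fh.write(f"{r.name}\t{'yes' if r.has_repeat else 'no'}\n")
        summary["n_repeats"] = len(repeats)
        summary["n_hairpin_regions"] = len(regions)
        summary["genes_with_repeats"] = {
            r.name: bool(r.has_repeat) for r in flagged
        }

        stage = "composition"
        gm.write_composition_json(genome, table, out / "composition.json")
        segments = gm.intergenic_complement(table)
        gm.intergenic_to_bed(segments, genome.id, len(genome), out / "intergenic.bed")
        report = gm.validate_annotation(table)
        (out / "annotation_report.txt").write_text(report.summary() + "\n")
        summary["n_intergenic_segments"] = len(segments)
        summary["total_intergenic_bp"] = sum(s.length for s in segments)

        drop_regions = regions
        for lib, sam_path in (("DNA", config.dna_sam), ("RNA", config.rna_sam)):
            if sam_path is None:
                continue
            stage = f"coverage_{lib.lower()}"
            reads = cov.read_alignments(sam_path, ref_id=genome.id)
            track = cov.coverage_tracks(reads, len(genome), library=lib)
            if config.mask_intervals:
                track = cov.mask_and_cap(track, config.mask_intervals, config.mask_cap)
            ratio = cov.end_ratio(track)
            cov.write_bedgraph(track.depth, genome.id, out / f"{lib.lower()}_depth.bedgraph")
            cov.write_bedgraph(ratio.ratio, genome.id, out / f"{lib.lower()}_end_ratio.bedgraph")
            calls = cov.hairpin_drop_calls(track, drop_regions,
                                           config.flank, config.drop_threshold)
            cov.drop_calls_to_tsv(calls, out / f"{lib.lower()}_drop_calls.tsv")
            summary[f"n_{lib.lower()}_reads"] = len(reads)
            summary[f"n_{lib.lower()}_flagged_drops"] = sum(c.flagged for c in calls)
            if lib == "RNA":
                stage = "polya"
                tails = tr.detect_tails(reads, genome, config.min_tail)
                sites = tr.call_polya_sites(tails, config.min_support,
                                            config.cluster_window)
                tr.annotate_sites(sites, table, config.short_utr_max)
                models = tr.build_transcript_models(table, sites)
                bounds = tr.classify_boundaries(table, sites, ratio, track)
                tr.tails_to_tsv(tails, out / "tail_observations.tsv")
                tr.sites_to_tsv(sites, out / "polya_sites.tsv")
                tr.models_to_tsv(models, out / "transcript_models.tsv")
                tr.boundaries_to_tsv(bounds, out / "boundary_classes.tsv")
                summary["n_polya_sites"] = len(sites)
                summary["n_mono"] = sum(m.cistronic_class == "mono" for m in models)
                summary["n_bi"] = sum(m.cistronic_class == "bi" for m in models)
                summary["n_multi"] = sum(m.cistronic_class == "multi" for m in models)
        if config.rna_sam is None:
            logger.info("no RNA alignments supplied; poly(A) stage skipped")
            summary["polya_stage"] = "skipped (DNA-only input)"
    except Exception as e:  # noqa: BLE001 - abort cleanly, name the stage
        shutil.rmtree(out, ignore_errors=True)
        raise StageError(stage, e) from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
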