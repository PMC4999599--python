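"""End-to-end pipeline: tags -> peaks -> consensus -> annotation -> motif.

A single YAML config with per-stage blocks drives the run; every published
threshold (4-fold enrichment, Poisson P 1e-4, FDR 0.001, 100-nt replicate
rule, 2-fold expression change, motif width 10 at site P 0.001) is a named
key defaulting to its standard value.  The run is deterministic under the
configured seed, logs every parameter actually used, and persists partial
artifacts if a stage fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io as vio
from .consensus import (
    assign_target_genes,
    classification_summary,
    classify_peaks,
    expression_overlap,
    intersect_replicates,
)
from .motifs import extract_peak_sequences, motif_fraction, write_meme, zoops_em
from .peaks import PeakCallParams, call_peaks, write_peaks_bed
from .simulate import SyntheticConfig, write_study
from .tags import clonal_filter, estimate_fragment_length, read_tags
from .validation import mapping_summary

logger = logging.getLogger("velvetchip")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    chip_tags: List[Path]
    input_tags: Path
    genome_fasta: Path
    annotation_gff: Path
    expression_tsv: Optional[Path] = None
    outdir: Path = Path("velvetchip_out")
    seed: int = 0
    max_per_position: int = 3
    max_shift: int = 500
    bin_size: int = 10
    consensus_max_dist: int = 100
    expression_fold_threshold: float = 2.0
    motif_width: int = 10
    motif_p_threshold: float = 0.001
    motif_n_starts: int = 20
    motif_max_iter: int = 200
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        base = Path(path).parent
        paths = raw.get("paths", {})

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        peak_params = PeakCallParams(**raw.get("peak_calling", {}))
        kwargs = dict(
            chip_tags=[resolve(p) for p in paths["chip_tags"]],
            input_tags=resolve(paths["input_tags"]),
            genome_fasta=resolve(paths["genome_fasta"]),
            annotation_gff=resolve(paths["annotation_gff"]),
            outdir=resolve(paths.get("outdir", "velvetchip_out")),
            peak_params=peak_params,
        )
        if paths.get("expression_tsv"):
            kwargs["expression_tsv"] = resolve(paths["expression_tsv"])
        for key in (
            "seed",
            "max_per_position",
            "max_shift",
            "bin_size",
            "consensus_max_dist",
            "expression_fold_threshold",
            "motif_width",
            "motif_p_threshold",
            "motif_n_starts",
            "motif_max_iter",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate(self) -> None:
        for p in [*self.chip_tags, self.input_tags, self.genome_fasta, self.annotation_gff]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _write_report(report: Dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True, default=str)
        handle.write("\n")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run the full analysis; returns (and writes) the JSON report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {"seed": config.seed, "libraries": [], "stages_skipped": []}
    stage = "setup"
    try:
        stage = "load"
        genome = vio.read_fasta(config.genome_fasta)
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        genes = vio.read_gff3(config.annotation_gff)
        libs = [read_tags(p) for p in config.chip_tags]
        input_raw = read_tags(config.input_tags)
        logger.info("loaded %d ChIP libraries, input %d tags", len(libs), input_raw.total_tags)

        stage = "tag_processing"
        chips = [clonal_filter(lib, config.max_per_position) for lib in libs]
        input_lib = clonal_filter(input_raw, config.max_per_position)
        frag_estimates = [
            estimate_fragment_length(lib, config.max_shift, bin_size=config.bin_size)
            for lib in chips
        ]

        stage = "peak_calling"
        results = []
        for i, (chip, frag) in enumerate(zip(chips, frag_estimates)):
            params = PeakCallParams(**{**vars(config.peak_params), "seed": config.seed + i})
            res = call_peaks(chip, input_lib, chrom_lengths, params, frag.length)
            results.append(res)
            write_peaks_bed(res.peaks, outdir / f"peaks_rep{i + 1}.bed")
            logger.info(
                "rep%d: fragment %d, %d candidates, %d FDR-pass, %d differential, %d peaks",
                i + 1, frag.length, res.n_candidates, res.n_pass_fdr,
                res.n_differential, res.n_total,
            )
        for lib, chip, frag, res in zip(libs, chips, frag_estimates, results):
            raw = lib.raw_tags + lib.n_skipped
            mapped = lib.raw_tags
            report["libraries"].append(
                {
                    "name": lib.name,
                    "reads": raw,
                    "mapped": mapped,
                    "percent_mapped": mapping_summary(raw, mapped) if raw else 0.0,
                    "tags_after_clonal_filter": chip.total_tags,
                    "fragment_length": frag.length,
                    "n_pass_fdr": res.n_pass_fdr,
                    "n_differential": res.n_differential,
                    "n_total_peaks": res.n_total,
                }
            )
        input_raw_total = input_raw.raw_tags + input_raw.n_skipped
        report["libraries"].append(
            {
                "name": input_raw.name,
                "reads": input_raw_total,
                "mapped": input_raw.raw_tags,
                "percent_mapped": mapping_summary(input_raw_total, input_raw.raw_tags)
                if input_raw_total
                else 0.0,
                "tags_after_clonal_filter": input_lib.total_tags,
            }
        )

        stage = "consensus"
        if len(results) >= 2:
            consensus = intersect_replicates(
                results[0].peaks, results[1].peaks, config.consensus_max_dist
            )
        else:
            from .consensus import ConsensusPeak

            consensus = [
                ConsensusPeak(p.chrom, p.start, p.end, p.summit, p.peak_value, (p,))
                for p in results[0].peaks
            ]
        report["n_consensus_peaks"] = len(consensus)
        with open(outdir / "consensus_peaks.bed", "w") as handle:
            for i, c in enumerate(consensus):
                handle.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\tconsensus_{i}\t"
                    f"{round(c.peak_value or 0)}\t.\t{c.summit}\n"
                )

        stage = "annotation"
        classified = classify_peaks(consensus, genes)
        report["classification"] = classification_summary(classified)
        targets = assign_target_genes(classified)
        report["n_target_genes"] = len(targets)

        stage = "expression_overlap"
        if config.expression_tsv is not None and Path(config.expression_tsv).exists():
            expression = vio.read_expression(config.expression_tsv)
            overlap = expression_overlap(targets, expression, config.expression_fold_threshold)
            report["expression_overlap"] = {
                "percent": overlap.percent,
                "n_dependent": overlap.n_dependent,
                "n_total": overlap.n_total,
            }
        else:
            report["stages_skipped"].append("expression_overlap")
            logger.warning("expression table missing; overlap stage skipped")
        with open(outdir / "target_genes.tsv", "w") as handle:
            handle.write("gene_id\tpeak_id\trelation\tpeak_value\tdependent\tmax_abs_log2\n")
            for t in targets:
                handle.write(
                    f"{t.gene_id}\t{t.peak_id}\t{t.relation}\t"
                    f"{'' if t.peak_value is None else f'{t.peak_value:.2f}'}\t"
                    f"{'' if t.dependent is None else int(t.dependent)}\t"
                    f"{'' if t.max_abs_log2 is None else f'{t.max_abs_log2:.3f}'}\n"
                )

        stage = "motif"
        half = max(results[0].peak_size, config.motif_width) // 2
        intervals = [
            (c.chrom, max(0, c.summit - half), c.summit + half) for c in consensus
        ]
        if len(intervals) >= 10:
            seqs = extract_peak_sequences(intervals, genome)
            em = zoops_em(
                seqs,
                width=config.motif_width,
                n_starts=config.motif_n_starts,
                max_iter=config.motif_max_iter,
                seed=config.seed,
            )
            write_meme(em.pwm, outdir / "motif.meme")
            percent, _ = motif_fraction(seqs, em.pwm, config.motif_p_threshold)
            report["motif"] = {
                "consensus": em.pwm.consensus,
                "gamma": em.gamma,
                "information_content_bits": em.pwm.information_content(),
                "percent_peaks_with_motif": percent,
            }
        else:
            report["stages_skipped"].append("motif")
            logger.warning("fewer than 10 consensus peaks; motif stage skipped")

        _write_report(report, outdir)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised as StageError
        try:
            report["failed_stage"] = stage
            _write_report(report, outdir)
        except Exception:  # pragma: no cover - best-effort persistence
            pass
        raise StageError(stage, exc) from exc


FIXTURE_PROFILES = {
    "tiny": dict(
        genome_length=100_000,
        n_chromosomes=1,
        n_genes=40,
        n_sites=10,
        n_chip_tags=10_000,
        n_input_tags=10_000,
        site_enrichment=150.0,
        min_site_distance=1200,
    ),
    "paper-shape": dict(
        genome_length=400_000,
        n_chromosomes=2,
        n_genes=240,
        n_sites=60,
        n_chip_tags=40_000,
        n_input_tags=40_000,
        site_enrichment=200.0,
        min_site_distance=1500,
    ),
}


def make_fixture(profile: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a self-contained dataset plus config.yaml runnable end to end.

    ``tiny`` is a 100 kb / 10-site smoke dataset; ``paper-shape`` carries
    two ChIP replicates plus input over 2 x 400 kb with ~60 planted sites,
    a tenth-scale analogue of a genome-wide binding study.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(FIXTURE_PROFILES)}")
    config = SyntheticConfig(seed=seed, **FIXTURE_PROFILES[profile])
    outdir = Path(outdir)
    write_study(config, outdir)
    cfg = {
        "seed": seed,
        "paths": {
            "chip_tags": ["chip_rep1.bed", "chip_rep2.bed"],
            "input_tags": "input.bed",
            "genome_fasta": "genome.fa",
            "annotation_gff": "genes.gff3",
            "expression_tsv": "expression.tsv",
            "outdir": "results",
        },
    }
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(cfg, handle)
    return outdir
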