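"""Synthetic ChIP-seq study generator.

Builds a toy genome with non-overlapping stranded gene models, plants
binding sites (preferentially intergenic) that optionally carry a 10-nt
consensus motif, draws two replicate ChIP tag libraries plus an input
library, and writes an expression table in which a chosen subset of genes
carries >= 2-fold changes.  Every output is a pure function of the
configuration and seed, and the ground truth (site centers, motif
placements, dependent genes) is recorded for downstream evaluation.

Tag model: input tags are uniform per chromosome with Bernoulli(0.5)
strands.  ChIP tags are a mixture of that background and site-derived tags;
a site-derived plus-strand tag starts at center - F/2 + eps and a
minus-strand tag at center + F/2 - eps with eps ~ round(Normal(0, F/8)),
reproducing the strand-offset structure a fragment-length estimator needs.
Each emitted tag is duplicated with a configurable clonal-duplicate
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .consensus import GeneIndex, GeneModel
from .motifs import reverse_complement
from .tags import TagLibrary

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}


class PlacementError(RuntimeError):
    """Raised when genes or sites cannot be placed under the configuration."""


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults describe a small but statistically faithful study: a 500 kb
    single-chromosome genome with 150 genes, 50 binding sites of ~200
    expected ChIP tags each against a 50k-tag library (about 8-fold window
    enrichment over background), fragment length 200 bp, an AACCTTGGAA
    consensus planted at 80% of sites, 10% clonal duplicates, and 30 genes
    with >= 2-fold expression changes.
    """

    genome_length: int = 500_000  # bp per chromosome
    n_chromosomes: int = 1
    n_genes: int = 150
    n_sites: int = 50
    fragment_length: int = 200
    n_chip_tags: int = 50_000
    n_input_tags: int = 50_000
    site_enrichment: float = 200.0  # expected ChIP tags per site
    motif_consensus: str = "AACCTTGGAA"
    motif_plant_prob: float = 0.8
    max_mismatches: int = 1
    dup_rate: float = 0.1
    n_dep_genes: int = 30
    seed: int = 0
    read_length: int = 50
    intergenic_fraction: float = 0.8
    min_site_distance: int = 1500
    gene_length_range: Tuple[int, int] = (600, 2000)

    def __post_init__(self) -> None:
        if self.genome_length <= 10 * self.fragment_length:
            raise ValueError("genome_length must exceed 10 x fragment_length")
        if not (0 <= self.motif_plant_prob <= 1 and 0 <= self.dup_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_sites * self.site_enrichment >= self.n_chip_tags:
            raise ValueError("n_sites x site_enrichment must be < n_chip_tags")
        if len(self.motif_consensus) != 10:
            raise ValueError("motif_consensus must be 10 nt")
        if not set(self.motif_consensus) <= set("ACGT"):
            raise ValueError("motif_consensus must be over ACGT")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}


@dataclass
class GroundTruth:
    """What was planted: the oracle for recovery tests."""

    site_positions: Dict[str, List[int]] = field(default_factory=dict)
    motif_positions: List[Tuple[str, int, str]] = field(default_factory=list)
    dependent_genes: Set[str] = field(default_factory=set)

    def all_sites(self) -> List[Tuple[str, int]]:
        return [(c, p) for c, pos in self.site_positions.items() for p in pos]


def _decode(arr: np.ndarray) -> str:
    return _BASES_U8[arr].tobytes().decode()


def generate_genome(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, np.ndarray], List[GeneModel]]:
    """I.i.d.-uniform genome plus non-overlapping stranded gene models.

    The genome is returned as mutable int arrays (0..3 base codes) so sites
    can be planted in place; use :func:`decode_genome` for strings.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome = {
        chrom: rng.integers(0, 4, size=config.genome_length, dtype=np.int8)
        for chrom in config.chrom_names
    }
    genes: List[GeneModel] = []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gene_no = 0
    min_gap = 100
    lo, hi = config.gene_length_range
    for chrom, k in zip(config.chrom_names, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=int(k))
        needed = int(lengths.sum()) + (int(k) + 1) * min_gap
        if needed > config.genome_length:
            raise PlacementError(
                f"cannot place {k} non-overlapping genes of {lo}-{hi} bp "
                f"in {config.genome_length} bp on {chrom}"
            )
        extra = config.genome_length - needed
        cuts = np.sort(rng.integers(0, extra + 1, size=int(k)))
        gaps = np.diff(np.concatenate([[0], cuts, [extra]])) + min_gap
        pos = 0
        for length, gap in zip(lengths, gaps[:-1]):
            pos += int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gene_no:04d}",
                    chrom=chrom,
                    start=pos,
                    end=pos + int(length),
                    strand=strand,
                )
            )
            pos += int(length)
            gene_no += 1
    return genome, genes


def decode_genome(genome: Dict[str, np.ndarray]) -> Dict[str, str]:
    return {chrom: _decode(arr) for chrom, arr in genome.items()}


def _intergenic_intervals(
    config: SyntheticConfig, genes: List[GeneModel], margin: int
) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in config.chrom_names:
        spans = sorted(
            (g.start, g.end) for g in genes if g.chrom == chrom
        )
        intervals = []
        prev = margin
        for start, end in spans:
            if start - prev > 0:
                intervals.append((prev, start))
            prev = max(prev, end)
        if config.genome_length - margin - prev > 0:
            intervals.append((prev, config.genome_length - margin))
        out[chrom] = intervals
    return out


def plant_sites_and_motifs(
    genome: Dict[str, np.ndarray],
    genes: List[GeneModel],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Place site centers (mostly intergenic) and plant the consensus motif.

    Modifies the genome in place.  With probability ``motif_plant_prob`` a
    site's central 10 bp are replaced by the consensus, on a random strand,
    with 0..``max_mismatches`` substitutions drawn uniformly.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    margin = 2 * config.fragment_length
    intervals = _intergenic_intervals(config, genes, margin)
    n_inter = int(round(config.n_sites * config.intergenic_fraction))
    n_genic = config.n_sites - n_inter

    truth = GroundTruth(site_positions={c: [] for c in config.chrom_names})
    placed: Dict[str, List[int]] = {c: [] for c in config.chrom_names}

    def try_place(chrom: str, center: int) -> bool:
        if not (margin <= center < config.genome_length - margin):
            return False
        if any(abs(center - c) < config.min_site_distance for c in placed[chrom]):
            return False
        placed[chrom].append(center)
        truth.site_positions[chrom].append(center)
        return True

    flat_inter = [
        (chrom, start, end)
        for chrom, ivs in intervals.items()
        for start, end in ivs
        if end - start > 40
    ]
    if not flat_inter and n_inter > 0:
        raise PlacementError("no intergenic space available for site placement")
    weights = np.array([end - start for _, start, end in flat_inter], dtype=float)
    weights /= weights.sum()

    attempts = 0
    placed_inter = 0
    while placed_inter < n_inter:
        attempts += 1
        if attempts > 10_000 * max(config.n_sites, 1):
            raise PlacementError("could not place intergenic sites (min distance too large?)")
        chrom, start, end = flat_inter[rng.choice(len(flat_inter), p=weights)]
        center = int(rng.integers(start + 20, end - 20))
        if try_place(chrom, center):
            placed_inter += 1

    genic = [g for g in genes if g.end - g.start > 40]
    attempts = 0
    placed_genic = 0
    while placed_genic < n_genic:
        attempts += 1
        if attempts > 10_000 * max(config.n_sites, 1):
            raise PlacementError("could not place intragenic sites")
        g = genic[int(rng.integers(0, len(genic)))]
        center = int(rng.integers(g.start + 20, g.end - 20))
        if try_place(g.chrom, center):
            placed_genic += 1

    for chrom in truth.site_positions:
        truth.site_positions[chrom].sort()

    for chrom, centers in truth.site_positions.items():
        for center in centers:
            if rng.random() >= config.motif_plant_prob:
                continue
            word = config.motif_consensus
            if config.max_mismatches > 0:
                k = int(rng.integers(0, config.max_mismatches + 1))
                word_list = list(word)
                for pos in rng.choice(10, size=k, replace=False):
                    choices = [b for b in "ACGT" if b != word_list[pos]]
                    word_list[pos] = choices[int(rng.integers(0, 3))]
                word = "".join(word_list)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = word if strand == "+" else reverse_complement(word)
            codes = np.array([_BASE_TO_INT[b] for b in planted], dtype=np.int8)
            genome[chrom][center - 5 : center + 5] = codes
            truth.motif_positions.append((chrom, center, strand))
    return truth


def _draw_site_tags(
    centers_chrom: List[Tuple[str, int]],
    n: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> List[Tuple[str, int, str]]:
    f = config.fragment_length
    site_idx = rng.integers(0, len(centers_chrom), size=n)
    strands = rng.random(n) < 0.5
    eps = np.rint(rng.normal(0.0, f / 8.0, size=n)).astype(np.int64)
    records = []
    for idx, is_plus, e in zip(site_idx, strands, eps):
        chrom, center = centers_chrom[int(idx)]
        if is_plus:
            pos = center - f // 2 + int(e)
            strand = "+"
        else:
            pos = center + f // 2 - int(e)
            strand = "-"
        pos = int(np.clip(pos, 0, config.genome_length - 1))
        records.append((chrom, pos, strand))
    return records


def _draw_uniform_tags(
    n: int, config: SyntheticConfig, rng: np.random.Generator
) -> List[Tuple[str, int, str]]:
    chrom_idx = rng.integers(0, config.n_chromosomes, size=n)
    pos = rng.integers(0, config.genome_length, size=n)
    strands = rng.random(n) < 0.5
    names = config.chrom_names
    return [
        (names[int(c)], int(p), "+" if s else "-")
        for c, p, s in zip(chrom_idx, pos, strands)
    ]


def _duplicate(
    records: List[Tuple[str, int, str]], dup_rate: float, rng: np.random.Generator
) -> List[Tuple[str, int, str]]:
    if dup_rate == 0:
        return records
    out = list(records)
    mask = rng.random(len(records)) < dup_rate
    out.extend(rec for rec, m in zip(records, mask) if m)
    return out


def simulate_tags(
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[TagLibrary, TagLibrary, TagLibrary]:
    """Two independent replicate ChIP libraries plus one input library."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rep_rngs = rng.spawn(3)
    centers = truth.all_sites()
    p_site = config.n_sites * config.site_enrichment / config.n_chip_tags

    def draw_chip(sub: np.random.Generator, name: str) -> TagLibrary:
        n_site = int(sub.binomial(config.n_chip_tags, p_site)) if centers else 0
        records = _draw_site_tags(centers, n_site, config, sub) if n_site else []
        records += _draw_uniform_tags(config.n_chip_tags - n_site, config, sub)
        records = _duplicate(records, config.dup_rate, sub)
        return TagLibrary.from_records(records, name=name)

    chip1 = draw_chip(rep_rngs[0], "chip_rep1")
    chip2 = draw_chip(rep_rngs[1], "chip_rep2")
    input_records = _draw_uniform_tags(config.n_input_tags, config, rep_rngs[2])
    input_records = _duplicate(input_records, config.dup_rate, rep_rngs[2])
    input_lib = TagLibrary.from_records(input_records, name="input")
    return chip1, chip2, input_lib


EXPRESSION_NOISE_SD = 0.25
N_TIMEPOINTS = 3


def simulate_expression(
    genes: List[GeneModel],
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-gene log2 expression ratios at three timepoints.

    Background ratios are Normal(0, sd=0.25); the ``n_dep_genes`` dependent
    genes (preferring genes whose 5' end faces a planted site) get
    |log2| >= 1 at one random timepoint with random sign.  Records the
    dependent set in ``truth``.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if config.n_dep_genes > len(genes):
        raise ValueError("n_dep_genes exceeds the number of genes")
    values = rng.normal(0.0, EXPRESSION_NOISE_SD, size=(len(genes), N_TIMEPOINTS))
    gene_ids = [g.gene_id for g in genes]

    index = GeneIndex(genes)
    facing: List[str] = []
    seen: Set[str] = set()
    for chrom, center in truth.all_sites():
        if index.containing(chrom, center) is not None:
            continue
        left = index.left_of(chrom, center)
        right = index.right_of(chrom, center)
        for g, faces5 in (
            (left, left is not None and left.strand == "-"),
            (right, right is not None and right.strand == "+"),
        ):
            if g is not None and faces5 and g.gene_id not in seen:
                facing.append(g.gene_id)
                seen.add(g.gene_id)
    pool = list(rng.permutation(facing))
    remaining = [gid for gid in rng.permutation(gene_ids) if gid not in seen]
    pool.extend(remaining)
    dependent = pool[: config.n_dep_genes]

    id_to_row = {gid: i for i, gid in enumerate(gene_ids)}
    for gid in dependent:
        row = id_to_row[gid]
        tp = int(rng.integers(0, N_TIMEPOINTS))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[row, tp] = sign * (1.0 + abs(rng.normal(0.0, 0.5)))
    truth.dependent_genes = set(dependent)
    columns = [f"log2_t{i + 1}" for i in range(N_TIMEPOINTS)]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=columns)


def simulate_study(config: SyntheticConfig):
    """Full synthetic study: genome, genes, truth, tag libraries, expression."""
    genome, genes = generate_genome(config)
    truth = plant_sites_and_motifs(genome, genes, config)
    chip1, chip2, input_lib = simulate_tags(truth, config)
    expression = simulate_expression(genes, truth, config)
    return genome, genes, truth, (chip1, chip2, input_lib), expression


def write_study(config: SyntheticConfig, outdir: str | Path) -> Path:
    """Generate a study and write all artifacts to ``outdir``."""
    from . import io as vio
    from .tags import write_tags_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth, (chip1, chip2, input_lib), expression = simulate_study(config)
    vio.write_fasta(decode_genome(genome), outdir / "genome.fa")
    vio.write_gff3(genes, outdir / "genes.gff3")
    write_tags_bed(chip1, outdir / "chip_rep1.bed", config.read_length)
    write_tags_bed(chip2, outdir / "chip_rep2.bed", config.read_length)
    write_tags_bed(input_lib, outdir / "input.bed", config.read_length)
    vio.write_expression(expression, outdir / "expression.tsv")
    vio.write_ground_truth(truth, outdir / "ground_truth.json")
    return outdir
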