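"""Replicate reconciliation, orientation-aware annotation and target genes.

Peaks from two biological replicates are merged into consensus peaks when
their summits lie within 100 nt.  Each consensus peak is then classified by
its genomic context: inside an ORF, or intergenic with the flanking genes'
orientations deciding whether the peak sits 3' of both neighbors, 5' of
exactly one, or in a divergent promoter (5' of both).  Genes whose 5' end
faces a peak are attributed as candidate targets, and the fraction of
targets with a >= 2-fold expression change is the expression-overlap
statistic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .peaks import Peak


class PeakClass(str, Enum):
    IN_ORF = "in_orf"
    THREE_PRIME_BOTH = "three_prime_both"
    FIVE_PRIME_ONE = "five_prime_one"
    DIVERGENT_FIVE_PRIME_BOTH = "divergent_five_prime_both"
    UNFLANKED = "unflanked"


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ConsensusPeak:
    """A binding region supported by both replicates (summits <= 100 nt apart)."""

    chrom: str
    start: int
    end: int
    summit: int
    peak_value: Optional[float] = None
    members: Tuple[Peak, ...] = ()

    @classmethod
    def from_members(cls, a: Peak, b: Peak) -> "ConsensusPeak":
        values = [v for v in (a.peak_value, b.peak_value) if v is not None]
        return cls(
            chrom=a.chrom,
            start=min(a.start, b.start),
            end=max(a.end, b.end),
            summit=(a.summit + b.summit) // 2,
            peak_value=float(np.mean(values)) if values else None,
            members=(a, b),
        )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.summit}"


@dataclass
class ClassifiedPeak:
    peak: ConsensusPeak
    peak_class: PeakClass
    five_prime_genes: Tuple[GeneModel, ...] = ()


@dataclass
class TargetGene:
    gene_id: str
    peak_id: str
    relation: str  # "5prime_single" or "5prime_divergent"
    peak_value: Optional[float] = None
    dependent: Optional[bool] = None
    max_abs_log2: Optional[float] = None


def intersect_replicates(
    peaks_a: Sequence[Peak | ConsensusPeak],
    peaks_b: Sequence[Peak | ConsensusPeak],
    max_dist: int = 100,
) -> List[ConsensusPeak]:
    """Greedy nearest-summit matching of two replicate peak lists.

    A pair matches iff the summit distance is <= ``max_dist`` (inclusive);
    each peak is used at most once; ties resolve to the closer pair, then to
    the leftmost.  The pairing is symmetric in its arguments.
    """
    by_chrom_b: Dict[str, List] = {}
    for j, p in enumerate(peaks_b):
        by_chrom_b.setdefault(p.chrom, []).append((p.summit, j))
    for rows in by_chrom_b.values():
        rows.sort()

    candidates = []  # (dist, leftmost summit, rightmost summit, i, j)
    for i, p in enumerate(peaks_a):
        rows = by_chrom_b.get(p.chrom, [])
        summits = [s for s, _ in rows]
        lo = bisect.bisect_left(summits, p.summit - max_dist)
        hi = bisect.bisect_right(summits, p.summit + max_dist)
        for s, j in rows[lo:hi]:
            dist = abs(p.summit - s)
            candidates.append((dist, min(p.summit, s), max(p.summit, s), i, j))
    candidates.sort()

    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))

    out = [ConsensusPeak.from_members(peaks_a[i], peaks_b[j]) for i, j in pairs]
    out.sort(key=lambda c: (c.chrom, c.summit))
    return out


class GeneIndex:
    """Sorted per-chromosome gene lookup: containment and nearest flanks."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: Dict[str, List[int]] = {}
        self._max_end: Dict[str, List[int]] = {}
        self._ends_sorted: Dict[str, List[Tuple[int, int]]] = {}
        self.n_genes = 0
        for chrom, rows in self._by_chrom.items():
            rows.sort(key=lambda g: (g.start, g.end))
            self._starts[chrom] = [g.start for g in rows]
            prefix, running = [], 0
            for g in rows:
                running = max(running, g.end)
                prefix.append(running)
            self._max_end[chrom] = prefix
            self._ends_sorted[chrom] = sorted((g.end, k) for k, g in enumerate(rows))
            self.n_genes += len(rows)

    def containing(self, chrom: str, pos: int) -> Optional[GeneModel]:
        rows = self._by_chrom.get(chrom, [])
        if not rows:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        while i >= 0 and self._max_end[chrom][i] > pos:
            if rows[i].start <= pos < rows[i].end:
                return rows[i]
            i -= 1
        return None

    def left_of(self, chrom: str, pos: int) -> Optional[GeneModel]:
        """Nearest gene wholly left of pos (largest end <= pos)."""
        rows = self._by_chrom.get(chrom, [])
        ends = self._ends_sorted.get(chrom, [])
        i = bisect.bisect_right(ends, (pos, len(rows))) - 1
        if i < 0:
            return None
        return rows[ends[i][1]]

    def right_of(self, chrom: str, pos: int) -> Optional[GeneModel]:
        """Nearest gene wholly right of pos (smallest start > pos)."""
        rows = self._by_chrom.get(chrom, [])
        if not rows:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos)
        if i >= len(rows):
            return None
        return rows[i]


def classify_peak(peak: ConsensusPeak, index: GeneIndex) -> ClassifiedPeak:
    """Classify a peak by its summit position and flanking-gene orientation.

    A summit inside a gene is intragenic (IN_ORF).  Otherwise the facing
    side of the left flank is its 3' side iff that gene is on the plus
    strand, and of the right flank its 5' side iff on the plus strand; the
    two facing sides decide the intergenic subclass.  Peaks missing a flank
    (contig ends) are UNFLANKED, but a present 5'-facing flank still
    contributes a target gene.
    """
    if index.n_genes == 0:
        raise ValueError("annotation is empty")
    summit = peak.summit
    if index.containing(peak.chrom, summit) is not None:
        return ClassifiedPeak(peak, PeakClass.IN_ORF)
    left = index.left_of(peak.chrom, summit)
    right = index.right_of(peak.chrom, summit)
    left_faces_5 = left is not None and left.strand == "-"
    right_faces_5 = right is not None and right.strand == "+"
    if left is None or right is None:
        present, faces5 = (left, left_faces_5) if right is None else (right, right_faces_5)
        genes = (present,) if (present is not None and faces5) else ()
        return ClassifiedPeak(peak, PeakClass.UNFLANKED, genes)
    if left_faces_5 and right_faces_5:
        return ClassifiedPeak(peak, PeakClass.DIVERGENT_FIVE_PRIME_BOTH, (left, right))
    if left_faces_5:
        return ClassifiedPeak(peak, PeakClass.FIVE_PRIME_ONE, (left,))
    if right_faces_5:
        return ClassifiedPeak(peak, PeakClass.FIVE_PRIME_ONE, (right,))
    return ClassifiedPeak(peak, PeakClass.THREE_PRIME_BOTH)


def classify_peaks(
    peaks: Sequence[ConsensusPeak], genes: Sequence[GeneModel]
) -> List[ClassifiedPeak]:
    index = GeneIndex(genes)
    return [classify_peak(p, index) for p in peaks]


def assign_target_genes(classified: Sequence[ClassifiedPeak]) -> List[TargetGene]:
    """Attribute candidate target genes from 5'-facing flanks.

    FIVE_PRIME_ONE peaks contribute their single facing gene, divergent
    peaks both flanking genes; 3'-only and intragenic peaks contribute none.
    A gene upstream of several peaks is counted once, keeping the peak with
    the larger peak value.
    """
    best: Dict[str, TargetGene] = {}
    for cp in classified:
        if not cp.five_prime_genes:
            continue
        relation = (
            "5prime_divergent"
            if cp.peak_class is PeakClass.DIVERGENT_FIVE_PRIME_BOTH
            else "5prime_single"
        )
        for gene in cp.five_prime_genes:
            candidate = TargetGene(
                gene_id=gene.gene_id,
                peak_id=cp.peak.name,
                relation=relation,
                peak_value=cp.peak.peak_value,
            )
            prev = best.get(gene.gene_id)
            if prev is None or (candidate.peak_value or 0.0) > (prev.peak_value or 0.0):
                best[gene.gene_id] = candidate
    return sorted(best.values(), key=lambda t: t.gene_id)


@dataclass
class OverlapResult:
    percent: float
    n_dependent: int
    n_total: int
    targets: List[TargetGene] = field(default_factory=list)


def expression_overlap(
    targets: Sequence[TargetGene],
    expression: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> OverlapResult:
    """Fraction of target genes with a >= ``fold_threshold`` expression change.

    ``expression`` is indexed by gene id with log2-ratio columns (one per
    timepoint).  A target is dependent iff its maximum absolute log2 ratio
    over timepoints is >= log2(fold_threshold), inclusive; genes absent from
    the table count as non-dependent.  Returns the percentage rounded to one
    decimal.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if not targets:
        return OverlapResult(0.0, 0, 0, [])
    log2_thr = np.log2(fold_threshold)
    max_abs = expression.abs().max(axis=1)
    n_dep = 0
    out = []
    for t in targets:
        if t.gene_id in max_abs.index:
            t.max_abs_log2 = float(max_abs.loc[t.gene_id])
            t.dependent = bool(t.max_abs_log2 >= log2_thr)
        else:
            t.max_abs_log2 = None
            t.dependent = False
        n_dep += t.dependent
        out.append(t)
    percent = round(100.0 * n_dep / len(targets), 1)
    return OverlapResult(percent, n_dep, len(targets), out)


def classification_summary(classified: Sequence[ClassifiedPeak]) -> Dict:
    """Per-class counts and percentages (1 decimal); intergenic rollup.

    UNFLANKED peaks are intergenic by construction and are reported
    separately within the intergenic rollup.
    """
    counts = {cls: 0 for cls in PeakClass}
    for cp in classified:
        counts[cp.peak_class] += 1
    n_total = len(classified)
    n_intergenic = n_total - counts[PeakClass.IN_ORF]

    def pct(n: int) -> float:
        return round(100.0 * n / n_total, 1) if n_total else 0.0

    return {
        "n_total": n_total,
        "n_intergenic": n_intergenic,
        "n_intragenic": counts[PeakClass.IN_ORF],
        "percent_intergenic": pct(n_intergenic),
        "percent_intragenic": pct(counts[PeakClass.IN_ORF]),
        "counts": {cls.value: counts[cls] for cls in PeakClass},
        "percentages": {cls.value: pct(counts[cls]) for cls in PeakClass},
    }
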