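"""Tag-library handling.

A *tag* is the mapped 5' position (with strand) of a sequenced read; it is
the atomic unit of all downstream enrichment computation.  This module reads
aligned tags from BED6 or SAM, applies clonal filtering (capping identical
tags to suppress PCR amplification towers), estimates the sequenced fragment
length from the offset between plus- and minus-strand tag clusters, and
builds fragment-extended coverage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Tuple

import numpy as np

Strand = str  # "+" or "-"
Key = Tuple[str, Strand]


@dataclass
class TagLibrary:
    """Per-(chromosome, strand) sorted tag 5' positions (0-based).

    ``raw_tags`` is the number of tags before any filtering; ``total_tags``
    (a property) is the current count.  ``n_skipped`` counts unmapped SAM
    records that were dropped on input.
    """

    positions: Dict[Key, np.ndarray] = field(default_factory=dict)
    raw_tags: int = 0
    name: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for key, arr in self.positions.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.positions[key] = arr
        if self.raw_tags == 0:
            self.raw_tags = self.total_tags

    @property
    def total_tags(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    def chroms(self) -> list[str]:
        return sorted({chrom for chrom, _ in self.positions})

    def on(self, chrom: str, strand: Strand) -> np.ndarray:
        return self.positions.get((chrom, strand), np.empty(0, dtype=np.int64))

    def merged(self, chrom: str) -> np.ndarray:
        """Sorted positions on both strands of one chromosome."""
        plus, minus = self.on(chrom, "+"), self.on(chrom, "-")
        if plus.size == 0:
            return minus
        if minus.size == 0:
            return plus
        return np.sort(np.concatenate([plus, minus]))

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, Strand]], name: str = "", n_skipped: int = 0
    ) -> "TagLibrary":
        buckets: Dict[Key, list] = {}
        for chrom, pos, strand in records:
            buckets.setdefault((chrom, strand), []).append(pos)
        positions = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in buckets.items()}
        return cls(positions=positions, name=name, n_skipped=n_skipped)

    def iter_records(self) -> Iterator[Tuple[str, int, Strand]]:
        for (chrom, strand), arr in sorted(self.positions.items()):
            for pos in arr:
                yield chrom, int(pos), strand


@dataclass
class FragmentEstimate:
    """Fragment-length estimate from +/- strand cross-correlation.

    ``length`` is the argmax of ``profile`` (shift in bp -> Pearson r);
    ``low_confidence`` flags profiles whose maximum correlation is so weak
    (< 0.05) that the argmax is not meaningful.
    """

    length: int
    profile: Dict[int, float]
    low_confidence: bool = False


class TagFileError(ValueError):
    """Raised for malformed tag input; carries the offending line number."""


def read_tags(path: str | Path, fmt: str | None = None, name: str | None = None) -> TagLibrary:
    """Read aligned tags from a BED6 or SAM file.

    One tag per record, at the read's 5' end: BED ``start`` for the plus
    strand, ``end - 1`` for the minus strand.  Unmapped SAM records are
    skipped and counted in ``n_skipped``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "SAM" if suffix == ".sam" else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "SAM"):
        raise ValueError(f"unknown tag format: {fmt!r}")
    if name is None:
        name = path.stem
    if fmt == "SAM":
        return _read_sam(path, name)
    return _read_bed(path, name)


def _read_bed(path: Path, name: str) -> TagLibrary:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TagFileError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TagFileError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise TagFileError(f"{path}:{lineno}: bad strand {strand!r}")
            if end <= start:
                raise TagFileError(f"{path}:{lineno}: end <= start")
            pos = start if strand == "+" else end - 1
            records.append((chrom, pos, strand))
    return TagLibrary.from_records(records, name=name)


def _read_sam(path: Path, name: str) -> TagLibrary:
    import pysam

    records = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                n_skipped += 1
                continue
            if read.is_reverse:
                records.append((read.reference_name, read.reference_end - 1, "-"))
            else:
                records.append((read.reference_name, read.reference_start, "+"))
    return TagLibrary.from_records(records, name=name, n_skipped=n_skipped)


def clonal_filter(library: TagLibrary, max_per_position: int = 3) -> TagLibrary:
    """Retain at most ``max_per_position`` tags per (chrom, position, strand).

    Deterministic (keeps the first ``max_per_position`` copies); idempotent.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    filtered: Dict[Key, np.ndarray] = {}
    for key, arr in library.positions.items():
        uniq, counts = np.unique(arr, return_counts=True)
        capped = np.minimum(counts, max_per_position)
        filtered[key] = np.repeat(uniq, capped)
    return TagLibrary(
        positions=filtered,
        raw_tags=library.raw_tags,
        name=library.name,
        n_skipped=library.n_skipped,
    )


def estimate_fragment_length(
    library: TagLibrary,
    max_shift: int = 500,
    min_shift: int = 20,
    bin_size: int = 10,
) -> FragmentEstimate:
    """Estimate fragment length from strand cross-correlation.

    For each shift d the minus-strand tags are moved left by d bp, both
    strands are binned (``bin_size`` bp) per chromosome, and the Pearson
    correlation between the tracks is computed over the whole genome.  The
    estimate is the shift maximizing the correlation; ties break toward the
    smaller shift.  This is the standard realization of fragment-length
    inference from tag autocorrelation structure.
    """
    has_plus = any(s == "+" and a.size for (_, s), a in library.positions.items())
    has_minus = any(s == "-" and a.size for (_, s), a in library.positions.items())
    if not (has_plus and has_minus):
        raise ValueError("cannot estimate fragment length: need tags on both strands")

    chrom_extent = {}
    for chrom in library.chroms():
        merged = library.merged(chrom)
        if merged.size:
            chrom_extent[chrom] = int(merged[-1]) + 1

    plus_tracks = {}
    for chrom, extent in chrom_extent.items():
        n_bins = extent // bin_size + 1
        plus = library.on(chrom, "+")
        plus_tracks[chrom] = np.bincount(plus // bin_size, minlength=n_bins)[:n_bins]

    profile: Dict[int, float] = {}
    for shift in range(min_shift, max_shift + 1, bin_size):
        xs, ys = [], []
        for chrom, extent in chrom_extent.items():
            n_bins = extent // bin_size + 1
            minus = library.on(chrom, "-") - shift
            minus = minus[minus >= 0]
            track = np.bincount(minus // bin_size, minlength=n_bins)[:n_bins]
            xs.append(plus_tracks[chrom])
            ys.append(track)
        x = np.concatenate(xs).astype(float)
        y = np.concatenate(ys).astype(float)
        if x.std() == 0 or y.std() == 0:
            profile[shift] = 0.0
        else:
            profile[shift] = float(np.corrcoef(x, y)[0, 1])

    best_shift = min_shift
    best_r = -np.inf
    for shift in sorted(profile):
        if profile[shift] > best_r:
            best_r = profile[shift]
            best_shift = shift
    return FragmentEstimate(
        length=best_shift, profile=profile, low_confidence=bool(best_r < 0.05)
    )


def coverage(
    library: TagLibrary,
    fragment_length: int,
    chrom_lengths: Dict[str, int] | None = None,
) -> Dict[str, np.ndarray]:
    """Fragment-extended per-base coverage.

    Each tag is extended ``fragment_length`` bp 3'-ward from its 5' position:
    a plus tag at x covers [x, x+F), a minus tag at x covers [x-F+1, x+1).
    Extensions running off the chromosome start are clipped.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    out: Dict[str, np.ndarray] = {}
    for chrom in library.chroms():
        plus, minus = library.on(chrom, "+"), library.on(chrom, "-")
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            hi = 0
            if plus.size:
                hi = max(hi, int(plus[-1]) + fragment_length)
            if minus.size:
                hi = max(hi, int(minus[-1]) + 1)
            length = hi
        diff = np.zeros(length + 1, dtype=np.int64)
        if plus.size:
            starts = np.clip(plus, 0, length)
            ends = np.clip(plus + fragment_length, 0, length)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        if minus.size:
            starts = np.clip(minus - fragment_length + 1, 0, length)
            ends = np.clip(minus + 1, 0, length)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        out[chrom] = np.cumsum(diff[:-1])
    return out


def write_tags_bed(library: TagLibrary, path: str | Path, read_length: int = 50) -> None:
    """Write tags as BED6; minus-strand intervals end at the 5' position + 1."""
    with open(path, "w") as handle:
        for i, (chrom, pos, strand) in enumerate(library.iter_records()):
            if strand == "+":
                start, end = pos, pos + read_length
            else:
                start, end = max(0, pos + 1 - read_length), pos + 1
            handle.write(f"{chrom}\t{start}\t{end}\ttag_{i}\t0\t{strand}\n")
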