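"""Peak calling against an input control.

Binding regions are accepted only if they satisfy, jointly:

* >= 4-fold enrichment of ChIP tags over the input-derived expectation,
* >= 4-fold enrichment over the local (10 kb) ChIP background,
* Poisson upper-tail P <= 1e-4 on the window tag count, and
* empirical FDR <= 0.001, estimated by re-running the identical
  candidate/score procedure on uniformly randomized tag placements.

Candidate windows have fixed width (the estimated fragment length), slide at
half-width steps, and are greedily thinned to non-overlapping centers in
order of descending tag count.  The *peak value* of an accepted region is its
tag count normalized to 10 million total mapped tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .tags import TagLibrary, coverage


@dataclass
class PeakCallParams:
    """Acceptance thresholds and geometry for peak calling."""

    fold_over_input: float = 4.0
    poisson_p: float = 1e-4
    fdr: float = 0.001
    fold_over_local: float = 4.0
    local_window: int = 10_000
    peak_size: int | None = None  # default: the fragment-length estimate
    n_randomizations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fold_over_input, self.poisson_p, self.fold_over_local) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr threshold must be in (0, 1]")
        if self.peak_size is not None and self.peak_size <= 0:
            raise ValueError("peak_size must be positive")
        if self.local_window <= 0:
            raise ValueError("local_window must be positive")


@dataclass
class Peak:
    """An accepted binding region (0-based, half-open interval)."""

    chrom: str
    start: int
    end: int
    summit: int
    tag_count: int
    peak_value: float
    fold_input: float
    fold_local: float
    p_poisson: float
    fdr: float

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ScoredWindow:
    chrom: str
    start: int
    end: int
    tag_count: int
    fold_input: float = np.nan
    fold_local: float = np.nan
    p_poisson: float = np.nan
    fdr: float = np.nan


@dataclass
class PeakCallResult:
    """Accepted peaks plus the filter-cascade bookkeeping.

    The cascade counts mirror a read-mapping summary table: windows passing
    the FDR gate, those additionally differential over input, and the final
    peak count after local-background filtering.
    """

    peaks: List[Peak]
    n_candidates: int = 0
    n_pass_fdr: int = 0
    n_differential: int = 0
    peak_size: int = 0
    windows: List[ScoredWindow] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.peaks)


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam), computed via the survival function."""
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def candidate_windows(chip: TagLibrary, peak_size: int) -> List[ScoredWindow]:
    """Sliding fixed-width windows thinned to non-overlapping centers.

    Windows of width ``peak_size`` at ``peak_size // 2`` steps are counted,
    then retained greedily by descending tag count subject to a minimum
    center separation of ``peak_size``; count ties break leftmost.
    """
    if peak_size <= 0:
        raise ValueError("peak_size must be positive")
    step = max(1, peak_size // 2)
    rows: List[Tuple[int, str, int]] = []  # (-count, chrom, start)
    for chrom in chip.chroms():
        pos = chip.merged(chrom)
        if pos.size == 0:
            continue
        starts = np.arange(0, int(pos[-1]) + 1, step)
        counts = np.searchsorted(pos, starts + peak_size, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        for start, count in zip(starts[counts > 0], counts[counts > 0]):
            rows.append((-int(count), chrom, int(start)))
    rows.sort()

    import bisect

    selected_centers: Dict[str, list] = {}
    out: List[ScoredWindow] = []
    for neg_count, chrom, start in rows:
        center = start + peak_size // 2
        centers = selected_centers.setdefault(chrom, [])
        i = bisect.bisect_left(centers, center)
        if i > 0 and center - centers[i - 1] < peak_size:
            continue
        if i < len(centers) and centers[i] - center < peak_size:
            continue
        centers.insert(i, center)
        out.append(ScoredWindow(chrom, start, start + peak_size, -neg_count))
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def _count_in(pos: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left"))


def score_windows(
    windows: Sequence[ScoredWindow],
    chip: TagLibrary,
    input_lib: TagLibrary,
    genome_size: int,
    params: PeakCallParams,
    peak_size: int,
) -> None:
    """Score windows in place with fold enrichments and Poisson P.

    The input-derived expectation is the library-size-scaled input count,
    floored at the uniform genome-wide rate (so input deserts cannot produce
    infinite folds); the local expectation is the ChIP tag density in
    ``local_window`` around (excluding) the window.  The Poisson lambda is
    the larger of the two expectations, so both the input comparison and the
    local background gate the P value.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    chip_total = chip.total_tags
    input_total = input_lib.total_tags
    if chip_total == 0 or input_total == 0:
        raise ValueError("both libraries must contain tags")
    floor = chip_total * peak_size / genome_size
    local_len = max(params.local_window - peak_size, 1)
    chip_pos = {c: chip.merged(c) for c in chip.chroms()}
    input_pos = {c: input_lib.merged(c) for c in input_lib.chroms()}
    empty = np.empty(0, dtype=np.int64)
    for w in windows:
        cpos = chip_pos.get(w.chrom, empty)
        ipos = input_pos.get(w.chrom, empty)
        chip_count = w.tag_count
        input_count = _count_in(ipos, w.start, w.end)
        expected_input = max(input_count * chip_total / input_total, floor)
        w.fold_input = chip_count / expected_input
        center = w.start + peak_size // 2
        half = params.local_window // 2
        big = _count_in(cpos, center - half, center + half)
        local_count = max(big - chip_count, 0)
        expected_local = max(local_count / local_len * peak_size, floor)
        w.fold_local = chip_count / expected_local
        lam = max(expected_input, expected_local)
        w.p_poisson = poisson_upper_tail(chip_count, lam)


def _randomized_library(
    chip: TagLibrary, chrom_lengths: Dict[str, int], rng: np.random.Generator
) -> TagLibrary:
    """Uniform redraw of the ChIP tags, preserving per-chromosome counts."""
    positions: Dict[Tuple[str, str], np.ndarray] = {}
    for chrom in chip.chroms():
        n = chip.merged(chrom).size
        if n == 0:
            continue
        length = chrom_lengths[chrom]
        pos = rng.integers(0, length, size=n)
        n_plus = int(rng.binomial(n, 0.5))
        positions[(chrom, "+")] = np.sort(pos[:n_plus])
        positions[(chrom, "-")] = np.sort(pos[n_plus:])
    return TagLibrary(positions=positions, name=chip.name + "_randomized")


def empirical_fdr(
    windows: Sequence[ScoredWindow],
    chip: TagLibrary,
    input_lib: TagLibrary,
    chrom_lengths: Dict[str, int],
    params: PeakCallParams,
    peak_size: int,
    rng: np.random.Generator | None = None,
) -> None:
    """Annotate scored windows with an empirical FDR, in place.

    The identical candidate/score procedure is run on ChIP tags redrawn
    uniformly per chromosome; for an observed window with P value p, the FDR
    is the mean number of randomized windows at p' <= p that also pass both
    fold thresholds, divided by the number of observed windows at p' <= p.
    A cumulative minimum enforces monotone non-increase with decreasing p.
    """
    if params.n_randomizations <= 0:
        raise ValueError("n_randomizations must be >= 1")
    if not windows:
        return
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genome_size = sum(chrom_lengths.values())
    rand_p: List[float] = []
    for _ in range(params.n_randomizations):
        rand_lib = _randomized_library(chip, chrom_lengths, rng)
        rand_windows = candidate_windows(rand_lib, peak_size)
        score_windows(rand_windows, rand_lib, input_lib, genome_size, params, peak_size)
        rand_p.extend(
            w.p_poisson
            for w in rand_windows
            if w.fold_input >= params.fold_over_input and w.fold_local >= params.fold_over_local
        )
    rand_p_arr = np.sort(np.asarray(rand_p))

    order = np.argsort([w.p_poisson for w in windows], kind="stable")
    p_sorted = np.asarray([windows[i].p_poisson for i in order])
    # rank with ties sharing the largest rank (count of observed p' <= p)
    ranks = np.searchsorted(p_sorted, p_sorted, side="right")
    mean_rand = np.searchsorted(rand_p_arr, p_sorted, side="right") / params.n_randomizations
    fdr = np.clip(mean_rand / ranks, 0.0, 1.0)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    for i, f in zip(order, fdr):
        windows[i].fdr = float(f)


def call_peaks(
    chip: TagLibrary,
    input_lib: TagLibrary,
    chrom_lengths: Dict[str, int],
    params: PeakCallParams | None = None,
    fragment_length: int | None = None,
) -> PeakCallResult:
    """Full peak call: candidates, scoring, FDR, thresholds, summits.

    ``fragment_length`` supplies the window width when ``params.peak_size``
    is unset, and the extension used to locate the coverage-maximum summit.
    """
    params = params or PeakCallParams()
    peak_size = params.peak_size or fragment_length
    if peak_size is None:
        raise ValueError("peak_size or fragment_length must be provided")
    if chip.total_tags == 0:
        return PeakCallResult(peaks=[], peak_size=peak_size)

    genome_size = sum(chrom_lengths.values())
    windows = candidate_windows(chip, peak_size)
    score_windows(windows, chip, input_lib, genome_size, params, peak_size)
    rng = np.random.default_rng(params.seed)
    empirical_fdr(windows, chip, input_lib, chrom_lengths, params, peak_size, rng)

    pass_fdr = [w for w in windows if w.fdr <= params.fdr and w.p_poisson <= params.poisson_p]
    differential = [w for w in pass_fdr if w.fold_input >= params.fold_over_input]
    final = [w for w in differential if w.fold_local >= params.fold_over_local]

    cov = coverage(chip, fragment_length or peak_size, chrom_lengths)
    chip_total = chip.total_tags
    peaks: List[Peak] = []
    for w in final:
        track = cov.get(w.chrom)
        if track is not None and w.start < track.size:
            local = track[w.start : min(w.end, track.size)]
            summit = w.start + int(np.argmax(local))
        else:
            summit = w.start + peak_size // 2
        peak = Peak(
            chrom=w.chrom,
            start=w.start,
            end=w.end,
            summit=summit,
            tag_count=w.tag_count,
            peak_value=peak_value(w.tag_count, chip_total),
            fold_input=w.fold_input,
            fold_local=w.fold_local,
            p_poisson=w.p_poisson,
            fdr=w.fdr,
        )
        assert peak.fold_input >= params.fold_over_input
        assert peak.fold_local >= params.fold_over_local
        assert peak.p_poisson <= params.poisson_p
        assert peak.fdr <= params.fdr
        peaks.append(peak)
    return PeakCallResult(
        peaks=peaks,
        n_candidates=len(windows),
        n_pass_fdr=len(pass_fdr),
        n_differential=len(differential),
        peak_size=peak_size,
        windows=list(windows),
    )


def peak_value(tag_count: float, total_mapped: int | Sequence[int]) -> float:
    """Tag count normalized to 10 million total mapped tags.

    With multiple libraries, returns the mean of per-library normalized
    counts (``tag_count`` then being a matching sequence).
    """
    if np.ndim(total_mapped) > 0:
        totals = np.asarray(total_mapped, dtype=float)
        counts = np.asarray(tag_count, dtype=float)
        if np.any(totals <= 0):
            raise ValueError("total mapped tag counts must be positive")
        return float(np.mean(counts * 1e7 / totals))
    if total_mapped <= 0:
        raise ValueError("total mapped tag count must be positive")
    return float(tag_count * 1e7 / total_mapped)


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+ peak export (extra columns: summit, folds, P, FDR)."""
    with open(path, "w") as handle:
        for i, p in enumerate(peaks):
            handle.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{round(p.peak_value)}\t.\t"
                f"{p.summit}\t{p.fold_input:.3f}\t{p.fold_local:.3f}\t"
                f"{p.p_poisson:.3e}\t{p.fdr:.5f}\n"
            )
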