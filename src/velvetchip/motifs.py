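"""De novo motif discovery and PWM scanning.

Discovery uses a zero-or-one-occurrence-per-sequence (ZOOPS) EM over a
fixed-width position weight matrix with a 0-order background estimated from
the input sequences.  Scanning computes log-odds scores on both strands and
converts them to exact p-values via a dynamic-programming convolution of the
discretized per-column score distributions under the background.

The background composition is strand-symmetrized (A paired with T, C with
G), which makes reverse-complement scanning exactly mirror-symmetric and
lets one p-value table serve both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _BASE_TO_INT.items():
        out[arr == ord(base)] = code
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def symmetrize_background(background: np.ndarray) -> np.ndarray:
    """Average complementary base frequencies (A/T and C/G)."""
    bg = np.asarray(background, dtype=float)
    return (bg + bg[::-1]) / 2.0


def background_from_sequences(sequences: Iterable[str]) -> np.ndarray:
    """Strand-symmetrized 0-order composition of a sequence set."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return symmetrize_background(counts / counts.sum())


@dataclass
class PWM:
    """Position probability matrix with a 0-order background.

    ``probs`` is (width, 4) over A/C/G/T; every column sums to 1 and all
    entries are positive (a pseudocount is applied at construction).
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a (width, 4) matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background), shape (width, 4), in bits."""
        return np.log2(self.probs / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    def information_content(self) -> float:
        """Total information in bits relative to the background."""
        return float(np.sum(self.probs * np.log2(self.probs / self.background)))

    @classmethod
    def from_sites(
        cls,
        sites: Sequence[str],
        background: Optional[np.ndarray] = None,
        pseudocount: float = 0.01,
    ) -> "PWM":
        """Build a PWM from aligned equal-length site sequences."""
        if not sites:
            raise ValueError("need at least one site")
        width = len(sites[0])
        counts = np.full((width, 4), pseudocount, dtype=float)
        for site in sites:
            if len(site) != width:
                raise ValueError("all sites must have equal length")
            enc = encode(site)
            for i, code in enumerate(enc):
                if code < 4:
                    counts[i, code] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = background_from_sequences(sites)
        else:
            background = symmetrize_background(background)
        return cls(probs=probs, background=background, pseudocount=pseudocount)


@dataclass
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    log_odds_score: float  # bits
    p_value: float


class ScoreDistribution:
    """Exact null distribution of the discretized PWM log-odds score.

    Scores are discretized at ``resolution`` bits per column and the
    distributions of the per-column integer scores under the background are
    convolved; ``pvalue`` returns P(score >= s) for a random background
    word.
    """

    def __init__(self, pwm: PWM, resolution: float = 0.01):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.pwm = pwm
        self.resolution = resolution
        self.int_scores = np.rint(pwm.log_odds() / resolution).astype(np.int64)

        dist = np.array([1.0])
        offset = 0  # score value of dist[0]
        for i in range(pwm.width):
            col = self.int_scores[i]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(dist.size + (hi - lo), dtype=float)
            for b in range(4):
                shift = int(col[b]) - lo
                new[shift : shift + dist.size] += dist * pwm.background[b]
            dist = new
            offset += lo
        self.min_score = offset
        self.max_score = offset + dist.size - 1
        # survival[s - min_score] = P(score >= s)
        self.survival = np.cumsum(dist[::-1])[::-1]

    def int_score(self, word: np.ndarray) -> int:
        """Discretized score of an encoded width-length word."""
        return int(self.int_scores[np.arange(self.pwm.width), word].sum())

    def pvalue_int(self, s: int) -> float:
        if s <= self.min_score:
            return 1.0
        if s > self.max_score:
            return float(self.survival[-1])
        return float(self.survival[s - self.min_score])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / self.resolution)))

    def score_threshold(self, p: float) -> int:
        """Smallest integer score with pvalue <= p (max_score + 1 if none)."""
        idx = np.searchsorted(-self.survival, -p, side="left")
        return int(self.min_score + idx)


def _window_int_scores(
    enc: np.ndarray, int_scores: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Integer scores of every window plus validity mask (no N)."""
    w = int_scores.shape[0]
    m = enc.size - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows < 4).all(axis=1)
    safe = np.where(windows < 4, windows, 0)
    scores = int_scores[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def scan_sequence(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 0.001,
    dist: Optional[ScoreDistribution] = None,
    sequence_id: str = "",
) -> List[MotifHit]:
    """Report all motif hits with p <= ``p_threshold`` on both strands.

    Windows containing N are skipped; overlapping hits are all reported.
    """
    if dist is None:
        dist = ScoreDistribution(pwm)
    enc = encode(sequence)
    w = pwm.width
    if enc.size < w:
        return []
    rc_int = dist.int_scores[::-1, ::-1]
    hits: List[MotifHit] = []
    for strand, table in (("+", dist.int_scores), ("-", rc_int)):
        scores, valid = _window_int_scores(enc, table)
        for j in np.nonzero(valid)[0]:
            p = dist.pvalue_int(int(scores[j]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        offset=int(j),
                        strand=strand,
                        log_odds_score=float(scores[j] * dist.resolution),
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def motif_fraction(
    sequences: Sequence[str],
    pwm: PWM,
    p_threshold: float = 0.001,
) -> Tuple[float, List[bool]]:
    """Percentage of sequences with >= 1 motif hit, rounded to one decimal."""
    if not sequences:
        raise ValueError("need at least one sequence")
    dist = ScoreDistribution(pwm)
    flags = [
        bool(scan_sequence(seq, pwm, p_threshold, dist=dist)) for seq in sequences
    ]
    percent = round(100.0 * sum(flags) / len(flags), 1)
    return percent, flags


def extract_peak_sequences(
    peaks: Sequence, genome: Dict[str, str], flank: int = 0
) -> List[str]:
    """Uppercased genomic sequence of each peak interval (+- ``flank``).

    ``peaks`` may be any objects with chrom/start/end attributes or
    (chrom, start, end) tuples.  Intervals beyond chromosome bounds are
    clipped with a warning; a zero-length chromosome is an error.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for p in peaks:
        chrom, start, end = (
            (p[0], p[1], p[2]) if isinstance(p, tuple) else (p.chrom, p.start, p.end)
        )
        seq = str(genome[chrom])
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom} has zero length")
        lo, hi = start - flank, end + flank
        if lo < 0 or hi > len(seq):
            warnings.warn(
                f"peak {chrom}:{start}-{end} (flank {flank}) clipped to chromosome bounds"
            )
        out.append(seq[max(0, lo) : min(len(seq), hi)].upper())
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------


@dataclass
class ZoopsResult:
    pwm: PWM
    gamma: float  # prior probability that a sequence carries a site
    log_likelihood: float
    ll_trace: List[float]
    site_posteriors: List[float]  # per-sequence total site probability
    best_sites: List[Optional[Tuple[int, str]]]  # MAP (offset, strand) or None
    start_kmer: str = ""


GAMMA_FLOOR = 0.01


def _enriched_kmer_starts(
    seqs_enc: List[np.ndarray], width: int, background: np.ndarray, n_starts: int
) -> List[str]:
    """Most background-enriched k-mers (both strands), rc-deduplicated."""
    counts: Dict[bytes, int] = {}
    n_windows = 0
    for enc in seqs_enc:
        if enc.size < width:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, width)
        valid = (windows < 4).all(axis=1)
        n_windows += int(valid.sum())
        for win in windows[valid]:
            key = win.tobytes()
            counts[key] = counts.get(key, 0) + 1
            rc = (3 - win[::-1]).astype(np.int8).tobytes()
            counts[rc] = counts.get(rc, 0) + 1
    log_bg = np.log(background)
    scored = []
    for key, count in counts.items():
        word = np.frombuffer(key, dtype=np.int8)
        expected = 2 * n_windows * float(np.exp(log_bg[word].sum()))
        ratio = (count + 1.0) / (expected + 1.0)
        scored.append((-ratio, key))
    scored.sort()
    picked: List[str] = []
    seen: set = set()
    for _, key in scored:
        if key in seen:
            continue
        word = np.frombuffer(key, dtype=np.int8)
        seen.add(key)
        seen.add((3 - word[::-1]).astype(np.int8).tobytes())
        picked.append("".join(BASES[int(b)] for b in word))
        if len(picked) >= n_starts:
            break
    return picked


def _pwm_from_seed(kmer: str, background: np.ndarray, match_prob: float = 0.7) -> np.ndarray:
    del background  # seeds are sharp regardless of composition
    probs = np.full((len(kmer), 4), (1.0 - match_prob) / 3.0)
    for i, base in enumerate(kmer):
        probs[i, _BASE_TO_INT[base]] = match_prob
    return probs / probs.sum(axis=1, keepdims=True)


def zoops_em(
    sequences: Sequence[str],
    width: int = 10,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    pseudocount: float = 0.01,
) -> ZoopsResult:
    """ZOOPS EM motif discovery over both strands.

    Each sequence carries at most one site.  The E-step computes, per
    sequence, the posterior over {no site} and every (offset, strand) under
    the current PWM, 0-order background and site prior gamma; the M-step
    re-estimates the PWM (pseudocount ``pseudocount``) and gamma.  EM is
    restarted from the ``n_starts`` most background-enriched ``width``-mers
    and the start with the highest final log likelihood wins.  Deterministic
    under ``seed``.
    """
    del seed  # retained for interface stability; the procedure is deterministic
    usable = [s for s in sequences if len(s) >= width]
    if len(usable) < 10:
        raise ValueError("need at least 10 sequences of length >= width")
    seqs_enc = [encode(s) for s in usable]
    background = background_from_sequences(usable)
    log_bg = np.log(np.maximum(background, 1e-12))

    # Per-sequence constants: window index matrices and background log-lik.
    windows_list, valid_list, bg_const = [], [], []
    for enc in seqs_enc:
        windows = np.lib.stride_tricks.sliding_window_view(enc, width)
        valid = (windows < 4).all(axis=1)
        windows_list.append(np.where(windows < 4, windows, 0))
        valid_list.append(valid)
        bg_const.append(float(log_bg[enc[enc < 4]].sum()))

    starts = _enriched_kmer_starts(seqs_enc, width, background, n_starts)
    if not starts:
        raise ValueError("no usable windows for seeding")

    best: Optional[ZoopsResult] = None
    for kmer in starts:
        result = _run_em_from(
            kmer, windows_list, valid_list, bg_const, background, log_bg,
            width, max_iter, tol, pseudocount,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def _run_em_from(
    kmer: str,
    windows_list: List[np.ndarray],
    valid_list: List[np.ndarray],
    bg_const: List[float],
    background: np.ndarray,
    log_bg: np.ndarray,
    width: int,
    max_iter: int,
    tol: float,
    pseudocount: float,
) -> ZoopsResult:
    probs = _pwm_from_seed(kmer, background)
    gamma = 0.5
    col_idx = np.arange(width)[None, :]
    ll_trace: List[float] = []
    n_seqs = len(windows_list)

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_ratio = np.log(probs) - log_bg[None, :]  # (width, 4)
        log_ratio_rc = log_ratio[::-1, ::-1]
        counts = np.full((width, 4), pseudocount)
        site_post_total = np.zeros(n_seqs)
        total_ll = 0.0
        map_sites: List[Optional[Tuple[int, str]]] = []
        for s in range(n_seqs):
            W, valid = windows_list[s], valid_list[s]
            m = W.shape[0]
            llr_plus = np.where(valid, log_ratio[col_idx, W].sum(axis=1), -np.inf)
            llr_minus = np.where(valid, log_ratio_rc[col_idx, W].sum(axis=1), -np.inf)
            n_sites = 2 * int(valid.sum())
            if n_sites == 0:
                total_ll += np.log(1 - gamma) + bg_const[s]
                site_post_total[s] = 0.0
                map_sites.append(None)
                continue
            log_site_prior = np.log(gamma / n_sites)
            logw = np.concatenate(
                [[np.log(1 - gamma)], log_site_prior + llr_plus, log_site_prior + llr_minus]
            )
            mx = logw.max()
            w_exp = np.exp(logw - mx)
            z = w_exp.sum()
            post = w_exp / z
            total_ll += mx + np.log(z) + bg_const[s]
            post_plus, post_minus = post[1 : 1 + m], post[1 + m :]
            site_post_total[s] = float(post_plus.sum() + post_minus.sum())
            np.add.at(counts, (np.broadcast_to(col_idx, W.shape), W), post_plus[:, None])
            rc_W = 3 - W[:, ::-1]
            np.add.at(counts, (np.broadcast_to(col_idx, W.shape), rc_W), post_minus[:, None])
            k = int(np.argmax(post))
            if post[k] <= post[0] or k == 0:
                map_sites.append(None)
            elif k <= m:
                map_sites.append((k - 1, "+"))
            else:
                map_sites.append((k - 1 - m, "-"))
        probs = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(site_post_total.mean(), GAMMA_FLOOR, 1 - 1e-6))
        ll_trace.append(total_ll)
        if np.isfinite(prev_ll) and abs(total_ll - prev_ll) < tol * max(1.0, abs(total_ll)):
            break
        prev_ll = total_ll

    pwm = PWM(probs=probs, background=background, pseudocount=pseudocount)
    return ZoopsResult(
        pwm=pwm,
        gamma=gamma,
        log_likelihood=ll_trace[-1],
        ll_trace=ll_trace,
        site_posteriors=list(site_post_total),
        best_sites=map_sites,
        start_kmer=kmer,
    )


def write_meme(pwm: PWM, path, name: str = "MOTIF_1") -> None:
    """Write the PWM in MEME minimal motif format."""
    bg = pwm.background
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        handle.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        handle.write(f"MOTIF {name} {pwm.consensus}\n")
        handle.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 0 E= 0\n"
        )
        for row in pwm.probs:
            handle.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
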