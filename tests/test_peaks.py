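"""Peak calling: Poisson testing, window scoring, FDR, recovery, invariants."""

import numpy as np
import pytest

import velvetchip as vc
from oracles import poisson_tail_decimal
from velvetchip.peaks import (
    PeakCallParams,
    call_peaks,
    candidate_windows,
    peak_value,
    poisson_upper_tail,
    score_windows,
)
from velvetchip.simulate import GroundTruth, SyntheticConfig, generate_genome, simulate_tags
from velvetchip.tags import TagLibrary, clonal_filter


class TestPoissonUpperTail:
    def test_boundary_cases(self):
        assert poisson_upper_tail(0, 5.0) == 1.0
        assert poisson_upper_tail(1, 0.0) == 0.0
        assert poisson_upper_tail(0, 0.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(1, -1.0)

    def test_against_decimal_summation_oracle(self):
        # spot value quoted as ~4.65e-5
        assert poisson_upper_tail(10, 2.0) == pytest.approx(
            poisson_tail_decimal(10, 2.0), rel=1e-12
        )
        assert poisson_upper_tail(10, 2.0) == pytest.approx(4.65e-5, rel=2e-3)
        for k, lam in [(1, 0.5), (3, 3.0), (40, 5.0), (100, 50.0), (7, 20.0)]:
            assert poisson_upper_tail(k, lam) == pytest.approx(
                poisson_tail_decimal(k, lam), rel=1e-10
            )


class TestCandidateWindows:
    def _lib(self, positions):
        return TagLibrary(positions={("chr1", "+"): np.sort(np.asarray(positions))})

    def test_single_cluster_one_candidate(self):
        lib = self._lib(np.full(100, 1000))
        wins = candidate_windows(lib, 200)
        covering = [w for w in wins if w.start <= 1000 < w.end]
        assert len(covering) == 1
        assert covering[0].tag_count == 100

    def test_separated_clusters_two_candidates(self):
        lib = self._lib(np.concatenate([np.full(50, 1000), np.full(50, 2000)]))
        wins = candidate_windows(lib, 200)
        assert len([w for w in wins if w.tag_count == 50]) == 2

    def test_count_tie_keeps_leftmost(self):
        # one tag at 50: windows [0,200) and [100,300) both hold it
        lib = self._lib([150])
        wins = candidate_windows(lib, 200)
        assert len(wins) == 1
        assert wins[0].start == 0

    def test_centers_respect_min_separation(self):
        lib = self._lib(np.arange(0, 5000, 7))
        wins = candidate_windows(lib, 200)
        centers = sorted(w.start + 100 for w in wins)
        assert all(b - a >= 200 for a, b in zip(centers, centers[1:]))


class TestScoreWindows:
    def test_identical_libraries_fold_near_one(self, rng):
        positions = {
            ("chr1", "+"): np.sort(rng.integers(0, 100_000, size=5000)),
        }
        lib = TagLibrary(positions=positions)
        wins = candidate_windows(lib, 200)
        score_windows(wins, lib, lib, 100_000, PeakCallParams(), 200)
        folds = [w.fold_input for w in wins if w.tag_count >= 5]
        assert np.median(folds) == pytest.approx(1.0, abs=0.3)

    def test_fold_and_pvalue_arithmetic(self):
        """40 ChIP tags against an input-derived expectation of 5 is 8-fold."""
        # Equal library sizes; the input holds 5 tags in the scored window.
        backbone = np.arange(10_000, 100_000, 100)
        chip = TagLibrary(
            positions={("chr1", "+"): np.sort(np.concatenate([np.full(40, 1000), backbone]))}
        )
        input_lib = TagLibrary(
            positions={("chr1", "+"): np.sort(np.concatenate(
                [np.full(5, 1000), np.full(35, 5000), backbone]
            ))}
        )
        assert chip.total_tags == input_lib.total_tags
        wins = [w for w in candidate_windows(chip, 200) if w.start <= 1000 < w.end]
        score_windows(wins, chip, input_lib, 100_000, PeakCallParams(), 200)
        w = wins[0]
        assert w.tag_count == 40
        assert w.fold_input == pytest.approx(8.0, rel=1e-9)
        # the local expectation around an isolated cluster is the floor here,
        # so the Poisson lambda is the input expectation of 5
        assert w.p_poisson == pytest.approx(poisson_tail_decimal(40, 5.0), rel=1e-9)
        assert w.p_poisson == pytest.approx(1.9e-24, rel=0.1)


class TestEmpiricalFdr:
    def test_fdr_monotone_in_pvalue(self, default_peaks):
        wins = default_peaks["result"].windows
        ordered = sorted(wins, key=lambda w: w.p_poisson)
        fdrs = [w.fdr for w in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_zero_randomizations_rejected(self):
        from velvetchip.peaks import ScoredWindow, empirical_fdr

        params = PeakCallParams()
        params.n_randomizations = 0
        lib = TagLibrary(positions={("chr1", "+"): np.arange(10)})
        with pytest.raises(ValueError):
            empirical_fdr(
                [ScoredWindow("chr1", 0, 200, 5)], lib, lib, {"chr1": 1000}, params, 200
            )


class TestCallPeaks:
    def test_planted_sites_recovered(self):
        cfg = SyntheticConfig(
            genome_length=200_000, n_genes=60, n_sites=20, n_chip_tags=20_000,
            n_input_tags=20_000, site_enrichment=300.0, min_site_distance=2000,
            seed=11, dup_rate=0.0,
        )
        genome, genes = generate_genome(cfg)
        from velvetchip.simulate import plant_sites_and_motifs

        truth = plant_sites_and_motifs(genome, genes, cfg)
        chip1, _, input_lib = simulate_tags(truth, cfg)
        result = call_peaks(
            clonal_filter(chip1), clonal_filter(input_lib), cfg.chrom_lengths,
            PeakCallParams(seed=11), cfg.fragment_length,
        )
        sites = truth.all_sites()
        ps = result.peak_size
        recovered = sum(
            any(p.chrom == c and abs(p.summit - pos) <= ps for p in result.peaks)
            for c, pos in sites
        )
        stray = [
            p for p in result.peaks
            if not any(p.chrom == c and abs(p.summit - pos) <= ps for c, pos in sites)
        ]
        assert recovered >= 19
        assert not stray

    def test_chip_equals_input_yields_no_peaks(self, rng):
        positions = {("chr1", "+"): np.sort(rng.integers(0, 100_000, size=5000))}
        lib = TagLibrary(positions=positions)
        result = call_peaks(lib, lib, {"chr1": 100_000}, PeakCallParams(seed=0), 200)
        assert result.peaks == []

    def test_empty_chip_yields_no_peaks(self):
        empty = TagLibrary(positions={})
        other = TagLibrary(positions={("chr1", "+"): np.arange(100)})
        assert call_peaks(empty, other, {"chr1": 1000}, None, 200).peaks == []

    def test_every_peak_satisfies_all_thresholds(self, default_peaks):
        params = PeakCallParams()
        for p in default_peaks["result"].peaks:
            assert p.fold_input >= params.fold_over_input
            assert p.fold_local >= params.fold_over_local
            assert p.p_poisson <= params.poisson_p
            assert p.fdr <= params.fdr
            assert p.start <= p.summit < p.end

    def test_cascade_counts_monotone(self, default_peaks):
        res = default_peaks["result"]
        assert res.n_total <= res.n_differential <= res.n_pass_fdr <= res.n_candidates

    def test_raising_fold_threshold_shrinks_peak_set(self, default_peaks):
        chip, input_lib = default_peaks["chip"], default_peaks["input"]
        lengths = {"chr1": 500_000}
        loose = call_peaks(chip, input_lib, lengths, PeakCallParams(seed=1), 200)
        strict = call_peaks(
            chip, input_lib, lengths, PeakCallParams(fold_over_input=8.0, seed=1), 200
        )
        loose_ids = {(p.chrom, p.start) for p in loose.peaks}
        strict_ids = {(p.chrom, p.start) for p in strict.peaks}
        assert strict_ids <= loose_ids

    def test_fold_ratios_invariant_to_library_doubling(self, rng):
        positions = np.sort(rng.integers(0, 50_000, size=2000))
        chip = TagLibrary(positions={("chr1", "+"): positions})
        chip2 = TagLibrary(positions={("chr1", "+"): np.sort(np.tile(positions, 2))})
        input_lib = TagLibrary(
            positions={("chr1", "+"): np.sort(rng.integers(0, 50_000, size=2000))}
        )
        wins1 = candidate_windows(chip, 200)
        score_windows(wins1, chip, input_lib, 50_000, PeakCallParams(), 200)
        wins2 = candidate_windows(chip2, 200)
        score_windows(wins2, chip2, input_lib, 50_000, PeakCallParams(), 200)
        folds1 = {(w.chrom, w.start): w.fold_input for w in wins1}
        folds2 = {(w.chrom, w.start): w.fold_input for w in wins2}
        shared = set(folds1) & set(folds2)
        assert shared
        for key in shared:
            assert folds1[key] == pytest.approx(folds2[key], rel=1e-9)


class TestPeakValue:
    def test_normalization_to_ten_million(self):
        assert peak_value(100, 10_000_000) == 100.0
        assert peak_value(50, 20_000_000) == 25.0
        assert peak_value(0, 10_000_000) == 0.0

    def test_multiple_libraries_averaged(self):
        assert peak_value([100, 50], [10_000_000, 20_000_000]) == pytest.approx(62.5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            peak_value(10, 0)
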