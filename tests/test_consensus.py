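"""Replicate intersection, orientation classification, targets, overlap."""

import numpy as np
import pandas as pd
import pytest

from oracles import max_bipartite_matching_size
from velvetchip.consensus import (
    ConsensusPeak,
    GeneIndex,
    GeneModel,
    PeakClass,
    assign_target_genes,
    classification_summary,
    classify_peak,
    classify_peaks,
    expression_overlap,
    intersect_replicates,
)


def peak(summit, chrom="chr1", value=None, width=200):
    return ConsensusPeak(
        chrom=chrom, start=summit - width // 2, end=summit + width // 2,
        summit=summit, peak_value=value,
    )


class TestIntersectReplicates:
    def test_identical_lists_fully_matched(self):
        peaks = [peak(s) for s in (1000, 5000, 9000)]
        merged = intersect_replicates(peaks, peaks)
        assert len(merged) == len(peaks)
        assert [c.summit for c in merged] == [1000, 5000, 9000]

    def test_hundred_nt_rule_inclusive(self):
        assert len(intersect_replicates([peak(1000)], [peak(1100)])) == 1
        assert len(intersect_replicates([peak(1000)], [peak(1101)])) == 0

    def test_symmetric_in_arguments(self, rng):
        a = [peak(int(s)) for s in np.sort(rng.integers(0, 100_000, size=40))]
        b = [peak(int(s)) for s in np.sort(rng.integers(0, 100_000, size=40))]
        ab = {(c.members[0].summit, c.members[1].summit) for c in intersect_replicates(a, b)}
        ba = {(c.members[1].summit, c.members[0].summit) for c in intersect_replicates(b, a)}
        assert ab == ba

    def test_consensus_count_bounded_by_smaller_list(self, rng):
        a = [peak(int(s)) for s in np.sort(rng.integers(0, 50_000, size=30))]
        b = [peak(int(s)) for s in np.sort(rng.integers(0, 50_000, size=10))]
        merged = intersect_replicates(a, b)
        assert len(merged) <= 10

    def test_small_perturbations_all_match(self, rng):
        summits = np.arange(1000, 41_000, 1000)
        a = [peak(int(s)) for s in summits]
        b = [peak(int(s + rng.integers(-50, 51))) for s in summits]
        assert len(intersect_replicates(a, b)) == len(a)

    def test_greedy_close_to_optimal_matching(self, rng):
        """Greedy nearest-summit matching nearly always equals the optimum."""
        agree = 0
        trials = 20
        for _ in range(trials):
            # replicate-like lists: separated summits, jittered counterpart,
            # with some peaks private to each replicate
            base = np.cumsum(rng.integers(200, 600, size=30))
            keep_a = rng.random(30) < 0.85
            keep_b = rng.random(30) < 0.85
            sa = sorted(int(x) for x in base[keep_a])
            sb = sorted(int(x + rng.integers(-150, 151)) for x in base[keep_b])
            greedy = len(intersect_replicates([peak(s) for s in sa], [peak(s) for s in sb]))
            optimal = max_bipartite_matching_size(sa, sb, 100)
            assert greedy <= optimal
            agree += greedy == optimal
        assert agree >= 0.95 * trials

    def test_consensus_interval_is_union_and_summit_mean(self):
        merged = intersect_replicates([peak(1000, value=10.0)], [peak(1060, value=20.0)])
        c = merged[0]
        assert (c.start, c.end) == (900, 1160)
        assert c.summit == 1030
        assert c.peak_value == pytest.approx(15.0)


GENES_CASES = {
    # peak at 5000; left gene [1000,2000), right gene [8000,9000)
    ("+", "+"): PeakClass.FIVE_PRIME_ONE,  # L 3' faces, R 5' faces
    ("-", "-"): PeakClass.FIVE_PRIME_ONE,  # L 5' faces, R 3' faces
    ("-", "+"): PeakClass.DIVERGENT_FIVE_PRIME_BOTH,
    ("+", "-"): PeakClass.THREE_PRIME_BOTH,
}


class TestClassifyPeak:
    @pytest.mark.parametrize("strands,expected", GENES_CASES.items())
    def test_flanking_orientation(self, strands, expected):
        left, right = strands
        genes = [
            GeneModel("gL", "chr1", 1000, 2000, left),
            GeneModel("gR", "chr1", 8000, 9000, right),
        ]
        cp = classify_peak(peak(5000), GeneIndex(genes))
        assert cp.peak_class is expected
        n_expected_targets = {
            PeakClass.FIVE_PRIME_ONE: 1,
            PeakClass.DIVERGENT_FIVE_PRIME_BOTH: 2,
            PeakClass.THREE_PRIME_BOTH: 0,
        }[expected]
        assert len(cp.five_prime_genes) == n_expected_targets

    def test_summit_inside_gene_is_intragenic(self):
        genes = [GeneModel("g", "chr1", 4000, 6000, "+")]
        cp = classify_peak(peak(5000), GeneIndex(genes))
        assert cp.peak_class is PeakClass.IN_ORF
        assert cp.five_prime_genes == ()

    def test_missing_flank_is_unflanked(self):
        genes = [GeneModel("g", "chr1", 8000, 9000, "+")]  # 5' faces the peak
        cp = classify_peak(peak(5000), GeneIndex(genes))
        assert cp.peak_class is PeakClass.UNFLANKED
        assert [g.gene_id for g in cp.five_prime_genes] == ["g"]

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            classify_peak(peak(5000), GeneIndex([]))


class TestAssignTargets:
    def test_divergent_contributes_two_singles_one_threeprime_none(self):
        genes = [
            GeneModel("a", "chr1", 1000, 2000, "-"),
            GeneModel("b", "chr1", 8000, 9000, "+"),
            GeneModel("c", "chr1", 21_000, 22_000, "+"),
            GeneModel("d", "chr1", 28_000, 29_000, "-"),
        ]
        classified = classify_peaks([peak(5000), peak(25_000)], genes)
        targets = assign_target_genes(classified)
        assert sorted(t.gene_id for t in targets) == ["a", "b"]

    def test_duplicate_gene_keeps_stronger_peak(self):
        genes = [
            GeneModel("gL", "chr1", 1000, 2000, "+"),
            GeneModel("gR", "chr1", 8000, 9000, "+"),
        ]
        classified = classify_peaks(
            [peak(5000, value=3.0), peak(6000, value=30.0)], genes
        )
        targets = assign_target_genes(classified)
        assert len(targets) == 1
        assert targets[0].peak_value == 30.0

    def test_target_count_identity_on_distinct_flanks(self, rng):
        """|targets| = |five_prime_one| + 2 |divergent| when flanks are distinct."""
        genes, peaks = [], []
        pos, gid = 0, 0
        counts = {PeakClass.FIVE_PRIME_ONE: 0, PeakClass.DIVERGENT_FIVE_PRIME_BOTH: 0}
        for _ in range(30):
            kind = rng.choice(["five", "div", "three"])
            left, right = {"five": "++", "div": "-+", "three": "+-"}[kind]
            genes.append(GeneModel(f"g{gid}", "chr1", pos, pos + 1000, left)); gid += 1
            peaks.append(peak(pos + 2000))
            genes.append(GeneModel(f"g{gid}", "chr1", pos + 3000, pos + 4000, right)); gid += 1
            pos += 10_000
        classified = classify_peaks(peaks, genes)
        for cp in classified:
            if cp.peak_class in counts:
                counts[cp.peak_class] += 1
        targets = assign_target_genes(classified)
        assert len(targets) == (
            counts[PeakClass.FIVE_PRIME_ONE]
            + 2 * counts[PeakClass.DIVERGENT_FIVE_PRIME_BOTH]
        )


class TestExpressionOverlap:
    def _targets(self, ids):
        from velvetchip.consensus import TargetGene

        return [TargetGene(g, "p", "5prime_single") for g in ids]

    def test_boundary_exactly_twofold_is_dependent(self):
        table = pd.DataFrame({"log2_t1": [1.0, 0.99]}, index=["g1", "g2"])
        result = expression_overlap(self._targets(["g1", "g2"]), table)
        flags = {t.gene_id: t.dependent for t in result.targets}
        assert flags == {"g1": True, "g2": False}
        assert result.percent == 50.0

    def test_absent_genes_count_as_non_dependent(self):
        table = pd.DataFrame({"log2_t1": [2.0]}, index=["g1"])
        result = expression_overlap(self._targets(["g1", "missing"]), table)
        assert result.n_dependent == 1
        assert result.n_total == 2

    def test_threshold_must_exceed_one(self):
        table = pd.DataFrame({"log2_t1": [0.0]}, index=["g1"])
        with pytest.raises(ValueError):
            expression_overlap(self._targets(["g1"]), table, fold_threshold=1.0)

    def test_no_flagged_genes_gives_zero(self):
        table = pd.DataFrame({"log2_t1": [0.1, -0.2]}, index=["g1", "g2"])
        assert expression_overlap(self._targets(["g1", "g2"]), table).percent == 0.0


class TestClassificationSummary:
    def test_counts_partition_total(self, rng):
        genes, peaks = [], []
        pos = 0
        for i in range(40):
            left, right = rng.choice(["+", "-"], size=2)
            genes.append(GeneModel(f"l{i}", "chr1", pos, pos + 1000, left))
            genes.append(GeneModel(f"r{i}", "chr1", pos + 3000, pos + 4000, right))
            peaks.append(peak(pos + 2000))
            if i % 4 == 0:
                peaks.append(peak(pos + 500))  # intragenic
            pos += 10_000
        classified = classify_peaks(peaks, genes)
        summary = classification_summary(classified)
        assert sum(summary["counts"].values()) == summary["n_total"] == len(peaks)
        intergenic_subclasses = (
            summary["counts"]["three_prime_both"]
            + summary["counts"]["five_prime_one"]
            + summary["counts"]["divergent_five_prime_both"]
            + summary["counts"]["unflanked"]
        )
        assert intergenic_subclasses == summary["n_intergenic"]
        assert summary["n_intergenic"] + summary["n_intragenic"] == summary["n_total"]
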