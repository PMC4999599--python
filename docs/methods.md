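# Methods

This note documents the models, defaults and numerical choices behind
velvetchip, and what the synthetic-data tests do and do not demonstrate
about real data.

## Tag model and processing

A tag is the 5′-most mapped position of a read plus its strand; all
enrichment statistics are computed on tags, never on read sequences.
Coordinates are 0-based and half-open internally; GFF3 is converted at the
boundary.

**Clonal filter.** At most `max_per_position = 3` tags are kept per
(chromosome, position, strand).  The cap suppresses PCR towers while
retaining genuine pile-up at strong sites; it is deliberately small and
configurable.  The same filter is applied to ChIP and input libraries —
whether the input should also be deduplicated is a judgment call, and
applying one rule uniformly keeps the two libraries comparable.

**Fragment length.** ChIP fragments place plus-strand tags ~F/2 upstream
and minus-strand tags ~F/2 downstream of a binding site, so the +/− tag
tracks are shifted copies of each other.  The estimator bins tags at 10 bp,
shifts the minus track left by d ∈ [20, 500] bp in 10-bp steps, and takes
the Pearson-correlation argmax over the genome (ties to the smaller shift).
Resolution is therefore one bin (10 bp).  When the maximum correlation is
below 0.05 the profile is effectively flat and the estimate is flagged
low-confidence rather than suppressed.

**Coverage.** Each tag is extended F bp 3′-ward; summits are coverage
argmaxima inside peak windows.  Total coverage mass equals
(tag count) × F, which the tests assert.

## Peak calling

Candidate windows have fixed width (the fragment estimate), slide at
half-width steps, and are greedily thinned by descending tag count with a
minimum center separation of one window width; count ties keep the
leftmost window.  Fixed-width windows mirror the tag-cluster footprint of a
point-source binding factor; broad-domain calling is out of scope.

Scoring a window with k ChIP tags:

* **λ_input** = input count × N_chip/N_input, floored at the uniform rate
  N_chip × width / genome size.  The floor prevents division by zero in
  input deserts and makes fold ratios scale-invariant in library size.
* **λ_local** = ChIP tag density in a 10 kb window centered on the
  candidate (candidate excluded) × width, same floor.  This realizes local
  background filtering: a window inside a broad pile-up is not called just
  because the input is quiet there.
* Poisson P = P(X ≥ k) at λ = max(λ_input, λ_local) — the conservative
  choice; both comparisons gate the p-value.

**Empirical FDR.** The identical candidate/score procedure is run
`n_randomizations = 3` times on ChIP tags redrawn uniformly per chromosome
(seeded).  For an observed window at p, FDR(p) = mean number of randomized
windows with p′ ≤ p that also pass both fold thresholds, divided by the
number of observed windows with p′ ≤ p, clipped to [0, 1] and made
monotone by a right-to-left cumulative minimum.  Three randomizations
suffice because the null tail is effectively empty at the operating
thresholds (the calibration test runs 20 independent null simulations and
allows at most one called peak in total).

A region is a peak iff fold-over-input ≥ 4 AND fold-over-local ≥ 4 AND
P ≤ 1e−4 AND FDR ≤ 0.001; every emitted peak re-asserts all four.  The
report also carries the filter cascade (FDR-pass ≥ differential ≥ final),
mirroring the usual sequencing-summary table.  In that table the mapped
percentage is computed as mapped/total reads.

A strong site typically yields the two windows flanking its center (one
per strand cluster); both summits converge on the site center, so the
replicate consensus and all recovery statistics are unaffected.  The peak
value normalizes the *total* window tag count to 10 million mapped tags; a
per-base average would only rescale all values by the window width.

## Replicate consensus and annotation

Two peaks from different replicates are the same site when their summit
distance is ≤ 100 nt, inclusive.  Summits are used as the reference points
because they are the most stable feature of a peak; matching is greedy on
(distance, leftmost summit), which is symmetric in the replicate order and
agrees with exhaustive maximum matching in ≥ 95% of realistic instances
(tested against a bipartite-matching oracle).

Classification uses only the summit and the flanking genes' strands: no
maximum promoter distance is imposed, since any cutoff would be arbitrary
without transcript evidence.  Peaks missing a flank (contig ends) form an
explicit UNFLANKED class, counted as intergenic and still contributing a
target gene if the present flank faces the peak with its 5′ side.  Target
genes are deduplicated (a gene downstream of two peaks counts once,
keeping the stronger peak), so the target count is a gene count, not a
peak–gene-pair count.  Genes absent from the expression table are treated
as non-dependent rather than dropped, preserving the attribution
denominator; the ≥ 2-fold rule is inclusive (|log2| ≥ 1 exactly is
dependent).

## Motif model

ZOOPS EM with fixed width 10 on both strands; the background is the
0-order composition of the input sequences, strand-symmetrized
(A↔T, C↔G averaged).  Symmetrization makes one exact p-value table valid
for both strands and reverse-complement scanning exactly mirror-symmetric.
EM restarts from the 20 most background-enriched 10-mers
(reverse-complement-deduplicated), seeds each start with 0.7 match
probability, applies pseudocount 0.01 in the M-step, floors γ at 0.01, and
keeps the restart with the highest final log likelihood.  The
log-likelihood is non-decreasing across iterations (asserted in tests) and
the procedure is deterministic.

A caveat worth stating: on motif-free sequences, unconstrained
maximum-likelihood ZOOPS does not drive γ to its floor — it latches onto
the best-scoring random 10-mer family and fits it with substantial γ.
This is a known overfitting mode that MEME counters with E-value-based
model selection, which is out of scope here.  The reliable null/signal
discriminator is the learned PWM's total information content, which stays
far below that of a planted motif; the tests assert exactly that.

**Exact p-values.** Log-odds scores are discretized at 0.01 bits per
column (configurable); the null distribution of the total integer score is
the convolution of per-column distributions under the background, and
P(score ≥ s) comes from its survival function.  The DP agrees with
exhaustive 4^w enumeration for w ≤ 5 (oracle test).  A peak "contains" the
motif if any window on either strand has site-level P ≤ 0.001 — the direct
site-level reading of the threshold.  Windows containing N are skipped.

## Validation arithmetic

ChIP-PCR enrichment: (target/control)_ChIP ÷ (target/control)_input, on
abundances or on Ct values via abundance = 2^(−Ct).  Relative expression:
log2 ratio = −ΔΔCt.  Amplification efficiency is fixed at 2 (100%) and
configurable; per-amplicon efficiency estimation from standard curves is
out of scope.  Replicate Ct values are averaged on the Ct scale.

## Synthetic data: what it emulates, and what it does not

Defaults (one choice, made a priori): 1 × 500 kb chromosome, 150
non-overlapping genes of 0.6–2 kb, 50 binding sites (80% intergenic,
≥ 1.5 kb apart), fragment length F = 200, 50k ChIP tags per replicate and
50k input tags, 200 expected ChIP tags per site, AACCTTGGAA planted at 80%
of sites with 0–1 mismatches, 10% clonal duplicates, 30
expression-dependent genes.  At these settings a site window is ~8-fold
enriched over background — clearly detectable at the standard thresholds
without being degenerate — and the null configuration (no sites) yields
essentially zero calls.

Site tags follow the two-cluster strand model: plus tags at
center − F/2 + ε, minus tags at center + F/2 − ε, ε ~ round(N(0, F/8)).
The paper-scale structure of real data is emulated; the following are not:
sequencing errors and quality, mappability and GC bias, paired-end
structure, chromatin-accessibility-dependent backgrounds, and
condition-dependent binding.  Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated model, not
robustness to those real-data artifacts.

Expression noise is Normal with sd 0.25 per timepoint (three timepoints),
so spurious ≥ 2-fold calls are rare (~2×10⁻⁴ per gene) and the dependent
set is dominated by the planted genes; dependent genes are planted
preferentially at genes whose promoters face binding sites, giving the
expression-overlap statistic genuine signal to detect.

## Problem sizes

The bundled fixtures are deliberately small: `tiny` (100 kb, 10 sites,
10k tags) runs the full pipeline in seconds; `paper-shape` (2 × 400 kb, 60
sites, 40k tags per replicate, two replicates) is a tenth-scale analogue
of a genome-wide study and is the dataset used for the recovery
(recall/precision ≥ 0.95) and calibration suites.  All fixture data are
generated programmatically from seeds; nothing binary is stored.

## Known limitations

* Peak geometry is fixed-width; variable-width or broad-domain calling is
  not supported.
* The FDR is an empirical randomization estimate, not an analytic bound;
  with 3 randomizations its resolution below ~1e−3 depends on the number
  of candidate windows.
* Motif discovery fits exactly one motif of exactly width 10; no width
  search, multiple motifs, or higher-order backgrounds.
* The greedy replicate matching can differ from the optimal matching in
  pathologically dense peak lists (closer than one peak width), which the
  caller cannot produce but hand-constructed input can.
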