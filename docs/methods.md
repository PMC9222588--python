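# Methods

## Locus model and coordinates

A locus is two plus-strand flank sequences, a 3-nt motif, and the ordered
CpG cytosine coordinates of the flanking island. Coordinates are
*repeat-collapsed*: the upstream flank ends at `repeat_start − 1`, the
downstream flank begins at `repeat_start`, and the repeat tract is an
insertion point between them. Because read-to-read repeat length varies by
thousands of bases within one sample, any fixed per-site coordinate system
must exclude the repeat; collapsing it makes a CpG's coordinate identical
across alleles and reads, which is what per-site aggregation requires.
Flanks are validated to contain no run of ≥ 3 motif copies on either
strand so the anchors cannot lock onto the repeat itself. All file
coordinates are 1-based inclusive; internal offsets are 0-based half-open.

## Repeat sizing

Orientation tries both strands and keeps the one whose combined
local-alignment score of the two 150-nt flank anchors is higher. Anchor
location aligns the prefix anchor against the whole read, then the suffix
anchor only downstream of the prefix end; scores are normalised by the
maximum attainable score (anchor length × match score). Alignment
parameters are match +1, mismatch −1, gap open −2, gap extend −1 —
standard moderate-gap-cost local alignment; they are module constants and
the score threshold is a parameter. Two thresholds play different roles:

* `ANCHOR_FLOOR` = 0.3 — below this an anchor is treated as absent
  (`no_anchor`); at 7% read error true anchors score ≈ 0.8–0.9, while the
  best spurious local alignment of a 150-mer in unrelated sequence stays
  well below 0.3, so the floor separates "not this locus" from "noisy".
* `min_score` = 0.5 (default) — the pass/fail quality filter applied by
  `filter_calls`, exposed on the CLI. The filter's role (discarding
  unreliable anchorings) mirrors raw-signal pipelines' score cutoffs, but
  on a normalised, portable scale.

The count is `⌊tract length / 3⌋`: interruptions count toward the
expansion, and a 1–2 nt remainder from indel noise is ignored. Zero-length
tracts are marked `zero_length` regardless of score (an anchored read with
no repeat between the anchors is biologically impossible at this locus and
indicates a chimeric or mis-anchored read). Allele classes: count < 35
normal, > 50 expanded, else intermediate. The premutation-range
intermediate class is kept rather than silently binned; allele-specific
methylation uses only normal and expanded. The sample median uses the
lower-middle element for even n, so every reported length is an observed
integer count.

## Interruption profiling

Reads with more than 35 triplets are sectioned into 240 nt from the 5'
end, the middle, and 240 nt from the 3' end; the middle exists only for
tracts > 480 nt, and shorter tracts report overlapping terminal sections
rather than being skipped. Per section the fraction of motif triplets is
computed by non-overlapping triplet decomposition. Frame 0 is anchored at
the tract start, but indels make the frame drift, so each section is also
evaluated in the best of the three frames (maximising the motif count) and
the best-frame value is the default output — otherwise indel errors
masquerade as interruptions. Known limitation: best-frame correction is
per-section, so an indel *inside* a 240-nt section still corrupts the
downstream remainder of that section; at 4% indel rates observed purity of
a truly pure section is therefore well below 1, and interruption-density
estimates are quantitative only on low-indel data (the recovery checks run
on noise-free tracts, isolating the statistic from the error model).

The pattern classifier flags an end *pure* when any single read reaches
the purity threshold (default 0.95 — sequencing errors make literal 100%
brittle) at that end, mirroring what an end-anchored assay can latch onto
in a single molecule. The middle is judged by its **median** fraction
across reads: with, say, a 10% interruption density over a 240-triplet
middle, roughly one read in two hundred has a chance-clean middle, and one
such molecule must not flip a typically interrupted sample to
"uninterrupted middle" — a max rule would, a median rule does not. Labels:
`uninterrupted`, `ends-pure-middle-interrupted` (RP-PCR invisible),
`end-interrupted-5prime`/`3prime` (that end never pure → RP-PCR visible),
`uniform` otherwise. `rp_pcr_detectable` is true iff at least one end is
never pure.

The pooled trinucleotide distribution uses fixed frame 0 (it describes
composition of the called tracts, not a per-section statistic).

## Methylation aggregation

Calls are three-way: LLR > 2.5 methylated, < −2.5 unmethylated, otherwise
ambiguous — strict inequalities, so boundary values are ambiguous. The
per-site fraction excludes ambiguous calls from numerator and denominator;
this is the established convention for LLR-based callers (an unconfident
call carries no evidence either way), and the ambiguous count is retained
per site so the inclusive alternative is recomputable. Parsing harmonises
minus-strand G coordinates to the plus-strand C (position − 1) and merges
both strands' evidence per site.

Consensus is the unweighted mean of the defined per-caller fractions at
each site; sites missing in some caller average over the defined ones
(dropping them would thin the island grid), and the number of contributing
callers is reported. Consensus is permutation-invariant and the identity
for a single caller.

Allele stratification joins records to repeat calls by read id;
intermediate, unassigned and unjoined reads contribute to the pooled
profile only and are counted in the log. When every read is stratified,
the pooled fraction at a site is exactly the coverage-weighted convex
combination of the strata fractions.

Smoothing is local linear regression with tricube weights (lowess,
statsmodels), span 0.75 of the sites, no robustness iterations, evaluated
at the input positions and clipped to [0, 1] — deterministic and
reproducible, preserving constants and linear trends. Method comparison is
Pearson r (two-sided) at the intersection of defined positions; array beta
values are treated as directly comparable to methylated fractions (both in
[0, 1]).

## QC

QC is self-contained by design: on-target status and ROI coverage derive
from the pipeline's own anchor alignments (a read is on target when its
anchor-implied collapsed-coordinate span overlaps the ROI by ≥ 1 base)
rather than from an external genome aligner, keeping the pipeline
dependency-free and testable. Read accuracy is global-alignment identity
(matches over alignment columns, gaps counted; edlib) of the oriented read
against its own locus template — the reference with the repeat tract set
to the read's called length. Throughput is summed read length over the
provided reads, so it is comparable only within a run, not to
instrument-level throughput.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Alleles.** Each read draws normal or expanded at 1:1 (a diploid
  sample). Normal count default 13 triplets (a common normal allele);
  expanded counts default lognormal(median 650, geometric spread 1.5) —
  a skewed, long-tailed law matching observed somatic mosaicism spanning
  roughly 140–940 triplets around a median of 650 at that spread. A
  `fixed` family supports controlled experiments.
* **Interruptions.** Per-triplet substitution with a given motif at a
  given density within a region — first 240 nt, last 240 nt, the
  remainder, or uniform — matching the sectioned statistic's geometry.
  No per-patient interruption densities are established in the
  literature; defaults are illustrative, not calibrated.
* **Errors.** Independent per-base substitution/insertion/deletion,
  default (0.03, 0.02, 0.02): 7% total, i.e. ~93% read accuracy, the
  realistic operating band for this read type. No homopolymer weighting —
  the simplest model reproducing the accuracy level; noted as extensible.
* **Length bias.** Retention probability exp(−0.15 · kb): at a ~2 kb
  length difference between alleles this yields the ~1.3× normal-allele
  overrepresentation targeted sequencing of such loci shows.
* **Methylation.** Each flank is split at its midpoint into a shore
  (outer) and island (inner) region; per region and allele a methylation
  probability generates each read's per-CpG state. Defaults: normal
  allele {shores 0.6, island 0.05}; expanded allele {upstream shore 0.6,
  island 0.8, distal shore 0.15} — hypermethylation of the expanded
  allele's island flanks and a profound distal-shore drop, with the
  normal allele control-like.
* **LLR emission.** N(+4, 2) for methylated, N(−4, 2) for unmethylated —
  straddling the ±2.5 cutoffs with a realistic ~23% ambiguous-call rate.
  Recovery checks use N(±5, 1) as a well-separated operating point.
* **Strand.** Reads are reverse-complemented with probability 0.5; truth
  stores plus-strand offsets.

All randomness flows from the single config seed (caller tables use
deterministic spawned streams), so equal seeds give byte-identical
output. The truth table records every attempted read with a `retained`
flag, making the length-bias closed form directly checkable.

What the generator does **not** emulate: raw-signal artefacts, realistic
per-base quality strings, homopolymer-dependent error, PCR chimeras,
mappability structure outside the locus, or correlated methylation along a
molecule (per-CpG states are independent given allele and region). Passing
tests therefore demonstrate correctness of the *analysis* under the stated
statistical structure, not robustness to every artefact of real runs.

## Problem sizes

The test suite and the acceptance script size their simulations for
desk-scale runs: 300-nt flanks with 20 CpGs for sizing checks (error-free
sizing over 200 reads spanning 1–2000 triplets; 500 noisy reads at true
count 400), 100 expanded reads for interruption recovery, and a 2000-nt
per-flank island with 400 CpGs at coverage 80 (expanded) / 110 (normal)
for methylation recovery. These sizes give binomial/alignment error bars
comfortably inside the asserted tolerances.
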