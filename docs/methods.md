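# Methods

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED-native). The two
1-based surfaces — TSS tables and `chrom:start-end` region strings on
the CLI — are converted exactly once at the reader boundary, so
`chr1:1-100` denotes the half-open interval [0, 100). Multi-mapping tag
weights ride in the BED score column; a tag hitting *k* loci carries
weight 1/*k* at each, which is a convention of this package (aligners
report multiplicity, not weights) and the reason raw counts and library
totals can be fractional.

## Weighted counting

The count of a region is the sum of tag weights under one of two rules:
`any_overlap` (≥ 1 bp, the bedtools-intersect default and the package
default) or `contained` (tag fully inside). The index stores, per
chromosome, tags sorted by start and by end with weight prefix sums;
an `any_overlap` query is then

  count[s, e) = W(start < e) − W(end ≤ s)

— exact because tags starting at or after `e` and tags ending at or
before `s` are disjoint sets — giving two binary searches per query.
Containment queries slice the start-sorted array and mask on ends. With
weights restricted to dyadic rationals (1, 1/2, 1/4, …) and desk-scale
totals, all partial sums are exactly representable in IEEE doubles, so
counting is exact, not approximately so; the test suite exploits this
to demand bit-equality against an all-pairs oracle.

## The randomized-window null

To test enrichment of a length-*L* query, the placement space of all
valid window starts is enumerated *exactly* as maximal gap intervals:
start `s` is valid iff [s, s+L) lies inside its chromosome and overlaps
no exclusion (a window overlaps exclusion [a, b) iff
s ∈ [a−L+1, b−1]). Sampling is uniform over the flattened space with
replacement across trials — each chromosome is hit with probability
proportional to its valid-start count, and trials are independent.
Compared to rejection-sampling shufflers this is unbiased and cannot
hang regardless of exclusion geometry; the trade-off is O(genome)
enumeration, trivial at any realistic chromosome count.

Defaults: exclusions = {query} (so the observed region never
contaminates its own null); 10,000 trials; a single seeded generator
drives all trials in order, making results bit-reproducible.

The empirical p-value is the add-one upper-tail estimator
(r+1)/(n+1) with ties counted as extreme — never anti-conservative,
never zero. The underlying study design this mirrors reported only
visual consistency of the observed count with the null histogram; the
p-value is this package's addition and is labelled as such in the JSON
output. The default histogram uses integer-width bins spanning the null
and the observed value, overridable by explicit edges.

## Promoter classes and the K–S comparison

Promoter = [tss0 − flank, tss0 + flank + 1) around each *distinct*
(chrom, position) pair (default flank 50 nt ⇒ 101 bp), clipped at
chromosome edges; strand never changes the window, and TSS records
sharing a position collapse with their gene ids concatenated.
Classification is plain interval overlap (≥ 1 bp) against the merged
peak set, so it is order-independent. Zero-count promoters are retained
in both class vectors; dropping them would condition on expression and
bias the comparison.

The two-sample K–S statistic evaluates both empirical CDFs at every
pooled data point (handling the heavy ties of near-empty promoter
windows exactly). The p-value is the asymptotic Kolmogorov series at
effective size n_x·n_y/(n_x+n_y) — the same large-sample formula R's
`ks.test(…, exact = FALSE)` applies — clamped to (0, 1]. The tests
freeze reference values computed with R's implementation and document
the asymptotic-vs-exact gap at small n. With mostly-zero count vectors
the statistic is dominated by the difference in the fraction of empty
promoters, which is precisely the quantity of interest at this signal
density.

## Bench formulas

* Relative expression is implemented literally as
  A = 2^((Ct_ref − Ct_ref-control) − (Ct_sample − Ct_sample-control)).
  Whether "ref" denotes the reference gene or the reference condition is
  ambiguous in common usage; both readings are arithmetic mirror images
  (swapping the pairs inverts A, a property-tested identity), so the
  function documents the symmetry rather than choosing.
* ChIP percent-of-input: %input = 100 × 2^(Ct_input_adj − Ct_IP) with
  Ct_input_adj = Ct_input − log2(1/input_fraction). The no-antibody
  background is subtracted in percent space, and the result is *not*
  floored at zero by default — a flag floors it — so systematic
  negative corrections stay visible.
* Isoform abundances: each integrated peak area over the summed area of
  all isoforms of the peptide (the total taken as 100%).
* 3C: every crosslinking frequency of a fragment pair is divided by
  that pair's control-condition mean, so the normalized control mean is
  1 by construction; pairs with ≥ 2 replicates per condition get a
  two-tailed Welch t-test (unequal variances — the safer default for
  n = 3 replicate designs) at α = 0.05. Normalization and p-values are
  scale-invariant per pair. If both samples are constant and equal the
  test degenerates to t = 0, p = 1 rather than NaN.

## The synthetic-data generator

The generator emulates the statistical regime the analyses assume, at
desk scale:

* **Genome**: 20 Mb over four chromosomes (6, 5.5, 4.5, 4 Mb). A real
  fly-genome-scale layout is a configuration, not the default.
* **Tags**: homogeneous Poisson background, default λ = 5 × 10⁻⁴
  tags/bp (E ≈ 10⁴ tags genome-wide — small enough for hundreds of
  replicates, dense enough that a 340 kb window holds ~170 tags);
  lengths uniform on [21, 23]; a `multimap_frac` (default 0.1) of tags
  carries weight 0.5. Spikes and peak-coupling are superposed: inside an
  elevated region with multiplier f, extra tags ~ Poisson((f−1)λ·len)
  are added, so intensities are exact, assuming elevated regions are
  effectively disjoint (at 1000 101-bp promoters on 20 Mb, overlaps are
  negligible).
* **TSS/peaks**: TSS positions uniform without replacement, placed so
  ±flank windows fit their chromosome; each promoter carries a peak
  (the window itself) with probability `peak_prob` (default 0.5);
  `coupling` multiplies the tag rate inside peak-bearing promoters
  (1 = independence, the null regime). A truth table records every
  promoter's class and rate multiplier.

Everything is a pure function of the config (including its seed) via
per-stage independent generator streams; the same config regenerates
byte-identical files.

What the generator does **not** emulate: sequence content and
alignability (no FASTA, no mappability structure), chromatin-domain
autocorrelation of real sRNA coverage, assembly gaps, GC bias, and
peak-width variation (synthetic peaks coincide with promoter windows).
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated model, not robustness to
those real-data artefacts; on real data the null model's homogeneity
assumption is the user's to justify (e.g. by adding gap exclusions).

## Problem sizes and numerical choices

Calibration of the region test is established over 200 independent
scenarios at 1000 trials each (p-values uniform by K–S); power against
a 5× spiked query over 50 replicates; the promoter comparison under
independence over 100 replicates and under 4× coupling over 50. These
sizes give the binomial margins the checks need while keeping the full
suite under a minute of compute. Degenerate inputs are defined, not
crashed on: empty libraries count zero everywhere (and an empty library
carries total 0, with normalization rejecting the zero denominator);
a placement space with no valid start raises before any sampling; the
empirical p is never 0 or undefined by construction.

Known limitations: the 1/k multimap weighting is a convention, stated
to users, not an inference; the K–S p-value is asymptotic (conservative
at very small class sizes); the enrichment test's null is homogeneous —
mappability- or GC-matched nulls are out of scope.
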