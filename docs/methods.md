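# Methods

`endrip` implements the bespoke computational steps of a two-timepoint
camptothecin (Top1-poison) genomics study: calling double-strand-break (DSB)
clusters from strand-specific END-seq peaks, classifying DNA-RNA hybrid
(R-loop) peaks from DRIP-seq into seven kinetic categories, and measuring
overlap enrichment between the resulting interval classes against a
randomization null.  Every stage is exercised end to end on synthetic data
with planted ground truth.  This note records the models, the parameters
that matter, and the design choices made where the procedure was genuinely
open.

## Coordinates and containers

All intervals are 0-based half-open (`[start, end)`, BED convention).  Two
intervals overlap iff they share at least one base pair; abutting intervals
do not overlap.  Signal tracks are piecewise-constant per chromosome
(bedGraph semantics, value 0 where uncovered).  Downstream stages consume
only the library's domain types; no stage re-parses files ad hoc.

## DSB cluster calling

END-seq reads flank a blunt double-ended break strand-specifically: minus
strand on the left (F2R1 orientation), plus strand on the right (F1R2).  A
break therefore appears as a reverse peak closely followed by a forward
peak.

**Pairing.** For each reverse peak `r` the closest admissible forward peak
`f` is sought with signed distance

- `d = f.start − r.end` when `f` starts at or after the reverse end,
- `d = 0` when the peaks overlap by ≥ 1 bp,
- negative (inadmissible) when `f` lies entirely left of `r`.

Pairs with `0 ≤ d < 150 bp` are kept; the cluster spans
`[r.start, f.end)`.  Matching is one-to-one: candidates are processed in
ascending `(d, forward start, reverse start)` order and each peak supports
at most one cluster, so a forward peak contested by two reverse peaks goes
to the smaller gap, ties to the leftmost.  Three conventions are the
package's own where the procedure was underdetermined: overlapping peaks
are valid pairs at distance 0 (end-blunting makes abutting flank peaks the
expected geometry at a break); a forward peak whose end coincides with the
reverse start ("book-ended on the left") is on the wrong side of the break
and is discarded even though the signed-distance formula would give 0; and
the greedy one-to-one resolution above, since a closest-match step alone
does not say how contested peaks resolve.  The pairing stage is verified
exactly against a brute-force all-pairs oracle on random instances.

**Consensus and universe.** Within each treated condition, clusters from
the two replicates are grouped by transitive ≥ 1 bp overlap; groups
containing both replicates are union-merged into consensus clusters
(support = {1, 2}).  The cluster universe is the union-merge of consensus
clusters across treated conditions.

**Kinetic classes.** Counts over the universe are normalized (below) and
each treated timepoint (10 and 20 min) is tested against the untreated
control.  A cluster is differentially enriched when `|log2FC| > 1` and
`p < 0.05` with positive sign.  Classes: *persistent* = enriched at both
timepoints, *transient* = 10 min only, *late* = 20 min only; any transient
cluster overlapping a late cluster is promoted, together with that late
cluster, to persistent; within each final class overlapping clusters are
merged.  Universe clusters enriched in neither contrast are reported as
unclassified in a side file, never silently dropped.

**Single-ended breaks.** Per strand, replicate-consensus peaks whose
distance to the nearest opposite-strand peak strictly exceeds 150 bp are
solitary-peak candidates.  To remove outliers, only peaks whose normalized
count lies within `[Q1, Q3]` (inclusive; linear-interpolation quantiles,
the scientific-stack default) are retained per strand; with fewer than four
solitary peaks on a strand the filter is skipped with a warning.  Retained
peaks enriched at both treated timepoints are persistent seDSB calls.

**Peak calling.** A deliberately minimal threshold-and-run caller is
provided for rectangular synthetic coverage (signal ≥ `min_fold` × max(local
background, genome-wide background mean), runs ≥ `min_width` bp, sub-threshold
gaps < `min_width/2` merged).  Model-based peak calling is out of scope; the
pipeline equally accepts externally called peaks.

## Normalization

Each library carries a raw spike factor `f`: on-target spike-in reads over
total quality-filtered reads (RiP/RQC) for END-seq, the spike-genome read
fraction for DRIP.  Factors are rescaled by the minimum across the
experiment's libraries, `s_i = f_i / min_j f_j` (so `min(s) = 1` exactly),
and combined with a median-ratio library-size factor
`ℓ_i = median_j(total_j) / total_i`.  The per-library table reports `f`,
`s`, `ℓ` and the combined factor `s·ℓ`.

Counts are corrected as `normalized = raw × ℓ / s`: a library with deeper
sequencing or higher spike recovery (higher immunoprecipitation efficiency)
is deflated.  Applying the two corrections in this orientation is a
deliberate design choice — it is the only composition under which (a)
higher spike recovery deflates counts, (b) deeper sequencing deflates
counts, and (c) between-library ratios of normalized counts are invariant
when all read counts and totals are scaled by a common constant (uniform
deeper sequencing).  The simulation closes the loop: the generator plants
per-library depth and efficiency multipliers and records the spike
metadata they imply, and normalizing with the recovered factors removes the
planted library effects exactly (up to binomial noise in the spike draw).

## Moderated differential test

On `y = log2(normalized + 0.5)` a two-sample t-test with variance
moderation is used.  Per region, `log2FC = mean(y_A) − mean(y_B)`; the
pooled within-group variance `s²` (on `d = n_A + n_B − 2` df) is shrunk
toward the median pooled variance across regions `s0²`:

    s̃² = (d0·s0² + d·s²) / (d0 + d),      t = log2FC / (s̃·√(1/n_A + 1/n_B)),

with two-sided p from a t distribution on `d0 + d` df.  The prior degrees
of freedom default to `d0 = 4`; the median-variance prior is a lightweight
stand-in for full empirical-Bayes moderation (fitting an inverse-gamma
prior is deliberately not reproduced).  The pseudocount 0.5 handles zero
counts.  If every region has zero variance, `s0²` is floored at 1e-8 with a
warning.  Two limits are verified numerically: `d0 → 0` recovers the
classical equal-variance t-test, `d0 → ∞` pins all variances at the
median.  On negative-binomial null data (dispersion 0.05, 2 vs 2
replicates, 2 000 regions) the empirical type-I error at α = 0.05 is
0.04–0.05, and power at a planted 4-fold change exceeds 0.99.

## DRIP branch

The region universe keeps a peak iff, in at least one biological
condition, a replicate-1 and a replicate-2 peak overlap; universe regions
are the union-merge of the whole overlap group.  True-positive hybrid
regions are then selected by comparing immunoprecipitated against RNase
H1-treated libraries: a region passes when `log2FC > 1` at `p < 0.05`
(the only explicit differential gate available; the filter's own threshold
was not otherwise specified).  Missing RNase H libraries skip the filter
with a prominent warning.

On RNase-H-passed regions each treated timepoint (5 and 60 min) is tested
against untreated; a region is up/down/ns at `p < 0.01` with the sign of
log2FC (p-only gate, fold gate configurable).  The state pair maps to the
seven categories: (up,up) stable gain, (down,down) stable loss, (up,ns)
transient gain, (down,ns) transient loss, (ns,up) late gain, (ns,down)
late loss, (ns,ns) no change.  Opposite-sign pairs — which the
seven-category scheme does not anticipate — are reported in a separate
*discordant* category and never counted among the seven.

## Overlap enrichment

For a query class of `n` intervals against a feature set: observed `k` =
number of query intervals overlapping ≥ 1 feature by ≥ 1 bp (per-interval,
not per-bp, counting).  Each of 100 shuffles re-places every interval
uniformly on its own chromosome, preserving the length multiset and
per-chromosome counts (staying on the source chromosome preserves
per-chromosome composition; cross-chromosome placement is a documented
switchable alternative).  The expectation is the mean shuffle count, the
per-interval success probability is the moment estimate `p̂ = expected/n`,
and `k` is referred to the binomial upper tail when `k ≥ expected`, lower
tail otherwise.  `p̂` is clamped away from the degenerate boundary of the
tail being tested by half a shuffle resolution, `1/(2·n·100)`, so a finite
randomization can never claim infinite significance — but a fully tiling
feature set still yields p = 1 exactly.  Effect size
`log2FC = log2((k + 0.5)/(expected + 0.5))` (pseudocount handles
`expected = 0`); the ratio uses the mean expectation rather than averaging
per-shuffle ratios.  Planted fixtures (features on 10 % of the genome,
placement probability 0.8) recover the analytic `log2(0.8/0.1) ≈ 3.0`
within ±0.3, and uniformly placed queries reject at 5 % about 2–9 % of the
time (slightly anti-conservative through Monte-Carlo noise in `p̂`).

## Annotation and profiles

Gene-feature annotation is midpoint-based with strand-aware windows:
promoter = 10 kbp upstream of the TSS plus the 5′UTR, terminator = 3′UTR
plus 10 kbp past the TES, gene body = the remaining transcribed unit;
priority promoter > terminator > gene body > intergenic, so every peak
receives exactly one category.  (Richer annotation logic such as
expression-informed assignment is out of scope.)  Reference-point
metaprofiles cut the ±3 kbp window around each region center
`c = ⌊(start+end)/2⌋` into 100 equal bins and average the track per bin;
bins extending past a chromosome edge are masked (NaN) and ignored in the
column mean.  Scaled gene-body (TSS-to-TES) metagenes are not implemented.

## Synthetic data: what it emulates, what it does not

The generator plants, on a 3 × 5 Mbp genome: 300 double-ended breaks (100
per kinetic class; flank peaks 300 bp, break gap uniform on [0, 140] bp),
30 single-ended breaks, 40 hybrid peaks per kinetic category (widths
0.8–2 kbp, bracketing the ~1.7 kbp average of restriction-digested DRIP
fragments) plus ~10 % decoy peaks, and 60 genes for annotation.  Effect
size |log2FC| = 2, negative-binomial dispersion 0.05, two replicates,
spike-in genome ratio 1:1000, library sizes jittered ±30 % with spike-in
recovery efficiencies drawn per library — parameter values the study
design states where it states them, otherwise chosen once as realistic for
this assay class and documented here (dispersion in particular is a free
parameter: the real replicate-to-replicate variance is unknown).  Sixty
percent of persistent breaks are nested inside stable-gain hybrid peaks so
the enrichment stage has a planted positive association to recover; decoy
peaks are RNase-H-insensitive (control-level signal in both IP and RNase H
libraries) to exercise the true-positive filter.  Per-replicate peak
coordinates are jittered ±20 bp on their outer edges only, so the planted
pairing gap is identical across replicates while consensus overlap stays
non-trivial.

Not emulated: read-level artifacts (mapping ambiguity, GC bias,
duplicates), blacklist regions, chromatin covariates, anything that makes
real peak calling hard.  Passing tests therefore demonstrate correctness
of the interval arithmetic, normalization algebra, statistics, and
classification logic under the stated noise model — not robustness to
alignment pathology.

## Problem sizes and numerical notes

The default test and acceptance runs use the full default study (3 × 5 Mbp,
~640 planted features, 14 libraries), 500 random pairing instances against
the brute-force oracle, 2 000 regions for calibration/power, and 200
enrichment runs of 100 shuffles each; the whole suite completes in well
under a minute of compute.  All randomness flows through
`numpy.random.Generator` (PCG64) seeded explicitly; identical config + seed
reproduces byte-identical dataset files, and the CLI `all` command is
byte-reproducible end to end (the run manifest, which carries a wall-clock
timestamp, is the one file excluded from that comparison).  Quantiles use
linear interpolation between order statistics; p-values are floored at the
smallest positive double to keep `-log10(p)` finite.

## Known limitations

- The moderated test approximates, but does not reproduce, full
  empirical-Bayes variance moderation; with very few regions the median
  prior is noisy.
- The binomial enrichment p-value treats query intervals as exchangeable
  Bernoulli trials; long-range clustering of real query sets would violate
  this and the shuffle null carries no blacklist or covariate matching.
- The midpoint rule assigns peaks spanning a feature boundary by their
  center only.
- `consensus_regions` requires exactly the two-replicate design the study
  uses; higher replicate counts would need a generalized consensus rule.
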