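# Methods

## Signal model and coverage construction

All analyses operate on per-base coverage tracks in which each aligned
fragment pair contributes a single unit at the fragment midpoint
(`floor((start+end)/2)`, 0-based half-open coordinates throughout; BED
is native, GFF-style inputs must be converted on read). ChIP libraries
are restricted to fragment lengths of 100–200 bp (inclusive) before
coverage construction: micrococcal-nuclease digestion of the sensor
strains yields ~85 % mononucleosomes and ~15 % dinucleosomes, and the
size filter removes the latter. ChEC libraries keep all fragments.

Tracks are normalized so the total coverage outside the ribosomal locus
equals 10,000,000. The rDNA is excluded only from the denominator; its
positions are scaled by the same factor, not zeroed. The target is
taken as exactly 10⁷ (the convention is an order-of-magnitude
anchor; any fixed constant gives identical downstream statistics, since
every estimator is either ratio-based or normalized to t = 0).
Biological repeats are averaged position-wise after normalization
wherever a single representative track is needed; the change estimators
below use the repeat-resolved tracks.

Smoothing is a centered moving average whose window shrinks at array
edges; constant input is preserved exactly. Even windows are ill-posed
for a centered filter and are rejected by default; internal callers
that need the literal even widths of the protocol (250 bp for ChIP
sample similarity, the 10-bp metagene window) use an explicit
asymmetric policy (window//2 left, window//2 − 1 right) or the
symmetric window+1 variant (metagene, default). Genome-wide sample
similarity is the Pearson correlation of two smoothed tracks (141 bp
ChEC, 250 bp ChIP) over all promoter and gene-body positions.

## Feature taxonomy

Each gene with −1/+1 nucleosome dyads is carved into: promoter (the −2
and −1 nucleosome footprints, dyad ± 73 bp, kept as one feature with
two disjoint intervals), NDR (the open interval between the −1 and +1
footprints), 5′ (first 350 bp after the TSS), 3′ (last 350 bp before
the TTS), mid (the remainder; empty at exactly 700 bp, and for shorter
genes 5′ takes the first min(350, L) bp so segments never overlap),
and terminator (100 bp downstream of the TTS). Minus-strand genes are
mirrored. Special loci (histone promoters, rRNA, ARS, centromere,
tRNA, TY+LTR, telomere) pass through unchanged.

Expression groups: genes are rank-split into five groups at the
cumulative proportions of the reference set (428, 1766, 3070, 832, 300
genes from lowest to highest expression). Boundaries are
`ceil(n × cumulative proportion)` — the rule that reproduces the
reference counts exactly and gives (7, 28, 48, 13, 4) on 100 genes.
Ties are broken by stable gene-id order, so grouping is invariant to
monotone relabeling of expression.

OPN score: mean occupancy over [TSS−150, TSS) divided by the mean over
[TSS−400, TSS−200), strand-aware and half-open (the endpoint openness
is a convention choice; half-open avoids double counting). Promoter
intervals for TF preference run from the TSS to the closest upstream
ORF but at least 700 bp; the floor reading follows the verbatim rule,
and the alternative cap reading ("at most 700 bp") is available as
`cap=True` since the underlying convention admits both.

## Scaled metagene

The frame is 1350 bp: 250 bp before the TSS, 350 bp after it, a
300-point middle, 350 bp before the TTS and 100 bp after it. Genes
need a known TSS/TTS and ≥ 700 bp to contribute; only genes > 1050 bp
contribute to the middle, whose coverage is smoothed (10-bp window,
implemented as the centered 11-point window) and linearly interpolated
at 300 equally spaced points including both endpoints,
`p_k = k·(L−1)/299` — inclusive endpoints keep the middle contiguous
with the fixed segments. Fixed segments are per-position means of raw
coverage across genes. Relative-change profiles are
`log₂(mean-across-repeats + 1) − log₂(t₀ mean + 1)`, the pseudo-count
applied after repeat averaging. Min–max scaling maps a profile
affinely onto [0, 1] (undefined, hence all-missing, for constant
profiles). Modification enrichment smooths both the mark and the HA
profile with a 51-bp window and reports
`log₂((mod + 0.5)/(HA + 0.5))`.

## Change estimation

ChIP variant: for every feature of a class and every repeat,
`x = log₂(mean coverage + pc)` is normalized to that repeat's t = 0
value; a single ordinary-least-squares line (with intercept — robust
when t = 0 repeats disagree) is fitted through all pooled (time, x)
points, and the slope × 90 min is the mean relative change. The
Pearson r of the pooled relation is the trend confidence, with the
standard two-sided t-test p-value (n − 2 df, no multiple-testing
correction); zero-variance inputs report r = 0, p = 1 so downstream
tables stay defined. Points are weighted equally (not per repeat).
pc defaults to 1 (matching the metagene convention; the protocol
leaves the feature-level value unstated) and is exposed — exact
closed-form recoveries use pc = 0.

ChEC variant (horizon 60 min): occupancies are first averaged across
all regions of a stratum within each (repeat, timepoint), then log₂-
transformed and normalized to the mean t = 0 level, and the line is
fitted with one point per repeat per timepoint. For balanced time
grids this equals the feature-level estimator on a single region
exactly (the per-repeat vs mean-t₀ centering difference is orthogonal
to time), which the tests assert at 1e−12.

Classification of a (myc, HA) change pair at threshold τ = 0.25
log₂/90 min (the screen never formalizes a threshold; τ is
configurable): incorporation if both ≥ τ; else eviction if HA ≤ −τ;
else replacement if myc ≥ τ; else stable. The rule is total.

PCA of genome-wide incorporation changes: log₂ mean myc per gene-body
segment (5′/mid/3′ of every gene), centered per segment across
samples, z-scored per sample (n−1 std), variables mean-centered
(standard PCA; switchable, as the original order of operations is
unstated), SVD scores, and mean ± standard error per (regulator,
timepoint) across repeats. RNA changes: per-gene
`log₂((count_t + pc)/(count₀ + pc))`, per-group median, 3-point
centered moving average shrunk at the ends.

A note on compositional normalization: fixed-total library
normalization makes a genuine genome-wide gain partially unobservable —
a net myc increase deflates all other strata by the log₂ of the total
mass change. With the default simulation (effects confined to small
strata) this drift is ≤ ~0.05 log₂ and is included in the recovery
benchmark; the noise-free exactness tests therefore run on expectation
tracks without renormalization, isolating estimator error from this
inherent property of the normalization.

## ChEC binding analytics

Enrichment of regulator R at feature type T standardizes log₂ mean
occupancies across regulators per type (sample n−1 std; zero
occupancies replaced by half the smallest positive value, degenerate
columns set to 0). Promoter preference is the summed normalized
coverage per promoter interval, compared between samples by Pearson
correlation.

Motifs are scanned on both strands by PWM log-odds against a uniform
(or supplied) background, thresholded at 80 % of the maximum attainable
score by default — a simple scanner standing in for p-value-calibrated
scanning, sufficient because the planted-motif analyses use
near-consensus PWMs where the threshold choice is immaterial. Motif
category priority: telomere > rRNA > gene body (within any TSS–TTS
span) > promoter (all remaining intergenic positions). Motif-window
math uses the match midpoint; occupancy matrices are strand-oriented
±80 bp rows sorted by category and total signal.

Spike-in absolute binding: spike-in reads = summed coverage in the
three control windows (±100 bp around each site; the width is a
convention choice, configurable); unique TF reads = mean coverage over
flank offsets −25..−6 and +6..+25 (the exact binding site, −5..+5,
excluded literally); absolute binding = flank mean / spike-in reads,
invariant to global depth rescaling. Bound-motif calls compare the
±80 bp window mean against the genome-wide mean coverage of the
motif's category (gene-body vs intergenic positions, telomere/rRNA
excluded; genome-wide rather than per-chromosome), bound iff
≥ 2-fold (inclusive). Sensor levels around the four
category × bound groups pool ±75 bp windows per timepoint.
Overlapping motif windows are pooled without deduplication.

## Synthetic screen generator

The simulator is the package's ground-truth instrument, not a fixture:
it emulates the study conditions. Defaults: a two-chromosome ~230-kb
genome, 72 genes of 0.8–2.6 kb with 0.6–1.2 kb intergenic gaps, log₂
expression ~ N(4, 1.5), nucleosome spacing 165 bp (+1 dyad 80 bp past
the TSS, −1 at 120 bp upstream, an NDR between the −1/+1 footprints),
a 3-kb rDNA locus, telomeres/centromeres, 24 promoter + 24 gene-body
planted 10-bp consensus motifs (alternating strands), and exactly
three spike-in sites outside genes.

ChIP: fragments ~N(151, 10) truncated to [80, 250] bp centered on
dyads, plus a 15 % dinucleosome population (~N(300, 30)) that the size
filter removes; counts are Poisson around 200 expected retained
fragments per nucleosome for HA, times a per-region myc fraction
(promoter/NDR 0.40, 5′ 0.15, mid 0.10, 3′ 0.12 — promoter-biased
steady-state exchange) for myc. A depletion effect multiplies the myc
fraction of its (region, expression-group) stratum by 2^(a·t/90): the
log-linear form matches the estimator's model, which is the right
choice for recovery testing and not a biological claim. Time grids:
0/20/40/60/90 min ChIP, 0/60 min ChEC.

ChEC: fragment midpoints follow an absolute per-bp intensity (uniform
background plus Gaussian footprints anchored at promoters, gene-body
positions, or motif centers weighted by each motif's planted occupancy
multiplier — ≥ 2 for true bound motifs, default 24 so bound windows
clear the 2-fold threshold decisively), scaled so the no-effect
library totals the configured depth (50,000 by default). Intensities
are absolute: a binding gain increases library mass while the spike-in
mass (fraction × depth per cell equivalent) stays constant, which is
what makes spike-in quantification meaningful. Fragment lengths
~N(60, 20) truncated ≥ 20. Component time-restriction supports
re-localization scenarios.

Each sample draws from its own stream seeded by (master seed,
CRC32(sample id)), so adding samples never perturbs existing ones;
fixed seeds give byte-identical outputs. Noise-free mode rounds
expectations to integer counts with fixed fragment lengths (150/300 bp
ChIP, 60 bp ChEC); exact real-valued expectation tracks
(`expected_chip_coverage`, `expected_chec_coverage`) serve the
closed-form tests, since integer fragment counts cannot realize 1e−6
exactness.

What the simulator does not emulate: sequence-dependent MNase bias,
mappability, PCR duplicates, fragment-boundary jitter around dyads,
replication, or biological covariance between repeats. Passing
recovery tests therefore demonstrate correctness of the analytics
under the stated signal model, not robustness to every artifact of
real libraries.

## Validation scenarios and problem sizes

The stratum-recovery benchmark plants a ∈ {+1, +0.5, −1} log₂/90 min
in the (5′, group 5), (mid, group 4) and (3′, group 5) strata and
re-estimates all 15 strata over 20 seeds (3 repeats, 5 timepoints,
Poisson noise, ~200 fragments/nucleosome, the 72-gene genome — sizes
chosen so the full benchmark runs in seconds while each stratum keeps
several genes). Mean recovered changes land within ±0.05 of truth;
null strata within ±0.05 of zero (drift + pseudo-count bias ~0.03,
seed-to-seed sd ~0.02 on the mean).

The spike-in scenario plants a 3-fold gene-body binding gain in a TF
model with all motif instances bound and low background (0.002/bp):
the absolute-binding statistic measures total flank occupancy, so
background and unbound-motif signal would dilute a planted fold — the
validation scenario makes the planted fold the truth of the measured
quantity. With mixed bound/unbound motifs and default background the
same 3-fold input reads out as ~2.6-fold, which is a property of the
pooled statistic, not an estimator error.

## Known limitations

* Fixed-total normalization absorbs genuine global changes (above).
* The PWM scanner reports log-odds scores, not calibrated p-values.
* The per-feature estimator weights pooled points, not repeats; with
  strongly unbalanced designs the two differ.
* Feature counts of the reference genome (n = 2444 promoters etc.) are
  properties of the real annotation and are not reproduced on
  synthetic genomes.
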