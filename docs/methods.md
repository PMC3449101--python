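# Methods

## Overview

`swatcna` locates recurrent copy number aberrations (CNAs) in an aCGH
cohort by scoring sliding windows of neighbouring probes for concordant
gain or loss across samples, gating the scores with per-chromosome
adaptive thresholds, and prioritizing the resulting regions by signal
amplitude and by gene density. Segmentation itself is an input: the
package consumes SEG-style constant-mean segment calls from any
external algorithm and never re-implements one (the bundled recursive
binary splitter exists only so synthetic cohorts can be analysed
end-to-end without external tools).

## Classification

Probes inherit a 5-point call {−2, −1, 0, +1, +2} from the segment
covering them. The abnormality threshold is computed per sample as

    T = | IQR(observed log2 ratios) − IQR(segment-predicted values) | × f

where the predicted value of a probe is its segment's mean, quartiles
use linear interpolation (type 7), and the factor change `f` defaults
to 0.75. The "middle fifty" of a well-segmented sample's predicted
values is much narrower than that of its raw ratios, so `T` scales with
the sample's noise floor; when observed and predicted distributions
coincide, `T = 0` and every non-zero segment is abnormal (a warning is
logged). An abnormal segment is high-level (±2) when it spans at most
`highlevel_max_width` probes (default 10 — roughly 700 kb on a 44K
array), otherwise single-copy (±1). Width is counted in probes covered
on the array, not base pairs, making the rule platform-density
independent. The width-only rule can mislabel narrow single-copy
events as high-level; an optional config flag
(`highlevel_amplitude_gate`) additionally requires |segment mean| > 2T
for ±2 calls and is off by default.

Whether a segmentation method's "predicted values" should be segment
means or model-fitted values is method-specific; segment means are used
because they are the only quantity every SEG dialect carries.

## Probe window scores

For direction d ∈ {gain, loss}, window size w and window start i, the
score is 100 × (#samples whose direction call equals d at all probes
i…i+w−1) / n_samples. Gain is pooled with amplification and loss with
high-level loss before scoring. Windows advance one probe at a time and
no partial windows are scored at chromosome ends — a score over fewer
probes would not be comparable. Scores are anti-monotone in w (a larger
window can only lose agreeing samples), which the test suite asserts on
random tables alongside exact agreement with a brute-force counter.

Regions detected at window sizes above the smallest configured size
must be re-detected by the internal smaller windows at equal or higher
recurrence: every probe of the region's MRI must be covered by at least
one smaller window whose score reaches the region's *peak* score. Peak
(not mean) is used because the MRI is defined by peak recurrence.

## Adaptive thresholds, CRIs and MRIs

Per chromosome and direction, thresholds are scanned down the ladder
(default 80…20 % in 10 % steps); the first whose gated windows cover at
least `target_coverage` (default 5 %) of the chromosome's probes is
accepted. If none reaches the target, the lowest ladder value is
accepted provided it gates anything; otherwise the chromosome carries
no CNA in that direction. Coverage is measured in probes, not base
pairs: on a uniform array the two agree, and probe counting is platform
independent. Ladder quantisation means the chosen threshold may
overshoot the target; the first threshold meeting it is accepted.
Gating is inclusive (PWS = AT gates).

Maximal runs of gated windows become CRIs; the probe span of a CRI is
the union of its member windows, and unions that overlap or abut are
merged. Within a CRI, windows achieving the maximum score chain
together when they overlap by ≥ 1 probe; each chain's probe union is
one MRI. This makes a flat-score CRI its own MRI and lets separated
maxima yield several MRIs per CRI. (The intersection of a chain was
rejected as the MRI definition: chains longer than one window size have
empty intersections, and a flat CRI must map to itself.)

## Amplitude prioritization

The null distribution of window mean intensity is estimated by drawing
`n_permutations` (default 10,000) random w-probe windows genome-wide,
the number per chromosome proportional to its probe count; the
statistic is the mean log2 ratio over the window's probes across all
samples. μ and σ are the sample mean and n−1 standard deviation of the
draws, and an MRI's P value is the one-tailed Gaussian tail probability
of its mean intensity in the aberration's own direction (a "gain" with
strongly negative mean must not pass). σ = 0 degenerates to P ∈ {0, 1}.
MRIs with P < `p_cutoff` (default 0.1) survive, ranked ascending by P
with ties broken by |mean intensity| descending. No multiple-testing
correction is applied; the cutoff is a screening heuristic, not an
error-rate guarantee. The seed is mandatory in the configuration so
runs are bit-reproducible.

## Gene-density prioritization

ARI = |mean MRI log2| × recurrence (recurrence = peak window score as a
fraction; the absolute value puts gains and losses on comparable
positive scales — directions are still ranked separately). RIC = number
of distinct gene names overlapping the MRI span by ≥ 1 bp divided by
the MRI's probe count. The focality index as defined algebraically
reduces to RIC ((RIC × ARI)/ARI) and is implemented literally with an
ARI = 0 guard; GDW = focality × ARI = RIC × ARI. Ranking is descending
GDW, ties by ARI then genome position. A gene-empty region has GDW 0
regardless of amplitude — by construction this scheme cannot rank
non-gene-coding loci, which is exactly why the amplitude list is kept
alongside it.

## Consensus and clustering

Same-direction MRIs from different segmentation methods pool
transitively on ≥ 1 bp overlap (the simplest deterministic rule; no
reciprocal-overlap fraction is required by default). Pools supported by
≥ `consensus_min_methods` (default 2) distinct methods become consensus
regions; the final set keeps regions present in both the
amplitude-derived and GDW-derived consensus lists.

Sample clustering uses the 5-point calls restricted to probes of CRIs
whose adaptive threshold is ≥ `cluster_min_at` (default 40 %), so
regions detectable only in small subsets cannot drive the grouping.
Distance is Euclidean on the integer call vectors with Ward linkage
(both configurable); the full linkage tree is always returned (and
exportable as Newick) so any cut is recoverable, with a default
3-group cut.

## Synthetic data

The generator plants rectangular events (chromosome, probe span,
direction, amplitude, prevalence) on an iid Gaussian noise floor.
Default amplitudes are +0.58 (log2 3/2, single-copy gain in a diploid
genome) and −1.0 (single-copy loss); default noise σ = 0.1 log2 units,
typical of a decent oligonucleotide array after normalisation; default
geometry 12 samples × 2 chromosomes × 500 probes keeps full-pipeline
tests inside a few seconds. Carriers are drawn per event at the stated
prevalence with the spec's seed, and the realised truth table is
returned for recovery scoring. The generator does *not* emulate GC/wave
artefacts, germline CNV polymorphism, cell-mixture attenuation or
probe-response heterogeneity — passing recovery tests therefore show
the region logic is correct under clean segment input, not that any
particular segmentation algorithm is robust on real arrays. The
reference segmenter (recursive binary splitting on the pooled
two-sample t statistic, default α = 1e−4, minimum segment 3 probes) is
deliberately simple; `perturb_segments` jitters its breakpoints to
fabricate disagreeing "methods" for consensus tests.

The packaged 6 × 20 toy layout is frozen in code as the minimal
configuration satisfying every fact its worked example states (first
window 0 %, second window 50 % carried by exactly samples A/D/E,
non-zero windows confined to the two probe-runs 2–10 and 12–19, every
non-zero score ≥ 50 %).

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; probe indices 0-based per
  chromosome; reports print 1-based positions. Strand is read, never used.
- Only autosomes (labels 1–22 after stripping any `chr` prefix) are
  analysed; other probes are dropped with a warning.
- Missing log2 values are imputed per sample as the mean of the nearest
  non-missing flanking probes within the chromosome (one-sided at ends);
  the imputation count is logged.
- A chromosome shorter than the window size yields an empty track
  (warning), contributes no permutation draws, and selects no threshold.
- Fewer than 4 observations per sample cannot define quartiles → error;
  all-missing MRI spans → error; probes uncovered by segments → error.
- Region extraction at equal scores: ties are resolved by genome
  position everywhere a serial order is needed.

## Problem sizes used in the checks

Property tests run on random tables up to 30 probes × 8 samples;
end-to-end recovery and calibration checks use 12-sample cohorts of
2 × 500 probes with 2,000 permutation draws and 1,000 scored windows —
large enough for stable Kolmogorov–Smirnov and recovery statistics
while keeping the default suite fast.

## Known limitations

- Adaptive thresholds are per whole chromosome; arm-level events can
  saturate a chromosome's budget and mask focal lesions on the other arm.
- The width-only high-level rule conflates narrow single-copy events
  with amplifications when the optional amplitude gate is off.
- Coverage targets assume approximately uniform probe spacing; highly
  non-uniform designs would need bp-weighted coverage (out of scope).
- The permutation null pools all samples, so a single extreme sample
  can inflate σ and mute real events in the amplitude filter.
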