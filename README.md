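# swatcna

Sliding-window, adaptive-threshold detection of recurrent copy number
aberrations (CNAs) from array comparative genomic hybridisation (aCGH)
data.

Given a cohort's probe-level log2 ratio matrix and per-sample segment
calls from one or more external segmentation algorithms (e.g. circular
binary segmentation, HMM-based smoothers), `swatcna` answers the
question cancer genomics screens keep asking: *which genomic regions
are gained or lost often enough, strongly enough, and focally enough
across the sample set to be worth following up?* It is aimed at
researchers mining aCGH cohorts for candidate driver loci who want a
systematic, parameter-file-driven alternative to eyeballing per-sample
segmentation plots.

## Method

1. **5-point classification.** Each segment is called from
   {−2, −1, 0, +1, +2} (high-level loss … high-level gain). A segment
   is abnormal when |segment mean| exceeds a per-sample threshold
   `T = |IQR(observed log2) − IQR(segment-predicted log2)| × f`
   (factor `f` = 0.75 by default); abnormal segments of ≤ 10 probes are
   called high-level (±2), wider ones single-copy (±1).
2. **Probe window scores (PWS).** For every chromosome, window size
   *w* ∈ {3…20} and direction, the score of the window starting at
   probe *i* is the percentage of samples whose calls share that
   direction at *all* probes *i…i+w−1*; windows slide by one probe.
3. **Adaptive thresholds (AT).** Per chromosome and direction, a
   threshold is chosen from the ladder 80, 70, …, 20 % — the highest
   value whose gated windows cover ≥ 5 % of the chromosome's probes
   (≈ 10 % total CNA per chromosome). Quiet chromosomes fall through to
   lenient thresholds, so low-prevalence recurrent lesions still surface.
4. **CRIs and MRIs.** Runs of gated windows form contiguous regions of
   interest (CRIs); within each CRI the probes attaining its peak
   recurrence form one or more minimum regions of interest (MRIs).
5. **Prioritization.** (a) *Amplitude*: each MRI's mean log2 ratio is
   tested against a Gaussian null fitted to randomly drawn same-size
   probe windows (draws weighted by chromosome length); MRIs with
   one-tailed *P* < 0.1 survive. (b) *Gene density*:
   `ARI = |mean log2| × recurrence`, `RIC = genes per MRI / probes per
   MRI`, `GDW = RIC × ARI`; ranking by GDW favours gene-dense lesions.
6. **Consensus and clustering.** MRIs flagged by ≥ 2 segmentation
   methods (≥ 1 bp overlap, direction-stratified) are merged; regions
   present in both prioritized lists form the final consensus. Samples
   are clustered hierarchically (Ward/Euclidean) on calls within CRIs
   detected at AT ≥ 40 %.
7. **Reports.** Static HTML: per-chromosome overview plots (median
   profile, recurrence chart with indexed CRI bars, high-level CNA
   frequency), karyograms, and per-region call grids with genome
   browser links.

## Worked example

The packaged toy experiment — 6 samples (A–F) on a 20-probe platform
with two regions of gain — can be scored by hand and by the library:

```python
from swatcna import figure1_fixture, collapse_direction, compute_pws
from swatcna import gate_windows, extract_cris

probes, calls = figure1_fixture()
track = compute_pws(collapse_direction(calls), probes, "1", 3, "gain")
print(track.scores)
cris = extract_cris(gate_windows(track, 50.0), track, probes)
for cri in cris:
    print(cri.index, cri.probe_start + 1, cri.probe_end + 1,
          [(m.probe_start + 1, m.probe_end + 1) for m in cri.mris])
```

prints

```
[  0.  50.  50.  66.66666667  83.33333333 100. 100.  83.33333333
   0.   0.   0.  83.33333333 100. 100.  83.33333333  66.66666667  50.   0.]
1 2 10 [(6, 9)]
2 12 19 [(13, 16)]
```

No sample is gained across all of probes 1–3, so the first 3-probe
window scores 0 %; samples A, D and E share gain across probes 2–4,
giving 50 %. Gating the track yields two CRIs (probe unions 2–10 and
12–19); within each, the probes reaching 100 % recurrence form the MRI.

A full synthetic run from the shell:

```sh
swatcna simulate --out sim --seed 5 --methods 3
swatcna run --probes sim/probes.tsv \
    --segments sim/method1.seg,sim/method2.seg,sim/method3.seg \
    --genes sim/genes.bed --out results
```

which writes per-method region/prioritization tables, the cross-method
consensus table, the sample tree (Newick) and the HTML report under
`results/`.

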