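"""Synthetic inputs: toy worked example, planted-CNA cohorts, reference segmenter.

Everything the pipeline consumes can be generated here so that the full
analysis runs end-to-end without external segmentation software:

* :func:`figure1_fixture` — a deterministic 6-sample x 20-probe gain
  layout suitable for demonstrating probe-window scoring by hand.
* :func:`simulate_cohort` — cohorts with planted aberrations (span,
  direction, amplitude, prevalence) on a Gaussian noise floor, returning
  the ground truth for recovery scoring.
* :func:`naive_segment` — a deliberately simple reference segmenter
  (recursive binary splitting on the two-sample t statistic) used to
  drive the classifier in tests and examples.
* :func:`perturb_segments` — jitters breakpoints to fabricate multiple
  disagreeing "methods" for consensus tests.

All generators are seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .classify import ClassificationTable
from .io_formats import ProbeMatrix, SegmentSet

logger = logging.getLogger("swatcna")

#: Default planted amplitudes: single-copy gain log2(3/2), single-copy loss.
GAIN_LOG2 = 0.58
LOSS_LOG2 = -1.0

_PROBE_SPACING = 100_000  # bp between synthetic probe starts
_PROBE_LENGTH = 60


def _probe_frame(chromosome: str, n_probes: int, offset: int = 0) -> pd.DataFrame:
    starts = (np.arange(n_probes) + offset) * _PROBE_SPACING
    return pd.DataFrame(
        {
            "probe_id": [f"chr{chromosome}_p{i + 1}" for i in range(n_probes)],
            "chromosome": chromosome,
            "start_bp": starts,
            "end_bp": starts + _PROBE_LENGTH,
        }
    )


# ---------------------------------------------------------------------------
# Toy worked example

# Gained probe spans (1-based inclusive) per sample. The layout is frozen:
# no sample is gained across all of probes 1-3; exactly samples A, D and E
# are gained across probes 2-4; every 3-probe window with a nonzero score
# lies in the runs whose probe unions are 2-10 and 12-19, and every nonzero
# score is at least 50%.
_FIGURE1_GAINS: dict[str, list[tuple[int, int]]] = {
    "A": [(2, 10), (12, 19)],
    "B": [(4, 10), (13, 18)],
    "C": [(5, 9), (12, 17)],
    "D": [(2, 10), (12, 19)],
    "E": [(2, 10), (12, 19)],
    "F": [(6, 10), (12, 16)],
}


def figure1_fixture() -> tuple[ProbeMatrix, ClassificationTable]:
    """Deterministic 6-sample, 20-probe toy experiment with regions of gain.

    log2 ratios are +0.58 (single-copy gain) over each sample's gained
    spans and 0 elsewhere; the classification table carries the matching
    {0, 1} calls. Regenerating the fixture always yields identical values.
    """
    n_probes, samples = 20, list(_FIGURE1_GAINS)
    calls = np.zeros((n_probes, len(samples)), dtype=np.int8)
    for j, sample in enumerate(samples):
        for lo, hi in _FIGURE1_GAINS[sample]:
            calls[lo - 1 : hi, j] = 1
    probes = _probe_frame("1", n_probes)
    log2 = pd.DataFrame(calls * GAIN_LOG2, columns=samples)
    pm = ProbeMatrix.from_frames(probes, log2)
    table = ClassificationTable(
        calls=pd.DataFrame(calls, index=pm.probes.index, columns=samples)
    )
    return pm, table


# ---------------------------------------------------------------------------
# Planted-CNA cohorts


@dataclass
class PlantedEvent:
    """One aberration to plant: a probe span with direction and prevalence."""

    chromosome: str
    probe_start: int  # chromosome-local, 0-based inclusive
    probe_end: int
    direction: str  # 'gain' | 'loss'
    amplitude: float | None = None  # log2 units; default by direction
    prevalence: float = 0.5
    high_level: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.prevalence <= 1):
            raise ValueError("prevalence must lie in (0, 1]")
        if self.probe_start > self.probe_end:
            raise ValueError("empty event span")
        if self.amplitude is None:
            self.amplitude = GAIN_LOG2 if self.direction == "gain" else LOSS_LOG2


@dataclass
class SimSpec:
    """Cohort blueprint: geometry, planted events, noise level and seed."""

    n_samples: int = 12
    n_probes: int = 500  # per chromosome
    n_chromosomes: int = 2
    events: list[PlantedEvent] = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        chroms = {str(i + 1) for i in range(self.n_chromosomes)}
        for ev in self.events:
            if ev.chromosome not in chroms:
                raise ValueError(f"event on unknown chromosome {ev.chromosome}")
            if ev.probe_end >= self.n_probes:
                raise ValueError("event span exceeds chromosome")


def simulate_cohort(spec: SimSpec) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Generate a cohort with planted CNAs plus iid Gaussian noise.

    Carriers of each event are drawn independently at the stated
    prevalence (seeded, so exact and reproducible). When two same-
    direction events overlap within one sample their amplitudes sum;
    such events are flagged in the returned truth table.

    Returns the probe matrix and a truth table (one row per event) with
    the realised carrier lists for recovery scoring.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    frames = [
        _probe_frame(str(c + 1), spec.n_probes) for c in range(spec.n_chromosomes)
    ]
    probes = pd.concat(frames, ignore_index=True)
    signal = np.zeros((len(probes), spec.n_samples))
    chrom_offset = {str(c + 1): c * spec.n_probes for c in range(spec.n_chromosomes)}
    truth_rows = []
    touched: dict[tuple[int, int], str] = {}  # (probe, sample) -> direction
    for k, ev in enumerate(spec.events):
        carriers = np.flatnonzero(rng.random(spec.n_samples) < ev.prevalence)
        lo = chrom_offset[ev.chromosome] + ev.probe_start
        hi = chrom_offset[ev.chromosome] + ev.probe_end
        overlapped = False
        for j in carriers:
            for p in range(lo, hi + 1):
                if touched.get((p, j)) == ev.direction:
                    overlapped = True
                touched[(p, j)] = ev.direction
            signal[lo : hi + 1, j] += ev.amplitude
        truth_rows.append(
            {
                "event": k,
                "chromosome": ev.chromosome,
                "probe_start": ev.probe_start,
                "probe_end": ev.probe_end,
                "start_bp": int(probes["start_bp"].iloc[lo]),
                "end_bp": int(probes["end_bp"].iloc[hi]),
                "direction": ev.direction,
                "amplitude": ev.amplitude,
                "prevalence": ev.prevalence,
                "high_level": ev.high_level,
                "carriers": ",".join(sample_ids[j] for j in carriers),
                "n_carriers": len(carriers),
                "overlaps_other_event": overlapped,
            }
        )
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
    log2 = pd.DataFrame(signal + noise, columns=sample_ids)
    return ProbeMatrix.from_frames(probes, log2), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Reference segmenter


def _best_split(x: np.ndarray, min_seg: int) -> tuple[int, float] | None:
    """Best binary split position and its two-sided p (pooled t test)."""
    n = len(x)
    if n < 2 * min_seg:
        return None
    ks = np.arange(min_seg, n - min_seg + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = csum[ks - 1]
    ss1 = csq[ks - 1]
    m1 = s1 / n1
    m2 = (csum[-1] - s1) / n2
    rss = (ss1 - n1 * m1**2) + (csq[-1] - ss1 - n2 * m2**2)
    pooled = np.maximum(rss / (n - 2), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1 / n1 + 1 / n2))
        tstat = np.abs(m1 - m2) / se
    # se == 0 (constant halves): a genuine mean difference is an infinitely
    # strong split, numerical dust is not
    same = np.abs(m1 - m2) <= 1e-12 * (1.0 + np.abs(m1) + np.abs(m2))
    tstat = np.where(se <= 1e-12, np.where(same, 0.0, np.inf), tstat)
    best = int(np.argmax(tstat))
    p = float(2.0 * t_dist.sf(tstat[best], df=n - 2)) if np.isfinite(tstat[best]) else 0.0
    return int(ks[best]), p


def _split_recursive(x: np.ndarray, lo: int, hi: int, min_seg: int, alpha: float, breaks: list[int]) -> None:
    res = _best_split(x[lo:hi], min_seg)
    if res is None:
        return
    k, p = res
    if p >= alpha:
        return
    breaks.append(lo + k)
    _split_recursive(x, lo, lo + k, min_seg, alpha, breaks)
    _split_recursive(x, lo + k, hi, min_seg, alpha, breaks)


def naive_segment(
    probes: ProbeMatrix,
    min_seg: int = 3,
    alpha: float = 1e-4,
    method: str = "naive",
) -> SegmentSet:
    """Reference segmentation by recursive binary mean-shift splitting.

    Per sample and chromosome, the split maximising the pooled
    two-sample t statistic is accepted while its p value is below
    ``alpha`` and both parts retain at least ``min_seg`` probes.
    Segments carry their mean log2 ratio and probe count, and tile each
    chromosome without gaps.
    """
    if min_seg < 2:
        raise ValueError("min_seg must be >= 2")
    rows = []
    for sample in probes.sample_ids:
        x_all = probes.log2[sample].to_numpy()
        for chrom in probes.chromosomes:
            idx = probes.chromosome_index(chrom)
            x = x_all[idx]
            breaks: list[int] = []
            _split_recursive(x, 0, len(x), min_seg, alpha, breaks)
            rows.extend(
                _segments_from_breaks(probes, chrom, sample, method, x, sorted(breaks))
            )
    return SegmentSet(pd.DataFrame(rows, columns=SegmentSet.COLUMNS))


def _segments_from_breaks(
    probes: ProbeMatrix,
    chrom: str,
    sample: str,
    method: str,
    x: np.ndarray,
    breaks: list[int],
) -> list[dict]:
    """Contiguous bp segments from chromosome-local probe break indices."""
    idx = probes.chromosome_index(chrom)
    starts_bp = probes.probes["start_bp"].to_numpy()[idx]
    ends_bp = probes.probes["end_bp"].to_numpy()[idx]
    bounds = [0, *breaks, len(x)]
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        rows.append(
            {
                "method": method,
                "sample": sample,
                "chromosome": chrom,
                "start_bp": int(starts_bp[lo]),
                "end_bp": int(starts_bp[hi]) if hi < len(x) else int(ends_bp[-1]) + 1,
                "probe_count": hi - lo,
                "seg_mean": float(np.mean(x[lo:hi])),
            }
        )
    return rows


def perturb_segments(
    segset: SegmentSet,
    jitter: int,
    seed: int,
    probes: ProbeMatrix,
    method: str = "perturbed",
) -> SegmentSet:
    """Jitter breakpoints by seeded uniform probe offsets in [-jitter, jitter].

    Segment means are recomputed from the probe matrix. Segments squeezed
    to zero probes by the jitter are dropped with a warning (their span
    is absorbed by a neighbour), emulating a segmentation method that
    disagrees with the original about breakpoint placement.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for (sample, chrom), grp in segset.df.groupby(["sample", "chromosome"], sort=False):
        grp = grp.sort_values("start_bp")
        idx = probes.chromosome_index(chrom)
        starts_bp = probes.probes["start_bp"].to_numpy()[idx]
        x = probes.log2[sample].to_numpy()[idx]
        # internal breakpoints in probe-index space
        breaks = [
            int(np.searchsorted(starts_bp, bp)) for bp in grp["start_bp"].iloc[1:]
        ]
        if jitter > 0 and breaks:
            breaks = [int(np.clip(b + rng.integers(-jitter, jitter + 1), 1, len(x) - 1)) for b in breaks]
        uniq = sorted(set(breaks))
        n_dropped += len(breaks) - len(uniq)
        rows.extend(_segments_from_breaks(probes, chrom, sample, method, x, uniq))
    if n_dropped:
        logger.warning("perturb_segments: %d degenerate segments dropped", n_dropped)
    return SegmentSet(pd.DataFrame(rows, columns=SegmentSet.COLUMNS))


def write_simulation(
    spec: SimSpec,
    out_dir,
    n_methods: int = 3,
    jitter: int = 2,
    gene_bed: bool = True,
) -> dict[str, str]:
    """Write a complete simulated input set: probe TSV, SEG files, truth, genes.

    ``n_methods`` SEG files are produced: the reference segmentation plus
    jittered copies, emulating disagreeing segmentation algorithms.
    """
    from pathlib import Path

    from .io_formats import write_probe_matrix, write_segments

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pm, truth = simulate_cohort(spec)
    paths = {"probes": str(out / "probes.tsv"), "truth": str(out / "truth.tsv")}
    write_probe_matrix(pm, paths["probes"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    base = naive_segment(pm, method="method1")
    write_segments(base, out / "method1.seg")
    paths["segments"] = [str(out / "method1.seg")]
    for k in range(2, n_methods + 1):
        perturbed = perturb_segments(base, jitter, spec.seed + k, pm, method=f"method{k}")
        write_segments(perturbed, out / f"method{k}.seg")
        paths["segments"].append(str(out / f"method{k}.seg"))
    if gene_bed:
        rng = np.random.default_rng(spec.seed + 1000)
        genes_path = out / "genes.bed"
        with open(genes_path, "w") as fh:
            g = 0
            for row in truth.itertuples():
                # a few genes inside each planted event, so GDW is exercised
                for _ in range(3):
                    start = int(rng.integers(row.start_bp, max(row.start_bp + 1, row.end_bp - 1)))
                    end = min(row.end_bp, start + 50_000)
                    g += 1
                    fh.write(f"{row.chromosome}\t{start}\t{end}\tGENE{g}\t0\t+\n")
        paths["genes"] = str(genes_path)
    return paths
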