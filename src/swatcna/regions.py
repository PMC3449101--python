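"""Adaptive thresholds and extraction of contiguous/minimum regions of interest.

For each chromosome and direction, an adaptive threshold (AT) is chosen
from a descending ladder (default 80..20 % in 10 % steps) so that the
windows passing the threshold cover approximately ``target_coverage``
(default 5 %) of the chromosome's probes per direction — about 10 % of
the chromosome in total. Chromosomes rich in aberration therefore get a
stringent threshold while quieter chromosomes are probed at lower
stringency, letting low-prevalence but recurrent aberrations surface.

Consecutive gated windows merge into contiguous regions of interest
(CRIs); within each CRI the probes reaching its maximum recurrence form
one or more minimum regions of interest (MRIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ProbeMatrix, RunConfig
from .windows import DIRECTIONS, TrackSet, WindowScoreTrack, consistency_filter

NO_CNA = "none"


@dataclass
class AdaptiveThresholdResult:
    chromosome: str
    direction: str
    chosen_at: float | str  # ladder percentage, or "none" when the chromosome is CNA-free
    coverage: float  # fraction of chromosome probes inside gated windows


@dataclass
class MRI:
    """Minimum region of interest: smallest span at the CRI's peak recurrence."""

    chromosome: str
    direction: str
    probe_start: int  # chromosome-local, 0-based inclusive
    probe_end: int
    start_bp: int
    end_bp: int
    recurrence: float  # peak PWS as a fraction of samples
    window_size: int
    index: int = 0
    cri_index: int = 0
    mean_intensity: float = float("nan")

    @property
    def probe_count(self) -> int:
        return self.probe_end - self.probe_start + 1

    @property
    def peak_pws(self) -> float:
        return self.recurrence * 100.0


@dataclass
class CRI:
    """Contiguous region of unbroken consensually imbalanced probes."""

    chromosome: str
    direction: str
    probe_start: int
    probe_end: int
    start_bp: int
    end_bp: int
    index: int  # serial within chromosome+direction, genome order
    peak_pws: float
    window_size: int
    at: float | str = NO_CNA
    mris: list[MRI] = field(default_factory=list)

    @property
    def probe_count(self) -> int:
        return self.probe_end - self.probe_start + 1


# ---------------------------------------------------------------------------


def coverage_at(track: WindowScoreTrack, at: float) -> float:
    """Fraction of chromosome probes covered by windows with PWS >= at."""
    if len(track.scores) == 0:
        return 0.0
    gated = gate_windows(track, at)
    covered = np.zeros(track.n_probes, dtype=bool)
    w = track.window_size
    for start in np.flatnonzero(gated):
        covered[start : start + w] = True
    return float(covered.sum()) / track.n_probes


def select_adaptive_threshold(
    track: WindowScoreTrack,
    ladder: tuple[float, ...],
    target_coverage: float,
) -> AdaptiveThresholdResult:
    """Choose the threshold gating ~``target_coverage`` of the chromosome.

    The ladder is scanned from the most stringent value down; the first
    (highest) threshold whose gated windows cover at least the target
    fraction of probes is selected. If no ladder value reaches the
    target, the least stringent value is accepted provided it gates
    anything at all; otherwise the chromosome is deemed CNA-free.
    """
    if list(ladder) != sorted(ladder, reverse=True):
        raise ValueError("threshold ladder must be strictly decreasing")
    if len(track.scores) == 0:
        return AdaptiveThresholdResult(track.chromosome, track.direction, NO_CNA, 0.0)
    for at in ladder:
        cov = coverage_at(track, at)
        if cov >= target_coverage:
            return AdaptiveThresholdResult(track.chromosome, track.direction, at, cov)
    lowest = ladder[-1]
    cov = coverage_at(track, lowest)
    if cov > 0.0:
        return AdaptiveThresholdResult(track.chromosome, track.direction, lowest, cov)
    return AdaptiveThresholdResult(track.chromosome, track.direction, NO_CNA, 0.0)


def gate_windows(track: WindowScoreTrack, at: float | str) -> np.ndarray:
    """Boolean vector over window starts: gated iff PWS >= at (inclusive)."""
    if at == NO_CNA:
        return np.zeros(len(track.scores), dtype=bool)
    if not (0 < float(at) <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    return track.scores >= float(at)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    out: list[tuple[int, int]] = []
    where = np.flatnonzero(mask)
    if where.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(where) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [where.size - 1]])
    for s, e in zip(starts, ends):
        out.append((int(where[s]), int(where[e])))
    return out


def extract_cris(
    gated: np.ndarray, track: WindowScoreTrack, probes: ProbeMatrix
) -> list[CRI]:
    """Convert runs of gated windows into serially indexed CRIs.

    Each run of consecutive gated windows spans the union of its member
    windows' probes; unions that overlap or abut (runs separated by fewer
    probes than the window size) merge into a single CRI.
    """
    w = track.window_size
    spans: list[tuple[int, int]] = []
    for first, last in _runs(gated):
        lo, hi = first, last + w - 1  # probe union of the run
        if spans and lo <= spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
        else:
            spans.append((lo, hi))
    idx = probes.chromosome_index(track.chromosome)
    starts_bp = probes.probes["start_bp"].to_numpy()[idx]
    ends_bp = probes.probes["end_bp"].to_numpy()[idx]
    cris = []
    for serial, (lo, hi) in enumerate(spans, start=1):
        member = np.arange(max(0, lo - w + 1), min(len(track.scores), hi + 1))
        member = member[gated[member]]
        peak = float(track.scores[member].max()) if member.size else 0.0
        cri = CRI(
            chromosome=track.chromosome,
            direction=track.direction,
            probe_start=lo,
            probe_end=hi,
            start_bp=int(starts_bp[lo]),
            end_bp=int(ends_bp[hi]),
            index=serial,
            peak_pws=peak,
            window_size=w,
        )
        cri.mris = extract_mris(cri, track, probes)
        cris.append(cri)
    return cris


def extract_mris(cri: CRI, track: WindowScoreTrack, probes: ProbeMatrix) -> list[MRI]:
    """Smallest probe spans within a CRI attaining its maximum recurrence.

    Member windows are those lying wholly inside the CRI span. Windows
    achieving the maximum PWS chain together when they overlap by at
    least one probe; each chain contributes one MRI covering the probes
    of its member windows. A CRI with flat PWS therefore yields a single
    MRI identical to the CRI; separated maxima yield several MRIs.
    """
    w = track.window_size
    lo, hi = cri.probe_start, cri.probe_end
    member = np.arange(lo, hi - w + 2)
    member = member[(member >= 0) & (member < len(track.scores))]
    if member.size == 0:
        return [
            MRI(
                cri.chromosome, cri.direction, lo, hi, cri.start_bp, cri.end_bp,
                cri.peak_pws / 100.0, w, index=1, cri_index=cri.index,
            )
        ]
    m = track.scores[member].max()
    top = member[track.scores[member] == m]
    idx = probes.chromosome_index(cri.chromosome)
    starts_bp = probes.probes["start_bp"].to_numpy()[idx]
    ends_bp = probes.probes["end_bp"].to_numpy()[idx]
    mris: list[MRI] = []
    chain_start = top[0]
    prev = top[0]
    chains: list[tuple[int, int]] = []
    for s in top[1:]:
        if s - prev <= w - 1:  # windows share >= 1 probe
            prev = s
        else:
            chains.append((chain_start, prev))
            chain_start = prev = s
    chains.append((chain_start, prev))
    for serial, (first, last) in enumerate(chains, start=1):
        p_lo, p_hi = int(first), int(last + w - 1)
        mris.append(
            MRI(
                chromosome=cri.chromosome,
                direction=cri.direction,
                probe_start=p_lo,
                probe_end=p_hi,
                start_bp=int(starts_bp[p_lo]),
                end_bp=int(ends_bp[p_hi]),
                recurrence=float(m) / 100.0,
                window_size=w,
                index=serial,
                cri_index=cri.index,
            )
        )
    return mris


def mean_intensity(mri: MRI, probes: ProbeMatrix) -> float:
    """Mean log2 ratio over the MRI's probes across all samples."""
    idx = probes.chromosome_index(mri.chromosome)
    block = probes.log2.to_numpy()[idx[mri.probe_start : mri.probe_end + 1]]
    if np.isnan(block).all():
        raise ValueError("all log2 values missing over the MRI span")
    return float(np.nanmean(block))


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class RegionAnalysis:
    """Regions and thresholds detected at one window size."""

    window_size: int
    thresholds: dict[tuple[str, str], AdaptiveThresholdResult]
    cris: list[CRI]

    @property
    def mris(self) -> list[MRI]:
        return [m for c in self.cris for m in c.mris]

    def cris_for(self, chromosome: str, direction: str) -> list[CRI]:
        return [c for c in self.cris if c.chromosome == chromosome and c.direction == direction]


def detect_regions(
    tracks: TrackSet,
    probes: ProbeMatrix,
    config: RunConfig,
    w: int,
    apply_consistency: bool = True,
) -> RegionAnalysis:
    """Full region extraction at one window size.

    Thresholds are selected independently per chromosome and direction;
    CRIs/MRIs are extracted from the gated windows and annotated with
    mean intensity. For window sizes above the smallest configured size,
    regions failing the cross-window-size consistency check (every MRI
    probe re-detected by a smaller window at equal or higher recurrence)
    are discarded.
    """
    thresholds: dict[tuple[str, str], AdaptiveThresholdResult] = {}
    cris: list[CRI] = []
    w_min = min(config.window_sizes)
    for chromosome in probes.chromosomes:
        for direction in DIRECTIONS:
            track = tracks.get(chromosome, w, direction)
            at_result = select_adaptive_threshold(
                track, config.at_ladder, config.target_coverage
            )
            thresholds[(chromosome, direction)] = at_result
            if at_result.chosen_at == NO_CNA:
                continue
            gated = gate_windows(track, at_result.chosen_at)
            chrom_cris = extract_cris(gated, track, probes)
            for cri in chrom_cris:
                cri.at = at_result.chosen_at
                for mri in cri.mris:
                    mri.mean_intensity = mean_intensity(mri, probes)
            if apply_consistency and w > w_min:
                chrom_cris = [
                    cri
                    for cri in chrom_cris
                    if all(
                        consistency_filter(
                            (mri.probe_start, mri.probe_end),
                            cri.peak_pws,
                            chromosome,
                            direction,
                            w,
                            tracks,
                            config.window_sizes,
                        )
                        for mri in cri.mris
                    )
                ]
                for serial, cri in enumerate(chrom_cris, start=1):
                    cri.index = serial
            cris.extend(chrom_cris)
    return RegionAnalysis(window_size=w, thresholds=thresholds, cris=cris)


def regions_table(analysis: RegionAnalysis):
    """CRI/MRI summary as a DataFrame in genome order (1-based positions)."""
    import pandas as pd

    rows = []
    for cri in analysis.cris:
        for mri in cri.mris:
            rows.append(
                {
                    "chromosome": cri.chromosome,
                    "direction": cri.direction,
                    "cri_index": cri.index,
                    "mri_index": mri.index,
                    "cri_span_bp": f"{cri.start_bp + 1}-{cri.end_bp}",
                    "mri_span_bp": f"{mri.start_bp + 1}-{mri.end_bp}",
                    "cri_probes": cri.probe_count,
                    "mri_probes": mri.probe_count,
                    "at": cri.at,
                    "peak_pws": cri.peak_pws,
                    "recurrence": mri.recurrence,
                    "mean_intensity": mri.mean_intensity,
                }
            )
    return pd.DataFrame(rows)
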