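"""Sliding probe-window scoring (PWS).

For every chromosome, window size w and direction (gain/loss), the probe
window score of the window starting at probe i is the percentage of
samples whose direction call equals the track direction at ALL probes
i..i+w-1. Windows advance by a single probe; no partial windows are
scored at chromosome ends, so a chromosome of n probes yields n - w + 1
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ProbeMatrix, RunConfig

logger = logging.getLogger("swatcna")

DIRECTIONS = ("gain", "loss")
_DIR_VALUE = {"gain": 1, "loss": -1}


@dataclass
class WindowScoreTrack:
    """PWS values for one (chromosome, window size, direction)."""

    chromosome: str
    window_size: int
    direction: str  # 'gain' | 'loss'
    scores: np.ndarray  # percentage per window start, length n_probes - w + 1
    n_samples: int

    @property
    def n_probes(self) -> int:
        return len(self.scores) + self.window_size - 1 if len(self.scores) else 0

    def windows_covering(self, probe: int) -> np.ndarray:
        """Window start indices whose span includes the given probe index."""
        lo = max(0, probe - self.window_size + 1)
        hi = min(len(self.scores) - 1, probe)
        return np.arange(lo, hi + 1)


def compute_pws(
    direction_table: pd.DataFrame,
    probes: ProbeMatrix,
    chromosome: str,
    w: int,
    direction: str,
) -> WindowScoreTrack:
    """Score all w-probe sliding windows of one chromosome in one direction.

    ``direction_table`` is the probe x sample {-1,0,1} matrix aligned with
    ``probes``. A sample counts for a window only if every probe of the
    window carries the track's direction; a sample mixing gain and loss
    within the window counts for neither direction.
    """
    if w < 2:
        raise ValueError("window size must be >= 2")
    idx = probes.chromosome_index(chromosome)
    values = direction_table.to_numpy()[idx]
    n_probes, n_samples = values.shape
    if n_probes < w:
        logger.warning(
            "chromosome %s has %d probes < window size %d: empty track",
            chromosome, n_probes, w,
        )
        return WindowScoreTrack(chromosome, w, direction, np.empty(0), n_samples)
    concordant = values == _DIR_VALUE[direction]
    # window is all-concordant iff the running sum over w probes equals w
    csum = np.cumsum(np.vstack([np.zeros(n_samples, dtype=np.int64), concordant]), axis=0)
    win_counts = csum[w:] - csum[:-w]  # (n_windows, n_samples)
    all_true = win_counts == w
    scores = 100.0 * all_true.sum(axis=1) / n_samples
    return WindowScoreTrack(chromosome, w, direction, scores, n_samples)


@dataclass
class TrackSet:
    """All tracks of an analysis, keyed by (chromosome, window size, direction)."""

    tracks: dict[tuple[str, int, str], WindowScoreTrack] = field(default_factory=dict)

    def get(self, chromosome: str, w: int, direction: str) -> WindowScoreTrack:
        return self.tracks[(chromosome, w, direction)]

    def add(self, track: WindowScoreTrack) -> None:
        self.tracks[(track.chromosome, track.window_size, track.direction)] = track

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks.values())


def compute_all_tracks(
    direction_table: pd.DataFrame, probes: ProbeMatrix, config: RunConfig
) -> TrackSet:
    """One :class:`WindowScoreTrack` per (chromosome, configured size, direction)."""
    out = TrackSet()
    for chromosome in probes.chromosomes:
        for w in config.window_sizes:
            for direction in DIRECTIONS:
                out.add(compute_pws(direction_table, probes, chromosome, w, direction))
    return out


def consistency_filter(
    mri_probe_span: tuple[int, int],
    peak_pws: float,
    chromosome: str,
    direction: str,
    w: int,
    tracks: TrackSet,
    window_sizes: tuple[int, ...],
) -> bool:
    """Cross-window-size consistency check for a region detected at size w.

    Regions found with larger windows must also be present in internal
    smaller windows at equal or higher recurrence: the region is retained
    iff, for every configured size w' < w, every probe of the region's MRI
    span (chromosome-local indices, inclusive) is covered by at least one
    w'-window whose PWS >= the region's peak PWS at size w.
    """
    lo, hi = mri_probe_span
    for w_small in window_sizes:
        if w_small >= w:
            continue
        track = tracks.get(chromosome, w_small, direction)
        if len(track.scores) == 0:
            return False
        for probe in range(lo, hi + 1):
            covering = track.windows_covering(probe)
            if covering.size == 0 or not (track.scores[covering] >= peak_pws).any():
                return False
    return True


def export_bedgraph(track: WindowScoreTrack, probes: ProbeMatrix, path) -> None:
    """Write one track as bedGraph (per-window score over the window span)."""
    idx = probes.chromosome_index(track.chromosome)
    starts = probes.probes["start_bp"].to_numpy()[idx]
    ends = probes.probes["end_bp"].to_numpy()[idx]
    w = track.window_size
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="PWS {track.chromosome} w={w} {track.direction}"\n'
        )
        for i, score in enumerate(track.scores):
            fh.write(f"{track.chromosome}\t{starts[i]}\t{ends[i + w - 1]}\t{score:g}\n")
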