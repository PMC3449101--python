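"""Five-point classification of segmented copy number states.

Each probe of each sample receives an integer call from
{-2, -1, 0, 1, 2} = {high-level loss, loss, normal, gain,
high-level gain/amplification}. A segment is abnormal when the absolute
segment mean exceeds a per-sample threshold derived from the difference
between the middle fifty (inter-quartile range) of the observed log2
ratios and the middle fifty of the segment-predicted values, scaled by a
factor change (default 0.75). Abnormal segments spanning at most
``highlevel_max_width`` probes are called high-level (+/-2); wider
abnormal segments are single-copy (+/-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ProbeMatrix, RunConfig, SegmentSet

logger = logging.getLogger("swatcna")

CALL_VALUES = (-2, -1, 0, 1, 2)


@dataclass
class ClassificationTable:
    """Probe x sample integer call matrix sharing the ProbeMatrix index."""

    calls: pd.DataFrame  # int8, index = probe positions, columns = samples

    def __post_init__(self) -> None:
        bad = ~self.calls.isin(CALL_VALUES)
        if bad.to_numpy().any():
            raise ValueError("classification calls must be in {-2,-1,0,1,2}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def to_tsv(self, path) -> None:
        """Dump as TSV: probe rows, sample columns, integer calls."""
        self.calls.to_csv(path, sep="\t", index_label="probe")


def iqr(values: np.ndarray) -> float:
    """Inter-quartile range with linearly interpolated (type-7) quartiles."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


def nud_threshold(
    observed: np.ndarray, predicted: np.ndarray, factor_change: float
) -> float:
    """Per-sample abnormality threshold in log2 units.

    T = |IQR(observed) - IQR(predicted)| * factor_change. Observed values
    are the sample's normalised log2 ratios; predicted values are the
    segment means propagated to every probe of the sample.
    """
    observed = np.asarray(observed, dtype=float)
    if observed[~np.isnan(observed)].size < 4:
        raise ValueError("need at least 4 observations to compute quartiles")
    t = abs(iqr(observed) - iqr(np.asarray(predicted, dtype=float))) * factor_change
    if t == 0.0:
        logger.warning("abnormality threshold is 0: every non-zero segment will be called")
    return t


def predicted_values(
    segments: pd.DataFrame, probes: ProbeMatrix, sample: str
) -> np.ndarray:
    """Segment means propagated to each probe of one sample.

    A probe belongs to the segment whose [start_bp, end_bp) interval
    contains its start coordinate. Raises if any probe is uncovered.
    """
    pred = np.full(probes.n_probes, np.nan)
    seg = segments.loc[segments["sample"] == sample]
    for chrom, grp in seg.groupby("chromosome", sort=False):
        idx = probes.chromosome_index(chrom)
        if idx.size == 0:
            continue
        pos = probes.probes["start_bp"].to_numpy()[idx]
        grp = grp.sort_values("start_bp")
        starts = grp["start_bp"].to_numpy()
        ends = grp["end_bp"].to_numpy()
        means = grp["seg_mean"].to_numpy()
        which = np.searchsorted(starts, pos, side="right") - 1
        ok = (which >= 0) & (pos < ends[np.clip(which, 0, len(ends) - 1)])
        if not ok.all():
            miss = probes.probes["probe_id"].to_numpy()[idx[~ok]][0]
            raise ValueError(f"probe {miss!r} (sample {sample}) not covered by any segment")
        pred[idx] = means[which]
    if np.isnan(pred).any():
        miss = probes.probes["probe_id"].to_numpy()[np.isnan(pred)][0]
        raise ValueError(f"probe {miss!r} (sample {sample}) not covered by any segment")
    return pred


def classify_segments(
    segments: SegmentSet, probes: ProbeMatrix, config: RunConfig
) -> ClassificationTable:
    """Classify every probe of every sample from one method's segments.

    Per sample: a segment is abnormal iff |segment_mean| > T where T comes
    from :func:`nud_threshold`; abnormal segments of width at most
    ``config.highlevel_max_width`` probes are called +/-2, wider ones
    +/-1, sign from the segment mean. Normal segments are 0. Width is
    counted in probes actually covered on the array, not the SEG field.
    """
    if len(segments.methods) > 1:
        raise ValueError("classify_segments expects segments from a single method")
    calls = np.zeros((probes.n_probes, probes.n_samples), dtype=np.int8)
    seg_df = segments.df
    for j, sample in enumerate(probes.sample_ids):
        observed = probes.log2[sample].to_numpy()
        pred = predicted_values(seg_df, probes, sample)
        t = nud_threshold(observed, pred, config.factor_change)
        sample_segs = seg_df.loc[seg_df["sample"] == sample]
        for chrom, grp in sample_segs.groupby("chromosome", sort=False):
            idx = probes.chromosome_index(chrom)
            if idx.size == 0:
                continue
            pos = probes.probes["start_bp"].to_numpy()[idx]
            for _, seg in grp.iterrows():
                inside = idx[(pos >= seg["start_bp"]) & (pos < seg["end_bp"])]
                if inside.size == 0:
                    continue
                mean = float(seg["seg_mean"])
                if abs(mean) <= t:
                    continue
                sign = 1 if mean > 0 else -1
                high = inside.size <= config.highlevel_max_width
                if high and config.highlevel_amplitude_gate:
                    high = abs(mean) > 2.0 * t
                calls[inside, j] = sign * (2 if high else 1)
    return ClassificationTable(
        calls=pd.DataFrame(calls, index=probes.probes.index, columns=probes.sample_ids)
    )


def collapse_direction(table: ClassificationTable) -> pd.DataFrame:
    """Collapse the 5-point calls to direction {-1, 0, 1}.

    Gain is combined with amplification and loss with high-level loss.
    """
    return np.sign(table.calls).astype(np.int8)
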