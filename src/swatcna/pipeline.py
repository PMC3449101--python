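"""End-to-end orchestration: segments in, prioritized consensus regions out."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassificationTable, classify_segments, collapse_direction
from .consensus_cluster import (
    ClusterResult,
    ConsensusRegion,
    cluster_samples,
    consensus_merge,
    intersect_prioritizations,
)
from .io_formats import GeneAnnotation, ProbeMatrix, RunConfig, SegmentSet
from .prioritize import (
    PrioritizedMRI,
    amplitude_filter,
    annotate_gene_scores,
    gdw_rank,
)
from .regions import RegionAnalysis, detect_regions
from .windows import TrackSet, compute_all_tracks

logger = logging.getLogger("swatcna")


@dataclass
class MethodResult:
    """Artifacts of one segmentation method's analysis at one window size."""

    method: str
    calls: ClassificationTable
    tracks: TrackSet
    analysis: RegionAnalysis
    amplitude_list: list[PrioritizedMRI] = field(default_factory=list)
    gdw_list: list[PrioritizedMRI] = field(default_factory=list)


@dataclass
class RunResult:
    probes: ProbeMatrix
    config: RunConfig
    per_method: dict[str, MethodResult]
    consensus_amplitude: list[ConsensusRegion] = field(default_factory=list)
    consensus_gdw: list[ConsensusRegion] = field(default_factory=list)
    consensus_final: list[ConsensusRegion] = field(default_factory=list)
    cluster: ClusterResult | None = None


def analyse_method(
    method: str,
    segments: SegmentSet,
    probes: ProbeMatrix,
    config: RunConfig,
    genes: GeneAnnotation | None = None,
    w: int | None = None,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """Classification, window scoring, region extraction and prioritization
    for one segmentation method at one window size (default: smallest)."""
    t0 = time.perf_counter()
    w = w if w is not None else min(config.window_sizes)
    calls = classify_segments(segments, probes, config)
    direction = collapse_direction(calls)
    tracks = compute_all_tracks(direction, probes, config)
    analysis = detect_regions(tracks, probes, config, w)
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    amplitude_list = amplitude_filter(analysis.mris, probes, config, rng)
    gdw_list = []
    if genes is not None:
        gdw_list = gdw_rank(annotate_gene_scores(list(amplitude_list), genes))
    logger.info("method %s analysed in %.2fs (%d CRIs, %d significant MRIs)",
                method, time.perf_counter() - t0, len(analysis.cris), len(amplitude_list))
    return MethodResult(
        method=method,
        calls=calls,
        tracks=tracks,
        analysis=analysis,
        amplitude_list=amplitude_list,
        gdw_list=gdw_list,
    )


def run_pipeline(
    probes: ProbeMatrix,
    segment_sets: dict[str, SegmentSet],
    config: RunConfig,
    genes: GeneAnnotation | None = None,
    cluster_method: str | None = None,
) -> RunResult:
    """Full analysis across segmentation methods.

    Per method: classify, score windows, extract regions, prioritize.
    Across methods: consensus-merge both prioritized lists, intersect
    them, and cluster samples on the stringent CRIs of one method
    (``cluster_method``, default the first).
    """
    probes = probes.impute_missing()
    rng = np.random.default_rng(config.rng_seed)
    per_method = {
        name: analyse_method(name, segs, probes, config, genes, rng=rng)
        for name, segs in segment_sets.items()
    }
    result = RunResult(probes=probes, config=config, per_method=per_method)
    if len(per_method) >= 2:
        amp = {m: [pm.mri for pm in r.amplitude_list] for m, r in per_method.items()}
        result.consensus_amplitude = consensus_merge(amp, config.consensus_min_methods)
        if genes is not None:
            gdw = {m: [pm.mri for pm in r.gdw_list] for m, r in per_method.items()}
            result.consensus_gdw = consensus_merge(gdw, config.consensus_min_methods)
            result.consensus_final = intersect_prioritizations(
                result.consensus_amplitude, result.consensus_gdw
            )
    cluster_on = cluster_method or next(iter(per_method))
    ref = per_method[cluster_on]
    try:
        result.cluster = cluster_samples(
            ref.calls,
            ref.analysis.cris,
            min_at=config.cluster_min_at,
            n_groups=config.cluster_groups,
            probes=probes,
        )
    except ValueError as exc:
        logger.warning("clustering skipped: %s", exc)
    return result


def write_outputs(result: RunResult, out_dir: str | Path, genes=None) -> None:
    """Write per-method tables, consensus tables and the cluster tree."""
    from .consensus_cluster import consensus_table, region_heatmap_matrix
    from .io_formats import write_regions_bed
    from .prioritize import prioritized_table
    from .regions import regions_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for method, res in result.per_method.items():
        regions_table(res.analysis).to_csv(out / f"{method}_regions.tsv", sep="\t", index=False)
        prioritized_table(res.amplitude_list).to_csv(
            out / f"{method}_amplitude.tsv", sep="\t", index=False
        )
        if res.gdw_list:
            prioritized_table(res.gdw_list).to_csv(
                out / f"{method}_gdw.tsv", sep="\t", index=False
            )
        write_regions_bed(res.analysis.cris, out / f"{method}_cris.bed")
    if result.consensus_final:
        consensus_table(result.consensus_final, genes).to_csv(
            out / "consensus.tsv", sep="\t", index=False
        )
        first = next(iter(result.per_method.values()))
        region_heatmap_matrix(first.calls, result.consensus_final, result.probes).to_csv(
            out / "consensus_heatmap.tsv", sep="\t"
        )
    if result.cluster is not None:
        (out / "sample_tree.nwk").write_text(result.cluster.to_newick() + "\n")
        result.cluster.labels.to_csv(out / "sample_groups.tsv", sep="\t")
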