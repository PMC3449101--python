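"""Cross-method consensus of MRIs and sample clustering on gated CRIs.

Regions flagged independently by multiple segmentation methods are more
trustworthy than any single method's call. Same-direction MRIs from
different methods that overlap by at least one base pair are pooled
transitively; pools supported by at least ``consensus_min_methods``
distinct methods become consensus regions. A final set intersects the
consensus regions of the amplitude-based list with those of the
gene-density-weighted list.

Sample structure is explored by agglomerative hierarchical clustering of
the 5-point classification calls restricted to probes of CRIs whose
adaptive threshold met a minimum stringency (default 40 %); Euclidean
distance with Ward linkage by default, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .classify import ClassificationTable
from .io_formats import _CHROM_ORDER, ProbeMatrix
from .regions import CRI, MRI


@dataclass
class ConsensusRegion:
    chromosome: str
    direction: str
    start_bp: int  # merged span = union of member MRI spans
    end_bp: int
    methods: frozenset[str]
    members: dict[str, list[MRI]] = field(default_factory=dict)
    in_amplitude_list: bool = False
    in_gdw_list: bool = False

    def overlaps(self, other: "ConsensusRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.direction == other.direction
            and self.start_bp < other.end_bp
            and other.start_bp < self.end_bp
        )


def consensus_merge(
    per_method: dict[str, list[MRI]], min_methods: int = 2
) -> list[ConsensusRegion]:
    """Pool overlapping same-direction MRIs across methods.

    MRIs from different methods overlapping by >= 1 bp merge
    transitively (an interval-sweep per chromosome and direction); pools
    supported by at least ``min_methods`` distinct methods survive.
    Output is in genome order; the result does not depend on the order
    of methods or of MRIs within a method.
    """
    if len(per_method) < 2:
        raise ValueError("consensus requires MRI lists from at least 2 methods")
    records = []
    for method, mris in per_method.items():
        for mri in mris:
            records.append((mri.chromosome, mri.direction, mri.start_bp, mri.end_bp, method, mri))
    out: list[ConsensusRegion] = []
    df = pd.DataFrame(records, columns=["chrom", "dir", "start", "end", "method", "mri"])
    for (chrom, direction), grp in df.groupby(["chrom", "dir"], sort=False):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        pool_start = pool_end = None
        pool: list[tuple[str, MRI]] = []

        def flush():
            methods = frozenset(m for m, _ in pool)
            if len(methods) >= min_methods:
                members: dict[str, list[MRI]] = {}
                for m, mri in pool:
                    members.setdefault(m, []).append(mri)
                out.append(
                    ConsensusRegion(
                        chromosome=chrom,
                        direction=direction,
                        start_bp=pool_start,
                        end_bp=pool_end,
                        methods=methods,
                        members=members,
                    )
                )

        for row in grp.itertuples():
            if pool_start is None:
                pool_start, pool_end, pool = row.start, row.end, [(row.method, row.mri)]
            elif row.start < pool_end:  # >= 1 bp overlap, transitive
                pool_end = max(pool_end, row.end)
                pool.append((row.method, row.mri))
            else:
                flush()
                pool_start, pool_end, pool = row.start, row.end, [(row.method, row.mri)]
        if pool_start is not None:
            flush()
    out.sort(key=lambda r: (_CHROM_ORDER.get(r.chromosome, 99), r.start_bp))
    return out


def intersect_prioritizations(
    amplitude_regions: list[ConsensusRegion],
    gdw_regions: list[ConsensusRegion],
) -> list[ConsensusRegion]:
    """Keep consensus regions present in both prioritized lists.

    A region survives iff it overlaps (>= 1 bp, same chromosome and
    direction) a member of the other list; survivors from the amplitude
    list are returned with both membership flags set.
    """
    final = []
    for region in amplitude_regions:
        if any(region.overlaps(other) for other in gdw_regions):
            region.in_amplitude_list = True
            region.in_gdw_list = True
            final.append(region)
    return final


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray  # scipy linkage encoding of the sample tree
    labels: pd.Series  # group assignment per sample at the requested cut
    feature_probes: np.ndarray  # global probe indices used as features
    sample_ids: list[str]

    @property
    def n_groups(self) -> int:
        return int(self.labels.nunique())

    def to_newick(self) -> str:
        """Sample tree in Newick format (branch lengths from merge heights)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.sample_ids)
        return str(tree).strip()


def cluster_samples(
    calls: ClassificationTable,
    cris: list[CRI],
    min_at: float = 40.0,
    n_groups: int = 3,
    probes: ProbeMatrix | None = None,
    metric: str = "euclidean",
    method: str = "ward",
) -> ClusterResult:
    """Hierarchically cluster samples on calls within stringent CRIs.

    The feature matrix is the classification call matrix restricted to
    probes of CRIs whose adaptive threshold is >= ``min_at`` — low-
    stringency regions (detectable only in small sample subsets) are
    excluded so they cannot drive the grouping.
    """
    if calls.calls.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    selected = [c for c in cris if c.at != "none" and float(c.at) >= min_at]
    if not selected:
        raise ValueError(f"no CRI was detected at an adaptive threshold >= {min_at}")
    probe_idx: list[np.ndarray] = []
    for cri in selected:
        if probes is not None:
            base = probes.chromosome_index(cri.chromosome)
            probe_idx.append(base[cri.probe_start : cri.probe_end + 1])
        else:
            probe_idx.append(np.arange(cri.probe_start, cri.probe_end + 1))
    features = np.unique(np.concatenate(probe_idx))
    matrix = calls.calls.to_numpy()[features].T.astype(float)  # samples x probes
    z = linkage(matrix, method=method, metric=metric)
    groups = fcluster(z, t=n_groups, criterion="maxclust")
    return ClusterResult(
        linkage_matrix=z,
        labels=pd.Series(groups, index=calls.sample_ids, name="group"),
        feature_probes=features,
        sample_ids=calls.sample_ids,
    )


def region_heatmap_matrix(
    calls: ClassificationTable,
    regions: list[CRI] | list[ConsensusRegion],
    probes: ProbeMatrix,
) -> pd.DataFrame:
    """Per-region, per-sample net CNA fraction in [-1, 1].

    Value = (fraction of the region's probes called gained) minus
    (fraction called lost) for each sample; used to shade consensus
    heatmaps.
    """
    if not regions:
        raise ValueError("no regions supplied")
    call_values = calls.calls.to_numpy()
    rows = []
    index = []
    pos = probes.probes["start_bp"].to_numpy()
    for region in regions:
        chrom_idx = probes.chromosome_index(region.chromosome)
        if hasattr(region, "probe_start"):
            idx = chrom_idx[region.probe_start : region.probe_end + 1]
            label = f"{region.direction}_{region.chromosome}_{region.index}"
        else:  # ConsensusRegion: genomic span
            inside = (pos[chrom_idx] >= region.start_bp) & (pos[chrom_idx] < region.end_bp)
            idx = chrom_idx[inside]
            label = f"{region.direction}_{region.chromosome}_{region.start_bp + 1}"
        block = call_values[idx]
        frac_gain = (block > 0).mean(axis=0)
        frac_loss = (block < 0).mean(axis=0)
        rows.append(frac_gain - frac_loss)
        index.append(label)
    return pd.DataFrame(rows, index=index, columns=calls.sample_ids)


def consensus_table(regions: list[ConsensusRegion], genes=None) -> pd.DataFrame:
    """Consensus regions as a TSV-ready table (1-based bp spans)."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chromosome": r.chromosome,
                "direction": r.direction,
                "span_bp": f"{r.start_bp + 1}-{r.end_bp}",
                "n_methods": len(r.methods),
                "methods": ",".join(sorted(r.methods)),
                "genes": (
                    genes.count_overlapping(r.chromosome, r.start_bp, r.end_bp)
                    if genes is not None
                    else ""
                ),
                "in_amplitude_list": r.in_amplitude_list,
                "in_gdw_list": r.in_gdw_list,
            }
        )
    return pd.DataFrame(rows)
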