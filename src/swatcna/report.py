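"""Web-style report generation: overview plots, karyograms, region pages.

The report is pure presentation over the analysis artifacts: an index
page, one page per chromosome with a three-panel overview figure
(median log2 profile with a 95 % band, probe-window recurrence with
gated CRIs, high-level CNA frequency), copy number karyograms, and one
page per CRI showing the coloured probe x sample call grid with its MRI
outlined and a genome-browser hyperlink. Regenerating a report from the
same artifacts is byte-identical (no timestamps are embedded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from jinja2 import Environment

from .classify import ClassificationTable
from .io_formats import ProbeMatrix, RunConfig
from .regions import CRI, MRI, RegionAnalysis, regions_table
from .windows import TrackSet

logger = logging.getLogger("swatcna")

#: Genome-browser URL templates by build label (Ensembl region view).
BUILD_URL_TEMPLATES = {
    "GRCh37": "https://grch37.ensembl.org/Homo_sapiens/Location/View?r={chrom}:{start}-{end}",
    "GRCh38": "https://www.ensembl.org/Homo_sapiens/Location/View?r={chrom}:{start}-{end}",
}

#: Call colours per the 5-point scheme.
CALL_COLORS = {2: "#e6c700", 1: "#2ca02c", 0: "#c8c8c8", -1: "#d62728", -2: "#17becf"}
CALL_NAMES = {2: "high-level gain", 1: "gain", 0: "normal", -1: "loss", -2: "high-level loss"}

_HIGHLEVEL_AXIS_MAX = 25.0  # high-level frequency panel is scaled to 25 % of samples

_env = Environment(autoescape=True)

_INDEX_TEMPLATE = _env.from_string(
    """<!DOCTYPE html>
<html><head><title>swatcna report</title></head><body>
<h1>Copy number aberration regions of interest</h1>
<h2>Chromosomes</h2>
<ul>
{% for chrom, page in chromosome_pages %}<li><a href="{{ page }}">chromosome {{ chrom }}</a></li>
{% endfor %}</ul>
<h2>Regions (genome order)</h2>
<table border="1" cellspacing="0">
<tr><th>#</th><th>chrom</th><th>direction</th><th>span (bp, 1-based)</th><th>probes</th>
<th>AT (%)</th><th>peak PWS (%)</th><th>page</th></tr>
{% for r in rows %}<tr><td>{{ r.index }}</td><td>{{ r.chromosome }}</td><td>{{ r.direction }}</td>
<td>{{ r.span }}</td><td>{{ r.probes }}</td><td>{{ r.at }}</td><td>{{ r.peak }}</td>
<td><a href="{{ r.page }}">{{ r.name }}</a></td></tr>
{% endfor %}</table>
</body></html>
"""
)

_CHROM_TEMPLATE = _env.from_string(
    """<!DOCTYPE html>
<html><head><title>chromosome {{ chrom }}</title></head><body>
<h1>Chromosome {{ chrom }}</h1>
<p><a href="index.html">back to index</a></p>
<img src="{{ figure }}" alt="chromosome {{ chrom }} overview"/>
<h2>Regions</h2>
<ul>
{% for name, page in regions %}<li><a href="{{ page }}">{{ name }}</a></li>
{% endfor %}</ul>
</body></html>
"""
)

_REGION_TEMPLATE = _env.from_string(
    """<!DOCTYPE html>
<html><head><title>{{ title }}</title>
<style>
td.call { width: 18px; height: 18px; }
td.mri { border-top: 2px solid black; border-bottom: 2px solid black; }
</style></head><body>
<h1>{{ title }}</h1>
<p><a href="index.html">back to index</a></p>
<p>Span (1-based): {{ chrom }}:{{ start1 }}-{{ end }} | adaptive threshold {{ at }}% |
peak PWS {{ peak }}%</p>
{% if url %}<p><a href="{{ url }}">view region in genome browser</a></p>{% endif %}
<table cellspacing="1">
<tr><th>probe</th>{% for s in samples %}<th>{{ s }}</th>{% endfor %}</tr>
{% for row in grid %}<tr><td>{{ row.probe }}</td>
{% for cell in row.cells %}<td class="call{% if row.in_mri %} mri{% endif %}"
 style="background:{{ cell.color }}" title="{{ cell.name }}"></td>{% endfor %}</tr>
{% endfor %}</table>
<p>green = gain, yellow = high-level gain, grey = normal, red = loss,
cyan = high-level loss; outlined rows are the MRI.</p>
</body></html>
"""
)


def browser_url(build: str, chromosome: str, start_bp: int, end_bp: int) -> str | None:
    """Genome-browser URL for a 0-based half-open span, or None if the
    build label has no registered template (a warning is logged)."""
    template = BUILD_URL_TEMPLATES.get(build)
    if template is None:
        logger.warning("unknown genome build %r: browser links omitted", build)
        return None
    return template.format(chrom=chromosome, start=start_bp + 1, end=end_bp)


@dataclass
class ReportBundle:
    """Layout of a generated report directory."""

    root: Path
    index_page: str
    chromosome_pages: dict[str, str] = field(default_factory=dict)
    region_pages: dict[str, str] = field(default_factory=dict)
    assets: list[str] = field(default_factory=list)

    def write_manifest(self) -> None:
        manifest = {
            "index": self.index_page,
            "chromosomes": self.chromosome_pages,
            "regions": self.region_pages,
            "assets": sorted(self.assets),
        }
        with open(self.root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


def _region_slug(cri: CRI) -> str:
    return f"{cri.direction}_chr{cri.chromosome}_CRI{cri.index}"


# ---------------------------------------------------------------------------
# Figures


def chromosome_overview(
    probes: ProbeMatrix,
    calls: ClassificationTable,
    tracks: TrackSet,
    analysis: RegionAnalysis,
    chromosome: str,
    path: str | Path,
    overview_w: int = 3,
) -> Path:
    """Three-panel chromosome overview figure.

    Top: per-probe median log2 across samples with a 95 % band (2.5th
    and 97.5th percentiles). Middle: 3-probe PWS bars, gains above and
    losses below the axis, with gated CRIs drawn as thick indexed bars.
    Bottom: high-level CNA frequency, axis capped at 25 % of the sample
    set (larger frequencies are clipped at the cap).
    """
    idx = probes.chromosome_index(chromosome)
    pos = probes.probes["start_bp"].to_numpy()[idx] / 1e6
    values = probes.log2.to_numpy()[idx]
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)

    med = np.nanmedian(values, axis=1)
    lo, hi = np.nanpercentile(values, [2.5, 97.5], axis=1)
    axes[0].fill_between(pos, lo, hi, color="purple", alpha=0.25, linewidth=0)
    axes[0].plot(pos, med, color="black", linewidth=0.8)
    axes[0].axhline(0, color="grey", linewidth=0.5)
    axes[0].set_ylabel("median log2")

    ax = axes[1]
    w = overview_w
    for direction, sign, color in (("gain", 1, "green"), ("loss", -1, "red")):
        track = tracks.get(chromosome, w, direction)
        if len(track.scores) == 0:
            continue
        centers = (pos[: len(track.scores)] + pos[w - 1 : w - 1 + len(track.scores)]) / 2
        ax.bar(centers, sign * track.scores, width=np.median(np.diff(pos)) if len(pos) > 1 else 0.1,
               color=color, linewidth=0)
        for cri in analysis.cris_for(chromosome, direction):
            x0 = probes.probes["start_bp"].to_numpy()[idx][cri.probe_start] / 1e6
            x1 = probes.probes["end_bp"].to_numpy()[idx][cri.probe_end] / 1e6
            y = sign * 112
            ax.plot([x0, x1], [y, y], color=color, linewidth=5, solid_capstyle="butt")
            ax.annotate(str(cri.index), ((x0 + x1) / 2, y + sign * 8),
                        ha="center", va="center", fontsize=7)
    ax.axhline(0, color="black", linewidth=1.2)  # ideogram axis
    ax.set_ylim(-135, 135)
    ax.set_ylabel("PWS (%)")

    call_values = calls.calls.to_numpy()[idx]
    n_samples = call_values.shape[1]
    high = 100.0 * (np.abs(call_values) == 2).sum(axis=1) / n_samples
    axes[2].bar(pos, np.minimum(high, _HIGHLEVEL_AXIS_MAX),
                width=np.median(np.diff(pos)) if len(pos) > 1 else 0.1, color="darkorange")
    axes[2].set_ylim(0, _HIGHLEVEL_AXIS_MAX)
    axes[2].set_ylabel("high-level CNA (%)")
    axes[2].set_xlabel("position (Mb)")
    fig.suptitle(f"chromosome {chromosome}")
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return Path(path)


def karyogram(
    probes: ProbeMatrix,
    calls: ClassificationTable,
    analysis: RegionAnalysis,
    path: str | Path,
    significant_mris: list[MRI] | None = None,
    cytoband_path: str | Path | None = None,
) -> Path:
    """Whole-genome karyogram of CNA calls and detected regions.

    Per chromosome: green/yellow bars above the ideogram for gain and
    high-level gain, red/cyan bars below for loss and high-level loss
    (a probe is marked when any sample carries the call), purple
    flanking bars for CRIs, and arrowheads at MRIs passing the amplitude
    significance filter. With no cytoband file, chromosomes are plain bars.
    """
    chroms = probes.chromosomes
    bands = _read_cytobands(cytoband_path) if cytoband_path else None
    fig, axes = plt.subplots(1, max(len(chroms), 1), figsize=(2.2 * max(len(chroms), 1), 6))
    if len(chroms) == 1:
        axes = [axes]
    sig = significant_mris or []
    for ax, chrom in zip(axes, chroms):
        idx = probes.chromosome_index(chrom)
        pos = probes.probes["start_bp"].to_numpy()[idx] / 1e6
        length = probes.probes["end_bp"].to_numpy()[idx][-1] / 1e6
        ax.add_patch(plt.Rectangle((-0.15, 0), 0.3, length, facecolor="#eeeeee",
                                   edgecolor="black", linewidth=0.6))
        if bands is not None:
            for _, b in bands[bands["chromosome"] == chrom].iterrows():
                shade = {"gneg": "#ffffff", "gpos25": "#cccccc", "gpos50": "#999999",
                         "gpos75": "#666666", "gpos100": "#333333", "acen": "#cc4444"}.get(
                    b["stain"], "#eeeeee")
                ax.add_patch(plt.Rectangle((-0.15, b["start_bp"] / 1e6), 0.3,
                                           (b["end_bp"] - b["start_bp"]) / 1e6,
                                           facecolor=shade, edgecolor="none"))
        cv = calls.calls.to_numpy()[idx]
        for call, x0, color in ((1, 0.22, CALL_COLORS[1]), (2, 0.34, CALL_COLORS[2]),
                                (-1, -0.22, CALL_COLORS[-1]), (-2, -0.34, CALL_COLORS[-2])):
            marked = np.flatnonzero((cv == call).any(axis=1))
            for p in marked:
                ax.plot([x0, x0], [pos[p], pos[p] + 0.1], color=color, linewidth=2)
        for direction in ("gain", "loss"):
            for cri in analysis.cris_for(chrom, direction):
                y0, y1 = pos[cri.probe_start], pos[cri.probe_end]
                x = 0.5 if direction == "gain" else -0.5
                ax.plot([x, x], [y0, y1], color="purple", linewidth=4, solid_capstyle="butt")
        for mri in sig:
            if mri.chromosome != chrom:
                continue
            y = (mri.start_bp + mri.end_bp) / 2e6
            x = 0.62 if mri.direction == "gain" else -0.62
            ax.plot([x], [y], marker="<" if mri.direction == "gain" else ">",
                    color="black", markersize=6)
        ax.set_xlim(-0.9, 0.9)
        ax.set_ylim(length * 1.05, -length * 0.02)
        ax.set_xticks([])
        ax.set_title(chrom, fontsize=9)
        ax.set_yticks([])
        for spine in ax.spines.values():
            spine.set_visible(False)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return Path(path)


def _read_cytobands(path: str | Path) -> pd.DataFrame:
    from .io_formats import normalize_chromosome

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start_bp", "end_bp", "band", "stain"])
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df


# ---------------------------------------------------------------------------
# Pages


def region_page(
    cri: CRI,
    calls: ClassificationTable,
    probes: ProbeMatrix,
    build: str = "GRCh37",
) -> str:
    """HTML page for one CRI: coloured call grid with the MRI outlined."""
    idx = probes.chromosome_index(cri.chromosome)
    local = np.arange(cri.probe_start, cri.probe_end + 1)
    grid = []
    probe_ids = probes.probes["probe_id"].to_numpy()[idx]
    call_values = calls.calls.to_numpy()[idx]
    mri_probes = set()
    for mri in cri.mris:
        mri_probes.update(range(mri.probe_start, mri.probe_end + 1))
    for p in local:
        grid.append(
            {
                "probe": probe_ids[p],
                "in_mri": p in mri_probes,
                "cells": [
                    {"color": CALL_COLORS[int(v)], "name": CALL_NAMES[int(v)]}
                    for v in call_values[p]
                ],
            }
        )
    url = browser_url(build, cri.chromosome, cri.start_bp, cri.end_bp)
    return _REGION_TEMPLATE.render(
        title=f"{cri.direction} CRI #{cri.index} on chromosome {cri.chromosome}",
        chrom=cri.chromosome,
        start1=cri.start_bp + 1,
        end=cri.end_bp,
        at=cri.at,
        peak=f"{cri.peak_pws:g}",
        url=url,
        samples=calls.sample_ids,
        grid=grid,
    )


def generate_report(
    out_dir: str | Path,
    probes: ProbeMatrix,
    calls: ClassificationTable,
    tracks: TrackSet,
    analysis: RegionAnalysis,
    config: RunConfig | None = None,
    significant_mris: list[MRI] | None = None,
    cytoband_path: str | Path | None = None,
) -> ReportBundle:
    """Write the full report directory and return its layout.

    Every CRI row in the index links to an existing region page; tables
    are accompanied by TSV files with identical record counts.
    """
    config = config or RunConfig()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(root=root, index_page="index.html")

    table = regions_table(analysis)
    table.to_csv(root / "regions.tsv", sep="\t", index=False)
    bundle.assets.append("regions.tsv")

    for cri in analysis.cris:
        slug = _region_slug(cri)
        page = f"region_{slug}.html"
        (root / page).write_text(region_page(cri, calls, probes, config.genome_build))
        bundle.region_pages[slug] = page

    index_rows = []
    for chrom in probes.chromosomes:
        figure = f"overview_chr{chrom}.png"
        chromosome_overview(probes, calls, tracks, analysis, chrom, root / figure,
                            overview_w=min(config.window_sizes))
        bundle.assets.append(figure)
        regions = [
            (_region_slug(c), bundle.region_pages[_region_slug(c)])
            for c in analysis.cris
            if c.chromosome == chrom
        ]
        page = f"chr{chrom}.html"
        (root / page).write_text(
            _CHROM_TEMPLATE.render(chrom=chrom, figure=figure, regions=regions)
        )
        bundle.chromosome_pages[chrom] = page

    karyo = "karyogram.png"
    karyogram(probes, calls, analysis, root / karyo,
              significant_mris=significant_mris, cytoband_path=cytoband_path)
    bundle.assets.append(karyo)

    serial = 0
    for cri in analysis.cris:
        serial += 1
        slug = _region_slug(cri)
        index_rows.append(
            {
                "index": serial,
                "chromosome": cri.chromosome,
                "direction": cri.direction,
                "span": f"{cri.start_bp + 1}-{cri.end_bp}",
                "probes": cri.probe_count,
                "at": cri.at,
                "peak": f"{cri.peak_pws:g}",
                "page": bundle.region_pages[slug],
                "name": slug,
            }
        )
    (root / "index.html").write_text(
        _INDEX_TEMPLATE.render(
            chromosome_pages=sorted(bundle.chromosome_pages.items(),
                                    key=lambda kv: probes.chromosomes.index(kv[0])),
            rows=index_rows,
        )
    )
    bundle.write_manifest()
    return bundle
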