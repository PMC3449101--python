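"""Readers and writers for the external formats and the run configuration.

The canonical in-memory model is:

* :class:`ProbeMatrix` — probe genomic metadata plus the probe x sample
  matrix of log2 fluorescence ratios, strictly sorted by genome position.
* :class:`SegmentSet` — per-sample, per-method constant-mean segments as
  produced by an external segmentation algorithm (SEG-style input).
* :class:`GeneAnnotation` — gene intervals used for gene-density weighting.
* :class:`RunConfig` — every analysis parameter, loadable from a single
  plain-text ``key=value`` file.

All internal coordinates are 0-based half-open; user-facing reports print
1-based positions. Only autosomes are analysed: chromosome labels are
normalised by stripping any ``chr`` prefix and rows on other chromosomes
are dropped with a warning.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("swatcna")

#: Chromosome labels retained for analysis (human autosomes).
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

_CHROM_ORDER = {c: i for i, c in enumerate(AUTOSOMES)}


def normalize_chromosome(label: str) -> str:
    """Strip a ``chr`` prefix and surrounding whitespace from a label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def _chrom_sort_key(labels: pd.Series) -> pd.Series:
    return labels.map(lambda c: _CHROM_ORDER.get(c, len(_CHROM_ORDER)))


# ---------------------------------------------------------------------------
# ProbeMatrix


@dataclass
class ProbeMatrix:
    """Probe metadata and per-sample log2 ratios, ordered by genome position.

    Attributes
    ----------
    probes
        DataFrame with columns ``probe_id``, ``chromosome``, ``start_bp``,
        ``end_bp`` (0-based half-open), indexed 0..n_probes-1 in genome
        order.
    log2
        DataFrame of log2 ratios, same index as ``probes``, one column per
        sample. May contain NaN (missing values).
    """

    probes: pd.DataFrame
    log2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.probes.index.equals(self.log2.index):
            raise ValueError("probes and log2 must share the same index")
        if self.log2.shape[1] < 2:
            raise ValueError("a ProbeMatrix needs at least 2 samples")
        if self.probes["probe_id"].duplicated().any():
            dup = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        if (self.probes["start_bp"] > self.probes["end_bp"]).any():
            raise ValueError("probe with start_bp > end_bp")

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2.columns)

    @property
    def n_samples(self) -> int:
        return self.log2.shape[1]

    @property
    def n_probes(self) -> int:
        return self.log2.shape[0]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in genome order."""
        seen = self.probes["chromosome"]
        return list(dict.fromkeys(seen))

    def chromosome_index(self, chromosome: str) -> np.ndarray:
        """Positional indices (genome-ordered) of the probes on a chromosome."""
        mask = (self.probes["chromosome"] == chromosome).to_numpy()
        return np.flatnonzero(mask)

    def values_for(self, chromosome: str) -> np.ndarray:
        """log2 matrix restricted to one chromosome (probes x samples)."""
        return self.log2.to_numpy()[self.chromosome_index(chromosome)]

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_frames(cls, probes: pd.DataFrame, log2: pd.DataFrame) -> "ProbeMatrix":
        """Sort by (chromosome, start_bp), drop non-autosomes, reindex."""
        probes = probes.copy()
        probes["chromosome"] = probes["chromosome"].map(normalize_chromosome)
        keep = probes["chromosome"].isin(AUTOSOMES)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d probes on non-autosomal chromosomes", n_drop)
        probes = probes.loc[keep]
        log2 = log2.loc[probes.index]
        order = np.lexsort(
            (probes["start_bp"].to_numpy(), _chrom_sort_key(probes["chromosome"]).to_numpy())
        )
        probes = probes.iloc[order].reset_index(drop=True)
        log2 = log2.iloc[order].reset_index(drop=True)
        return cls(probes=probes, log2=log2.astype(float))

    def impute_missing(self) -> "ProbeMatrix":
        """Impute NaN log2 values per sample from flanking probes.

        Each missing value becomes the mean of the nearest non-missing
        probes on either side within the same chromosome (one-sided at
        chromosome ends). The number of imputed cells is logged.
        """
        log2 = self.log2.copy()
        n_imputed = int(log2.isna().sum().sum())
        if n_imputed == 0:
            return self
        for chrom in self.chromosomes:
            idx = self.chromosome_index(chrom)
            block = log2.iloc[idx]
            filled = (block.ffill() + block.bfill()) / 2.0
            filled = filled.where(~filled.isna(), block.ffill())
            filled = filled.where(~filled.isna(), block.bfill())
            log2.iloc[idx] = filled
        logger.info("imputed %d missing log2 values", n_imputed)
        return ProbeMatrix(probes=self.probes, log2=log2)


def read_probe_matrix(path: str | Path) -> ProbeMatrix:
    """Read a tab-delimited probe matrix.

    Expected header: ``probe_id  chromosome  start  end  <sample1> ...``.
    Rows need not be sorted; non-numeric log2 cells become NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    required = ["probe_id", "chromosome", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if len(sample_cols) < 2:
        raise ValueError(f"{path}: need at least 2 sample columns, found {len(sample_cols)}")
    probes = df[required].rename(columns={"start": "start_bp", "end": "end_bp"})
    probes["start_bp"] = probes["start_bp"].astype(np.int64)
    probes["end_bp"] = probes["end_bp"].astype(np.int64)
    log2 = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    return ProbeMatrix.from_frames(probes, log2)


def write_probe_matrix(pm: ProbeMatrix, path: str | Path) -> None:
    out = pm.probes.rename(columns={"start_bp": "start", "end_bp": "end"}).copy()
    out = pd.concat([out, pm.log2], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SegmentSet


@dataclass
class SegmentSet:
    """Constant-mean segments per (sample, method).

    ``df`` columns: method, sample, chromosome, start_bp, end_bp (0-based
    half-open), probe_count, seg_mean. Within one sample+method+chromosome
    the segments are non-overlapping and sorted.
    """

    df: pd.DataFrame

    COLUMNS = ["method", "sample", "chromosome", "start_bp", "end_bp", "probe_count", "seg_mean"]

    @property
    def methods(self) -> list[str]:
        return sorted(self.df["method"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def for_method(self, method: str) -> "SegmentSet":
        return SegmentSet(self.df.loc[self.df["method"] == method].reset_index(drop=True))

    def merged_with(self, other: "SegmentSet") -> "SegmentSet":
        return SegmentSet(pd.concat([self.df, other.df], ignore_index=True))


def read_segments(
    path: str | Path,
    method: str,
    sample_map: dict[str, str] | None = None,
    fill_gaps: bool = False,
) -> SegmentSet:
    """Read a SEG-style table: sample, chromosome, start, end, num_probes, seg_mean.

    The header row is optional; fields may be tab- or whitespace-delimited.
    Overlapping segments within a sample+chromosome are an error. Gaps
    between consecutive segments are an error unless ``fill_gaps`` is set,
    in which case the nearer flanking segment is extended to cover the gap.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and not _is_number(parts[2] if len(parts) > 2 else ""):
                continue  # header
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            sample, chrom, start, end, n_probes, mean = parts[:6]
            rows.append(
                {
                    "method": method,
                    "sample": sample_map.get(sample, sample) if sample_map else sample,
                    "chromosome": normalize_chromosome(chrom),
                    "start_bp": int(start),
                    "end_bp": int(end),
                    "probe_count": int(n_probes),
                    "seg_mean": float(mean),
                }
            )
    df = pd.DataFrame(rows, columns=SegmentSet.COLUMNS)
    if (df["probe_count"] < 1).any():
        raise ValueError(f"{path}: segment with probe_count < 1")
    pieces = []
    for (sample, chrom), grp in df.groupby(["sample", "chromosome"], sort=False):
        grp = grp.sort_values("start_bp").reset_index(drop=True)
        starts = grp["start_bp"].to_numpy()
        ends = grp["end_bp"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{path}: overlapping segments for sample {sample} chr {chrom}")
        gaps = np.flatnonzero(starts[1:] > ends[:-1])
        if gaps.size:
            if not fill_gaps:
                raise ValueError(
                    f"{path}: gap between segments for sample {sample} chr {chrom} "
                    f"(pass fill_gaps=True to extend flanking segments)"
                )
            ends = ends.copy()
            for g in gaps:  # extend the left segment over the gap
                ends[g] = starts[g + 1]
            grp["end_bp"] = ends
        pieces.append(grp)
    out = pd.concat(pieces, ignore_index=True) if pieces else df
    return SegmentSet(out)


def write_segments(segset: SegmentSet, path: str | Path, method: str | None = None) -> None:
    df = segset.df if method is None else segset.for_method(method).df
    out = df[["sample", "chromosome", "start_bp", "end_bp", "probe_count", "seg_mean"]]
    out = out.rename(
        columns={"start_bp": "start", "end_bp": "end", "probe_count": "num_probes"}
    )
    out.to_csv(path, sep="\t", index=False)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# GeneAnnotation


@dataclass
class GeneAnnotation:
    """Gene intervals (0-based half-open) used for gene-density weighting.

    Strand is read but never used downstream. Duplicate names (transcripts)
    are permitted; overlap counting de-duplicates by name.
    """

    df: pd.DataFrame  # columns: name, chromosome, start_bp, end_bp, strand

    COLUMNS = ["name", "chromosome", "start_bp", "end_bp", "strand"]

    @classmethod
    def empty(cls) -> "GeneAnnotation":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    def count_overlapping(self, chromosome: str, start_bp: int, end_bp: int) -> int:
        """Distinct gene names overlapping [start_bp, end_bp) by >= 1 bp."""
        d = self.df
        if d.empty:
            return 0
        hit = (
            (d["chromosome"] == chromosome)
            & (d["start_bp"] < end_bp)
            & (d["end_bp"] > start_bp)
        )
        return int(d.loc[hit, "name"].nunique())


def read_genes(path: str | Path, dialect: str | None = None) -> GeneAnnotation:
    """Read genes from BED (0-based half-open) or GFF3 (1-based closed).

    The dialect is auto-detected from the file extension; pass
    ``dialect='bed'`` or ``'gff'`` to override. Internal coordinates are
    0-based half-open regardless of input dialect.
    """
    import pyranges as pr

    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "gff" if suffix in {".gff", ".gff3", ".gtf"} else "bed"
    if path.stat().st_size == 0:
        return GeneAnnotation.empty()
    try:
        if dialect == "bed":
            df = pr.read_bed(str(path)).df
            name_col = "Name" if "Name" in df.columns else None
        else:
            df = pr.read_gff3(str(path), full=True).df
            if "Feature" in df.columns and (df["Feature"] == "gene").any():
                df = df.loc[df["Feature"] == "gene"]
            name_col = "Name" if "Name" in df.columns else ("ID" if "ID" in df.columns else None)
    except Exception as exc:  # pinpoint the offending line for the user
        raise ValueError(f"{path}: unparseable ({_find_bad_line(path, dialect)}): {exc}") from exc
    if df.empty:
        return GeneAnnotation.empty()
    out = pd.DataFrame(
        {
            "name": df[name_col].astype(str) if name_col else [f"feature_{i}" for i in range(len(df))],
            "chromosome": df["Chromosome"].astype(str).map(normalize_chromosome),
            "start_bp": df["Start"].astype(np.int64),
            "end_bp": df["End"].astype(np.int64),
            "strand": df["Strand"].astype(str) if "Strand" in df.columns else ".",
        }
    ).reset_index(drop=True)
    if (out["start_bp"] >= out["end_bp"]).any():
        bad = out.loc[out["start_bp"] >= out["end_bp"]].index[0]
        raise ValueError(f"{path}: invalid interval at record {bad + 1}")
    return GeneAnnotation(out)


def _find_bad_line(path: Path, dialect: str) -> str:
    expect = 3 if dialect == "bed" else 8
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < expect:
                return f"line {lineno}"
    return "unknown line"


# ---------------------------------------------------------------------------
# RunConfig


@dataclass
class RunConfig:
    """Analysis parameters, all overridable from a key=value text file.

    Defaults: window sizes 3..20 probes; adaptive-threshold ladder 80..20 %
    in decreasing 10 % steps; 5 % target coverage per direction per
    chromosome (10 % total); high-level calls limited to segments of at
    most 10 probes; abnormality threshold factor 0.75; permutation filter
    cutoff P < 0.1.
    """

    window_sizes: tuple[int, ...] = tuple(range(3, 21))
    at_ladder: tuple[float, ...] = (80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0)
    target_coverage: float = 0.05
    highlevel_max_width: int = 10
    factor_change: float = 0.75
    p_cutoff: float = 0.1
    n_permutations: int = 10_000
    rng_seed: int = 1
    consensus_min_methods: int = 2
    cluster_min_at: float = 40.0
    cluster_groups: int = 3
    genome_build: str = "GRCh37"
    highlevel_amplitude_gate: bool = False  # also require |mean| > 2T for +/-2
    fill_segment_gaps: bool = False

    def __post_init__(self) -> None:
        self.window_sizes = tuple(int(w) for w in self.window_sizes)
        self.at_ladder = tuple(float(a) for a in self.at_ladder)
        if any(w < 2 for w in self.window_sizes):
            raise ValueError("window_sizes must all be >= 2")
        if any(not (0 < a <= 100) for a in self.at_ladder):
            raise ValueError("at_ladder values must lie in (0, 100]")
        if list(self.at_ladder) != sorted(self.at_ladder, reverse=True) or len(
            set(self.at_ladder)
        ) != len(self.at_ladder):
            raise ValueError("at_ladder must be strictly decreasing")
        if not (0 < self.target_coverage <= 1):
            raise ValueError("target_coverage must lie in (0, 1]")
        if not (0 < self.cluster_min_at <= 100):
            raise ValueError("cluster_min_at must lie in (0, 100]")


_LIST_KEYS = {"window_sizes", "at_ladder"}
_BOOL_KEYS = {"highlevel_amplitude_gate", "fill_segment_gaps"}
_INT_KEYS = {
    "highlevel_max_width",
    "n_permutations",
    "rng_seed",
    "consensus_min_methods",
    "cluster_groups",
}
_FLOAT_KEYS = {"target_coverage", "factor_change", "p_cutoff", "cluster_min_at"}


def read_config(path: str | Path) -> RunConfig:
    """Read a plain-text ``key=value`` configuration file.

    Unset keys take the defaults documented on :class:`RunConfig`; an
    unknown key is an error (protects against silent typos).
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    overrides: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (tok.strip() for tok in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key in _LIST_KEYS:
                parts = [tok.strip() for tok in value.split(",") if tok.strip()]
                overrides[key] = tuple(float(p) if key == "at_ladder" else int(p) for p in parts)
            elif key in _BOOL_KEYS:
                overrides[key] = value.lower() in {"1", "true", "yes", "on"}
            elif key in _INT_KEYS:
                overrides[key] = int(value)
            elif key in _FLOAT_KEYS:
                overrides[key] = float(value)
            else:
                overrides[key] = value
    return RunConfig(**overrides)


# ---------------------------------------------------------------------------
# Region BED export


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write CRI/MRI records as BED (0-based half-open).

    The name field is ``<direction>_CRI_<serial>`` (or ``_MRI_``), the
    score field is the peak probe-window score x 10.
    """
    with open(path, "w") as fh:
        fh.write('track name="swatcna_regions"\n')
        for r in sorted(
            regions, key=lambda r: (_CHROM_ORDER.get(r.chromosome, 99), r.start_bp)
        ):
            kind = type(r).__name__
            name = f"{r.direction}_{kind}_{r.index}"
            score = int(round(r.peak_pws * 10))
            fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{name}\t{score}\t.\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read back a BED written by :func:`write_regions_bed` (round-trip)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            direction, kind, index = name.rsplit("_", 2)
            rows.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(start),
                    "end_bp": int(end),
                    "direction": direction,
                    "kind": kind,
                    "index": int(index),
                    "peak_pws": float(score) / 10.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "direction", "kind", "index", "peak_pws"],
    )
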