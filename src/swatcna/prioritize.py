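"""Prioritization of detected MRIs.

Two complementary rankings are provided:

* **Amplitude-based** — an MRI's mean log2 ratio across all samples is
  compared with a permutation null built from random probe windows of
  the same size drawn genome-wide (draws per chromosome proportional to
  its probe count). The Gaussian fitted to the permuted window means
  gives a one-tailed P value in the aberration's direction; MRIs with
  P below the cutoff (default 0.1) survive.

* **Gene-density-weighted (GDW)** — the aberration recurrence index
  ARI = |mean intensity| x recurrence is moderated by the regional
  information content RIC = genes per MRI / probes per MRI. The focality
  index AFI = (RIC x ARI) / ARI algebraically reduces to RIC and is
  implemented literally (with an ARI = 0 guard); GDW = AFI x ARI.
  Ranking by GDW favours gene-dense regions over gene-poor ones of
  similar amplitude. Gains and losses are ranked separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io_formats import GeneAnnotation, ProbeMatrix, RunConfig
from .regions import MRI


@dataclass
class NullDistribution:
    """Gaussian null for window mean intensities at one window size."""

    window_size: int
    mu: float
    sigma: float
    n_draws: int


@dataclass
class PrioritizedMRI:
    mri: MRI
    p_value: float
    ari: float = float("nan")
    ric: float = float("nan")
    afi: float = float("nan")
    gdw: float = float("nan")
    gene_count: int = 0
    amplitude_rank: int = 0
    gdw_rank: int = 0

    @property
    def probe_count(self) -> int:
        return self.mri.probe_count


def null_distribution(
    probes: ProbeMatrix, w: int, n_perm: int, rng: np.random.Generator | int
) -> NullDistribution:
    """Permutation null of mean log2 over random w-probe windows.

    ``n_perm`` window starts are drawn genome-wide, the number per
    chromosome proportional to its probe count (chromosomes shorter than
    w contribute none). The statistic is the mean log2 ratio over the
    window's probes across all samples; mu and sigma are the sample mean
    and (n-1) standard deviation of the permuted statistics.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    sizes = {c: probes.chromosome_index(c).size for c in probes.chromosomes}
    eligible = {c: n for c, n in sizes.items() if n >= w}
    if not eligible:
        raise ValueError(f"no chromosome has >= {w} probes")
    total = sum(eligible.values())
    values = probes.log2.to_numpy()
    stats = np.empty(0)
    draws_per_chrom = {
        c: int(round(n_perm * n / total)) for c, n in eligible.items()
    }
    # rounding may under/overshoot; adjust on the largest chromosome
    biggest = max(eligible, key=eligible.get)
    draws_per_chrom[biggest] += n_perm - sum(draws_per_chrom.values())
    samples = []
    for chrom in probes.chromosomes:
        k = draws_per_chrom.get(chrom, 0)
        if k <= 0:
            continue
        idx = probes.chromosome_index(chrom)
        starts = rng.integers(0, idx.size - w + 1, size=k)
        block = values[idx]
        for s in starts:
            samples.append(np.nanmean(block[s : s + w]))
    stats = np.asarray(samples)
    return NullDistribution(
        window_size=w,
        mu=float(stats.mean()),
        sigma=float(stats.std(ddof=1)),
        n_draws=len(stats),
    )


def amplitude_p(mri_mean: float, direction: str, mu: float, sigma: float) -> float:
    """One-tailed Gaussian tail probability in the aberration's direction.

    Gains: P = 1 - Phi((x - mu)/sigma); losses: P = Phi((x - mu)/sigma).
    With sigma = 0 the null is degenerate: P = 0 if x lies beyond mu in
    the aberration's direction, else 1.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        beyond = mri_mean > mu if direction == "gain" else mri_mean < mu
        return 0.0 if beyond else 1.0
    z = (mri_mean - mu) / sigma
    return float(1.0 - norm.cdf(z)) if direction == "gain" else float(norm.cdf(z))


def amplitude_filter(
    mris: list[MRI],
    probes: ProbeMatrix,
    config: RunConfig,
    rng: np.random.Generator | int | None = None,
) -> list[PrioritizedMRI]:
    """Keep MRIs whose mean intensity is significant against the null.

    One null distribution is built per distinct window size among the
    MRIs; survivors (P < ``config.p_cutoff``) are ranked ascending by P,
    ties broken by |mean intensity| descending.
    """
    if rng is None:
        rng = config.rng_seed
    rng = np.random.default_rng(rng)
    nulls = {
        w: null_distribution(probes, w, config.n_permutations, rng)
        for w in sorted({m.window_size for m in mris})
    }
    kept = []
    for mri in mris:
        null = nulls[mri.window_size]
        p = amplitude_p(mri.mean_intensity, mri.direction, null.mu, null.sigma)
        if p < config.p_cutoff:
            kept.append(PrioritizedMRI(mri=mri, p_value=p))
    kept.sort(key=lambda pm: (pm.p_value, -abs(pm.mri.mean_intensity)))
    for rank, pm in enumerate(kept, start=1):
        pm.amplitude_rank = rank
    return kept


# ---------------------------------------------------------------------------
# Gene-density weighting


def ari(mean_intensity: float, recurrence: float) -> float:
    """Aberration recurrence index: |mean log2| x recurrence.

    The absolute value puts gains and losses on comparable positive
    scales; the two directions are still ranked separately.
    """
    if not (0 < recurrence <= 1):
        raise ValueError("recurrence must lie in (0, 1]")
    return abs(mean_intensity) * recurrence


def ric(gene_count: int, probe_count: int) -> float:
    """Regional information content: genes per MRI / probes per MRI."""
    if probe_count < 1:
        raise ValueError("probe_count must be >= 1")
    return gene_count / probe_count


def afi(ric_score: float, ari_score: float) -> float:
    """Aberration focality index, (RIC x ARI) / ARI, as printed.

    The expression reduces algebraically to RIC; the ARI = 0 case is
    guarded to return RIC directly.
    """
    if ari_score == 0:
        return ric_score
    return (ric_score * ari_score) / ari_score


def gdw(ari_score: float, ric_score: float) -> float:
    """Gene density weighting: AFI x ARI."""
    if ari_score < 0 or ric_score < 0:
        raise ValueError("scores must be >= 0")
    return afi(ric_score, ari_score) * ari_score


def annotate_gene_scores(
    prioritized: list[PrioritizedMRI], genes: GeneAnnotation
) -> list[PrioritizedMRI]:
    """Populate ARI/RIC/AFI/GDW and gene counts on prioritized MRIs."""
    for pm in prioritized:
        mri = pm.mri
        pm.gene_count = genes.count_overlapping(mri.chromosome, mri.start_bp, mri.end_bp)
        pm.ari = ari(mri.mean_intensity, mri.recurrence)
        pm.ric = ric(pm.gene_count, mri.probe_count)
        pm.afi = afi(pm.ric, pm.ari)
        pm.gdw = gdw(pm.ari, pm.ric)
    return prioritized


def gdw_rank(prioritized: list[PrioritizedMRI]) -> list[PrioritizedMRI]:
    """Reorder by GDW descending (ties: ARI descending, then genome position).

    Gains and losses are ranked separately; the returned list carries
    gains first, each direction internally ordered, with ``gdw_rank``
    assigned within its direction.
    """
    from .io_formats import _CHROM_ORDER

    def position(pm: PrioritizedMRI):
        return (_CHROM_ORDER.get(pm.mri.chromosome, 99), pm.mri.start_bp)

    out: list[PrioritizedMRI] = []
    for direction in ("gain", "loss"):
        group = [pm for pm in prioritized if pm.mri.direction == direction]
        group.sort(key=lambda pm: (-pm.gdw, -pm.ari, position(pm)))
        for rank, pm in enumerate(group, start=1):
            pm.gdw_rank = rank
        out.extend(group)
    return out


def prioritized_table(prioritized: list[PrioritizedMRI]):
    """TSV-ready table: region, span, P, ARI, RIC, GDW, ranks (1-based bp)."""
    import pandas as pd

    rows = []
    for pm in prioritized:
        m = pm.mri
        rows.append(
            {
                "chromosome": m.chromosome,
                "direction": m.direction,
                "cri_index": m.cri_index,
                "mri_span_bp": f"{m.start_bp + 1}-{m.end_bp}",
                "probe_count": m.probe_count,
                "recurrence": m.recurrence,
                "mean_intensity": m.mean_intensity,
                "p_value": pm.p_value,
                "gene_count": pm.gene_count,
                "ari": pm.ari,
                "ric": pm.ric,
                "gdw": pm.gdw,
                "amplitude_rank": pm.amplitude_rank,
                "gdw_rank": pm.gdw_rank,
            }
        )
    return pd.DataFrame(rows)
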