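"""Metagene distributions, exon-length comparison, expression correlation.

The metagene profile places every site on a scaled transcript axis
u in [0, 3): u < 1 is the 5'UTR, 1 <= u < 2 the CDS, 2 <= u < 3 the 3'UTR,
each region stretched to unit length regardless of its nucleotide span.  A
site exactly at the stop-codon boundary lands at u = 2.0 (first 3'UTR bin).
m6A in plant and mammalian transcriptomes concentrates near the stop codon
and into the 3'UTR, which this profile makes visible as a mode near u = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TranscriptModel",
    "MetageneProfile",
    "ExonLengthComparison",
    "transcript_models_from_gtf",
    "transcript_to_genomic",
    "scaled_position",
    "metagene_profile",
    "exon_length_comparison",
    "correlate",
]


@dataclass
class TranscriptModel:
    """Exon structure and CDS boundaries of one transcript.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping; ``cds_start``/``cds_end`` are transcript coordinates
    (0-based half-open), so the 5'UTR spans [0, cds_start) and the 3'UTR
    spans [cds_end, length).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if not 0 <= self.cds_start <= self.cds_end <= self.length:
            raise ValueError(f"{self.transcript_id}: CDS outside transcript bounds")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end


def transcript_models_from_gtf(gtf_path) -> dict[str, TranscriptModel]:
    """Build transcript models from a GTF with exon and CDS features."""
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    models: dict[str, TranscriptModel] = {}
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (gid, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start - 1, feat.end))  # to 0-based half-open
    for tid, ex in exons.items():
        gid, strand = meta[tid]
        ex = sorted(ex)
        if tid not in cds:
            raise ValueError(f"transcript {tid} has no CDS feature")
        cds_glo = min(s for s, _ in cds[tid])
        cds_ghi = max(e for _, e in cds[tid])
        # genomic -> transcript offset of the CDS span
        t_lo = _genomic_to_transcript(ex, strand, cds_glo)
        t_hi = _genomic_to_transcript(ex, strand, cds_ghi - 1)
        cds_start, cds_end = min(t_lo, t_hi), max(t_lo, t_hi) + 1
        models[tid] = TranscriptModel(tid, gid, strand, ex, cds_start, cds_end)
    return models


def _genomic_to_transcript(exons: list[tuple[int, int]], strand: str, gpos: int) -> int:
    offset = 0
    for s, e in exons:
        if s <= gpos < e:
            t = offset + (gpos - s)
            break
        offset += e - s
    else:
        raise ValueError(f"genomic position {gpos} not exonic")
    length = sum(e - s for s, e in exons)
    return t if strand == "+" else length - 1 - t


def transcript_to_genomic(model: TranscriptModel, tpos: int) -> int:
    """0-based genomic position of a transcript coordinate (inverse mapping)."""
    if not 0 <= tpos < model.length:
        raise ValueError(f"position {tpos} outside transcript {model.transcript_id}")
    walk = tpos if model.strand == "+" else model.length - 1 - tpos
    for s, e in model.exons:
        if walk < e - s:
            return s + walk
        walk -= e - s
    raise AssertionError("unreachable: exon walk exhausted")


def scaled_position(model: TranscriptModel, tpos: int) -> float:
    """Scaled metagene coordinate u in [0, 3) of a transcript position."""
    if not 0 <= tpos < model.length:
        raise ValueError(f"site {tpos} outside transcript {model.transcript_id}")
    if tpos < model.cds_start:
        return tpos / model.utr5_len
    if tpos < model.cds_end:
        return 1.0 + (tpos - model.cds_start) / model.cds_len
    return 2.0 + (tpos - model.cds_end) / model.utr3_len


@dataclass
class MetageneProfile:
    """Histogram of scaled site positions; densities integrate to 1."""

    bins_per_region: int
    edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        regions = np.repeat(["5UTR", "CDS", "3UTR"], self.bins_per_region)
        return pd.DataFrame(
            {
                "bin_start": self.edges[:-1],
                "bin_end": self.edges[1:],
                "region": regions,
                "count": self.counts,
                "density": self.density,
            }
        )


def metagene_profile(sites: Iterable[tuple[str, int]] | pd.DataFrame,
                     models: Mapping[str, TranscriptModel],
                     bins_per_region: int = 100) -> MetageneProfile:
    """Histogram sites over the scaled 5'UTR/CDS/3'UTR axis.

    ``sites`` is either an iterable of (transcript_id, tpos) pairs or a site
    table with those columns.  Every site must be assignable to a model.
    """
    if isinstance(sites, pd.DataFrame):
        pairs = list(zip(sites["transcript_id"], sites["tpos"]))
    else:
        pairs = list(sites)
    u = np.array([scaled_position(models[tid], int(tpos)) for tid, tpos in pairs])
    edges = np.linspace(0.0, 3.0, 3 * bins_per_region + 1)
    counts, _ = np.histogram(u, bins=edges)
    width = 1.0 / bins_per_region
    total = counts.sum()
    density = counts / (total * width) if total else np.zeros_like(counts, dtype=float)
    return MetageneProfile(bins_per_region, edges, counts, density)


@dataclass
class ExonLengthComparison:
    median_m6a: float
    median_control: float
    median_diff: float
    rank_sum_statistic: float


def exon_length_comparison(m6a_exons: Sequence[float],
                           control_exons: Sequence[float]) -> ExonLengthComparison:
    """Medians and a rank-sum location statistic for exon-length lists.

    The statistic is the Mann-Whitney U of m6A-containing exon lengths
    against control exon lengths; no p-value interpretation is attached.
    """
    a = np.asarray(m6a_exons, dtype=float)
    b = np.asarray(control_exons, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both exon-length lists must be non-empty")
    u_stat = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    return ExonLengthComparison(
        median_m6a=float(np.median(a)),
        median_control=float(np.median(b)),
        median_diff=float(np.median(a) - np.median(b)),
        rank_sum_statistic=u_stat,
    )


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Pearson correlation of paired per-gene values; NaN flags zero variance."""
    if method != "pearson":
        raise ValueError(f"unsupported method: {method!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("inputs must be finite")
    if np.std(xa) == 0 or np.std(ya) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, ya).statistic)
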