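"""Poly(A)-site clustering and coupling of APA isoform choice with m6A.

Read 3'-end positions of a gene are grouped into poly(A)-site clusters by
single-linkage chaining: consecutive sorted positions join one cluster while
each gap is at most 24 nt (inclusive).  Among clusters with enough read
support the one nearest the stop codon in the direction of transcription is
the proximal isoform and the farthest the distal one.  Genes whose proximal
and distal mean poly(A) tail lengths differ at least two-fold are screened
as APA genes, and methylation coupling is summarized as
log2((ratio_D + eps) / (ratio_P + eps)) over the reads of each cluster.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import ReadSiteCall

__all__ = [
    "ReadEndRecord",
    "PolyACluster",
    "read_polya_tsv",
    "cluster_positions",
    "cluster_polya_sites",
    "assign_proximal_distal",
    "apa_polya_length_screen",
    "apa_methylation_fold_change",
    "attach_cluster_m6a",
    "apa_fold_change_table",
    "clusters_frame",
]

POLYA_COLUMNS = ["read_id", "gene_id", "chrom", "end_pos", "strand", "polya_length", "qc_tag"]


@dataclass(frozen=True)
class ReadEndRecord:
    """One read's genomic 3'-end and its poly(A) tail length (if PASS)."""

    read_id: str
    gene_id: str
    chrom: str
    end_pos: int  # 1-based genomic position of the 3' end
    strand: str
    polya_length: float | None = None
    qc_tag: str = "PASS"


@dataclass
class PolyACluster:
    """A chained group of read 3'-ends for one gene and strand."""

    gene_id: str
    chrom: str
    strand: str
    positions: list[int]
    read_ids: list[str]
    polya_lengths: list[float] = field(default_factory=list)
    role: str | None = None  # "proximal" | "distal" | "other" | None
    m6a_ratio: float | None = None
    m6a_calls: int = 0

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def representative(self) -> int:
        """Modal end position; ties broken toward the most 3' position."""
        counts = Counter(self.positions)
        top = max(counts.values())
        candidates = [p for p, c in counts.items() if c == top]
        return max(candidates) if self.strand == "+" else min(candidates)

    @property
    def polya_mean(self) -> float:
        return float(np.mean(self.polya_lengths)) if self.polya_lengths else math.nan

    @property
    def polya_median(self) -> float:
        return float(np.median(self.polya_lengths)) if self.polya_lengths else math.nan


def read_polya_tsv(path, column_map: Mapping[str, str] | None = None) -> list[ReadEndRecord]:
    """Load per-read poly(A) records; non-PASS qc rows are excluded.

    ``column_map`` renames foreign headers (e.g. nanopolish-polya output) to
    the canonical ones: read_id, gene_id, chrom, end_pos, strand,
    polya_length, qc_tag.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in POLYA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"poly(A) table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        if str(row.qc_tag) != "PASS":
            continue
        length = None if pd.isna(row.polya_length) else float(row.polya_length)
        records.append(
            ReadEndRecord(str(row.read_id), str(row.gene_id), str(row.chrom),
                          int(row.end_pos), str(row.strand), length, str(row.qc_tag))
        )
    return records


def cluster_positions(positions: Sequence[int], window: int = 24) -> list[list[int]]:
    """Single-linkage chaining of sorted positions: gap <= window joins.

    Returns groups of indices into the *sorted* position array.
    """
    if len(positions) == 0:
        return []
    order = np.argsort(positions, kind="mergesort")
    sorted_pos = np.asarray(positions)[order]
    groups: list[list[int]] = [[int(order[0])]]
    for prev, idx in zip(sorted_pos[:-1], range(1, len(sorted_pos))):
        if sorted_pos[idx] - prev <= window:
            groups[-1].append(int(order[idx]))
        else:
            groups.append([int(order[idx])])
    return groups


def cluster_polya_sites(records: Iterable[ReadEndRecord], window: int = 24) -> list[PolyACluster]:
    """Cluster PASS read ends per (gene, chrom, strand)."""
    by_gene: dict[tuple[str, str, str], list[ReadEndRecord]] = {}
    for rec in records:
        if rec.qc_tag != "PASS":
            continue
        by_gene.setdefault((rec.gene_id, rec.chrom, rec.strand), []).append(rec)
    clusters: list[PolyACluster] = []
    for (gene_id, chrom, strand), recs in sorted(by_gene.items()):
        positions = [r.end_pos for r in recs]
        for group in cluster_positions(positions, window):
            members = [recs[i] for i in group]
            clusters.append(
                PolyACluster(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    positions=[m.end_pos for m in members],
                    read_ids=[m.read_id for m in members],
                    polya_lengths=[m.polya_length for m in members if m.polya_length is not None],
                )
            )
    return clusters


def assign_proximal_distal(clusters: Sequence[PolyACluster], strand: str,
                           stop_codon_genomic: int,
                           min_cluster_reads: int = 10) -> list[PolyACluster]:
    """Label one gene's clusters proximal/distal/other relative to the stop codon.

    Distance is measured in the direction of transcription; genes with fewer
    than two clusters of at least ``min_cluster_reads`` reads are non-APA and
    keep role None.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand: {strand!r}")
    sign = 1 if strand == "+" else -1
    qualifying = [c for c in clusters if c.count >= min_cluster_reads]
    if len(qualifying) < 2:
        for c in clusters:
            c.role = None
        return list(clusters)
    dist = {id(c): sign * (c.representative - stop_codon_genomic) for c in qualifying}
    proximal = min(qualifying, key=lambda c: dist[id(c)])
    distal = max(qualifying, key=lambda c: dist[id(c)])
    for c in clusters:
        if c is proximal:
            c.role = "proximal"
        elif c is distal:
            c.role = "distal"
        elif c in qualifying:
            c.role = "other"
        else:
            c.role = None
    return list(clusters)


def apa_polya_length_screen(clusters: Sequence[PolyACluster]) -> pd.DataFrame:
    """Per-gene screen for a >= 2-fold proximal/distal poly(A)-length change.

    The fold change is max(meanP, meanD)/min(meanP, meanD); exactly two-fold
    is flagged (inclusive boundary).  A zero mean length leaves the fold
    undefined (NaN, not flagged).
    """
    rows = []
    by_gene: dict[str, dict[str, PolyACluster]] = {}
    for c in clusters:
        if c.role in ("proximal", "distal"):
            by_gene.setdefault(c.gene_id, {})[c.role] = c
    for gene_id, roles in sorted(by_gene.items()):
        if "proximal" not in roles or "distal" not in roles:
            continue
        mean_p = roles["proximal"].polya_mean
        mean_d = roles["distal"].polya_mean
        if math.isnan(mean_p) or math.isnan(mean_d):
            continue
        if min(mean_p, mean_d) == 0:
            fold, flagged = math.nan, False
        else:
            fold = max(mean_p, mean_d) / min(mean_p, mean_d)
            flagged = fold >= 2.0
        rows.append((gene_id, mean_p, mean_d, fold, flagged))
    return pd.DataFrame(
        rows, columns=["gene_id", "mean_polya_proximal", "mean_polya_distal", "fold", "flagged"]
    )


def apa_methylation_fold_change(ratio_distal: float, ratio_proximal: float,
                                epsilon: float = 0.01) -> float:
    """Signed log2 fold change of distal vs proximal m6A ratio.

    A pseudo-ratio epsilon keeps zero ratios finite.
    """
    return math.log2((ratio_distal + epsilon) / (ratio_proximal + epsilon))


def attach_cluster_m6a(clusters: Sequence[PolyACluster],
                       read_calls: Iterable[ReadSiteCall],
                       passing_sites: set[tuple[str, int]] | None = None) -> None:
    """Compute each cluster's m6A ratio from its own reads' site calls.

    The ratio is read-site-call weighted: modified calls / total calls over
    the cluster's reads, restricted to sites in ``passing_sites`` (pairs of
    (transcript_id, tpos)) when given.
    """
    calls_by_read: dict[str, list[ReadSiteCall]] = {}
    for c in read_calls:
        if passing_sites is not None and (c.transcript_id, c.center_pos) not in passing_sites:
            continue
        calls_by_read.setdefault(c.read_id, []).append(c)
    for cluster in clusters:
        n_mod = n_total = 0
        for rid in cluster.read_ids:
            for call in calls_by_read.get(rid, ()):
                n_total += 1
                n_mod += call.modified
        cluster.m6a_calls = n_total
        cluster.m6a_ratio = (n_mod / n_total) if n_total else None


def apa_fold_change_table(clusters: Sequence[PolyACluster], epsilon: float = 0.01,
                          min_cluster_reads: int = 10) -> pd.DataFrame:
    """Per-gene distal-vs-proximal methylation log2 fold changes.

    Genes where either isoform lacks covered passing site calls, or has
    fewer than ``min_cluster_reads`` reads with calls, are absent.
    """
    rows = []
    by_gene: dict[str, dict[str, PolyACluster]] = {}
    for c in clusters:
        if c.role in ("proximal", "distal"):
            by_gene.setdefault(c.gene_id, {})[c.role] = c
    for gene_id, roles in sorted(by_gene.items()):
        if "proximal" not in roles or "distal" not in roles:
            continue
        p, d = roles["proximal"], roles["distal"]
        if p.m6a_ratio is None or d.m6a_ratio is None:
            continue
        if p.m6a_calls < min_cluster_reads or d.m6a_calls < min_cluster_reads:
            continue
        rows.append(
            (gene_id, p.m6a_ratio, d.m6a_ratio,
             apa_methylation_fold_change(d.m6a_ratio, p.m6a_ratio, epsilon))
        )
    return pd.DataFrame(rows, columns=["gene_id", "ratio_proximal", "ratio_distal", "log2_fc"])


def clusters_frame(clusters: Sequence[PolyACluster]) -> pd.DataFrame:
    """Tabular cluster summary for export."""
    rows = [
        (c.gene_id, c.chrom, c.strand, c.representative, c.count,
         c.polya_mean, c.polya_median, c.role if c.role else "none",
         c.m6a_ratio if c.m6a_ratio is not None else math.nan, c.m6a_calls)
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "representative", "n_reads",
                 "polya_mean", "polya_median", "role", "m6a_ratio", "m6a_calls"],
    )
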