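"""Per-site stoichiometry: aggregate read calls, filter, map, compare.

Per-read modification probabilities are binarized (default cut 0.5, ties to
modified) and aggregated per transcript position into modified/total counts;
the m6A ratio of a site is n_mod/n_total.  A site is reported as modified
when at least ``min_mod_reads`` (default 20) reads carry the modification.
Transcript coordinates are lifted to genome coordinates by walking the
CIGAR of a transcript-to-genome alignment base by base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam

from . import model as _model
from .sigio import SiteFeatureVector

__all__ = [
    "ReadSiteCall",
    "ConditionComparison",
    "binarize",
    "calls_from_vectors",
    "aggregate_sites",
    "map_to_genome",
    "annotate_genomic",
    "pool_genomic",
    "compare_conditions",
    "gene_m6a_level",
    "write_sites",
    "write_bed",
    "read_calls_frame",
]

SITE_COLUMNS = [
    "chrom", "pos", "strand", "transcript_id", "tpos",
    "motif", "n_mod", "n_total", "ratio", "pass_filter",
]


@dataclass(frozen=True)
class ReadSiteCall:
    """One read's modification call at one RRACH site."""

    read_id: str
    transcript_id: str
    center_pos: int
    motif: str
    probability: float
    call: str  # "modified" | "unmodified"

    @property
    def modified(self) -> bool:
        return self.call == "modified"


def binarize(probability: float, threshold: float = 0.5) -> str:
    """Call a read modified iff its probability >= threshold (ties modified)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability out of range: {probability}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold out of range: {threshold}")
    return "modified" if probability >= threshold else "unmodified"


def calls_from_vectors(bundle: "_model.ModelBundle",
                       vectors: Sequence[SiteFeatureVector],
                       threshold: float = 0.5) -> list[ReadSiteCall]:
    """Predict and binarize every feature vector against the bundle."""
    probs = _model.predict_many(bundle, vectors)
    return [
        ReadSiteCall(v.read_id, v.transcript_id, v.center_pos, v.motif,
                     float(p), binarize(float(p), threshold))
        for v, p in zip(vectors, probs)
    ]


def read_calls_frame(calls: Iterable[ReadSiteCall]) -> pd.DataFrame:
    """Tabular view of per-read calls."""
    return pd.DataFrame(
        [(c.read_id, c.transcript_id, c.center_pos, c.motif, c.probability, c.call)
         for c in calls],
        columns=["read_id", "transcript_id", "center_pos", "motif", "probability", "call"],
    )


def aggregate_sites(calls: Iterable[ReadSiteCall], min_mod_reads: int = 20) -> pd.DataFrame:
    """Per-site modified/total counts and stoichiometry ratio.

    All sites are returned; ``pass_filter`` records whether the site reaches
    the modified-read support cut (n_mod >= min_mod_reads).  Downstream
    analyses default to pass-filter sites only.
    """
    rows: dict[tuple[str, int], list] = {}
    for c in calls:
        key = (c.transcript_id, c.center_pos)
        if key not in rows:
            rows[key] = [c.motif, 0, 0]
        rows[key][2] += 1
        if c.modified:
            rows[key][1] += 1
    records = [
        (tid, pos, motif, n_mod, n_total, n_mod / n_total, n_mod >= min_mod_reads)
        for (tid, pos), (motif, n_mod, n_total) in sorted(rows.items())
    ]
    return pd.DataFrame(
        records,
        columns=["transcript_id", "tpos", "motif", "n_mod", "n_total", "ratio", "pass_filter"],
    )


def _query_to_ref(aln: pysam.AlignedSegment) -> dict[int, int]:
    """Query-position -> 0-based reference-position map over aligned bases."""
    return {q: r for q, r in aln.get_aligned_pairs(matches_only=True)}


def map_to_genome(transcript_pos: int, aln: pysam.AlignedSegment,
                  _pairs: dict[int, int] | None = None) -> tuple[str, int, str] | None:
    """Lift a 0-based transcript position to (chrom, 1-based pos, strand).

    M/=/X CIGAR operations advance both coordinates, insertions advance the
    transcript only, deletions and introns (D/N) advance the genome only.
    A reverse-strand alignment stores the reverse complement of the
    transcript, so transcript position ``t`` corresponds to query position
    ``L-1-t``.  Positions falling in an insertion or outside the alignment
    are unmappable and return None.
    """
    qlen = aln.infer_query_length()
    if aln.is_reverse:
        qpos = qlen - 1 - transcript_pos
    else:
        qpos = transcript_pos
    pairs = _pairs if _pairs is not None else _query_to_ref(aln)
    rpos = pairs.get(qpos)
    if rpos is None:
        return None
    strand = "-" if aln.is_reverse else "+"
    return aln.reference_name, rpos + 1, strand


def annotate_genomic(sites: pd.DataFrame, alignments: Iterable[pysam.AlignedSegment]) -> pd.DataFrame:
    """Add chrom/pos/strand columns to a site table via per-transcript alignments.

    Alignments are keyed by query name (the transcript id); sites whose
    transcript has no alignment, or whose position is not covered by an
    aligned base, are kept with missing genomic fields.
    """
    by_tid: dict[str, tuple[pysam.AlignedSegment, dict[int, int]]] = {}
    for aln in alignments:
        if aln.is_unmapped:
            continue
        by_tid[aln.query_name] = (aln, _query_to_ref(aln))
    chroms, gpos, strands = [], [], []
    for tid, tpos in zip(sites["transcript_id"], sites["tpos"]):
        entry = by_tid.get(tid)
        hit = map_to_genome(int(tpos), entry[0], entry[1]) if entry else None
        if hit is None:
            chroms.append(pd.NA)
            gpos.append(pd.NA)
            strands.append(pd.NA)
        else:
            chroms.append(hit[0])
            gpos.append(hit[1])
            strands.append(hit[2])
    out = sites.copy()
    out["chrom"] = chroms
    out["pos"] = pd.array(gpos, dtype="Int64")
    out["strand"] = strands
    return out


def pool_genomic(sites: pd.DataFrame, min_mod_reads: int = 20) -> pd.DataFrame:
    """Pool reads from transcripts sharing a genomic A into genome-level sites."""
    mapped = sites.dropna(subset=["chrom", "pos", "strand"])
    grouped = (
        mapped.groupby(["chrom", "pos", "strand"], sort=True)
        .agg(motif=("motif", "first"), n_mod=("n_mod", "sum"), n_total=("n_total", "sum"))
        .reset_index()
    )
    grouped["ratio"] = grouped["n_mod"] / grouped["n_total"]
    grouped["pass_filter"] = grouped["n_mod"] >= min_mod_reads
    return grouped


@dataclass
class ConditionComparison:
    """Exact-coordinate overlap of two pass-filter site sets."""

    n_a: int
    n_b: int
    n_shared: int
    n_a_only: int
    n_b_only: int
    shared: pd.DataFrame  # key columns + ratio_a, ratio_b, delta
    median_delta: float


def compare_conditions(sites_a: pd.DataFrame, sites_b: pd.DataFrame,
                       key: str = "auto") -> ConditionComparison:
    """Intersect two pass-filter site tables and report per-site ratio deltas.

    Keys on (chrom, pos, strand) when both tables carry genomic coordinates,
    else on (transcript_id, tpos); ``key`` may force "genomic" or
    "transcript".
    """
    a = sites_a[sites_a["pass_filter"]].copy()
    b = sites_b[sites_b["pass_filter"]].copy()
    genomic_cols = ["chrom", "pos", "strand"]
    has_genomic = all(c in a.columns for c in genomic_cols) and all(
        c in b.columns for c in genomic_cols
    )
    if key == "auto":
        key = "genomic" if has_genomic else "transcript"
    if key == "genomic":
        if not has_genomic:
            raise ValueError("genomic keying requested but a table lacks genomic columns")
        cols = genomic_cols
        a = a.dropna(subset=cols)
        b = b.dropna(subset=cols)
    elif key == "transcript":
        cols = ["transcript_id", "tpos"]
    else:
        raise ValueError(f"unknown keying: {key!r}")
    merged = a[cols + ["ratio"]].merge(
        b[cols + ["ratio"]], on=cols, how="inner", suffixes=("_a", "_b")
    )
    merged["delta"] = merged["ratio_b"] - merged["ratio_a"]
    n_shared = len(merged)
    return ConditionComparison(
        n_a=len(a),
        n_b=len(b),
        n_shared=n_shared,
        n_a_only=len(a) - n_shared,
        n_b_only=len(b) - n_shared,
        shared=merged,
        median_delta=float(merged["delta"].median()) if n_shared else float("nan"),
    )


def gene_m6a_level(sites: pd.DataFrame, tx2gene: dict[str, str]) -> pd.Series:
    """Unweighted mean ratio of pass-filter sites per gene.

    Genes with no passing site are absent from the output.
    """
    passing = sites[sites["pass_filter"]].copy()
    passing["gene_id"] = passing["transcript_id"].map(tx2gene)
    passing = passing.dropna(subset=["gene_id"])
    return passing.groupby("gene_id")["ratio"].mean()


def write_sites(sites: pd.DataFrame, path) -> None:
    """Site table TSV with the documented column order."""
    out = sites.copy()
    for col in SITE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[SITE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_bed(sites: pd.DataFrame, path) -> None:
    """BED6 export of mapped pass-filter sites; score = round(1000 * ratio)."""
    mapped = sites[sites["pass_filter"]].dropna(subset=["chrom", "pos", "strand"])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for _, row in mapped.iterrows():
            name = f"{row['transcript_id']}:{row['tpos']}:{row['motif']}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) - 1}\t{int(row['pos'])}\t"
                f"{name}\t{round(1000 * row['ratio'])}\t{row['strand']}\n"
            )
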