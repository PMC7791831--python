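"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of segmented direct-RNA
current: each base dwells in the pore for a geometric number of raw samples
(mean 8, minimum 3) drawn around a base-dependent current level with
Gaussian noise, and methylation of the central A of an RRACH motif shifts
the segment mean by ``mod_shift`` raw units and stretches its dwell by
``mod_dwell_factor``.  Three generators cover the pipeline's inputs:

* labeled single-motif reads for training (modified vs unmodified),
* read mixtures at known per-site stoichiometry for recovery experiments,
* an annotated transcriptome (FASTA/GTF/SAM/poly(A) TSV/event tables) with
  stop-codon-biased site placement and two poly(A) isoforms per APA gene.

Every generator is a pure function of (params, seed); random streams are
split per site and per read, so changing the depth of one site does not
reshuffle any other draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from . import model as _model
from . import quantify as _quantify
from .meta import TranscriptModel
from .polya_apa import ReadEndRecord
from .sigio import (
    EventRead,
    SiteFeatureVector,
    batch_read_site_vectors,
    write_events,
)

__all__ = [
    "SimParams",
    "LabeledEvents",
    "MixtureSim",
    "TranscriptomeSim",
    "simulate_read",
    "simulate_labeled_events",
    "simulate_mixture",
    "ratio_recovery_experiment",
    "summarize_recovery",
    "simulate_transcriptome",
]

_BASES = "ACGT"


@dataclass
class SimParams:
    """Generator settings; defaults define the reference study conditions.

    Current levels are arbitrary picoampere-like units.  ``mod_shift`` is
    the raw-unit mean shift of the modified central A and
    ``mod_dwell_factor`` the multiplier of its expected dwell.
    """

    seed: int = 0
    base_levels: dict = field(default_factory=lambda: {"A": 100.0, "C": 90.0, "G": 110.0, "T": 80.0})
    noise_sd: float = 2.0
    dwell_mean: float = 8.0
    dwell_min: int = 3
    mod_shift: float = 3.0
    mod_dwell_factor: float = 1.5
    context_spill: float = 0.0  # fraction of mod_shift applied to +/-1 neighbors
    flank: int = 100  # random flanking bases around a planted motif
    # transcriptome shape
    n_genes: int = 100
    utr5_range: tuple[int, int] = (30, 60)
    cds_range: tuple[int, int] = (120, 240)
    utr3_range: tuple[int, int] = (150, 250)
    intron_range: tuple[int, int] = (60, 200)
    apa_fraction: float = 0.5
    apa_offset: int = 80  # nt between proximal and distal cleavage (>= 50)
    sites_per_gene: int = 6
    stop_bias: float = 0.7  # mass of site placement near the stop codon
    ratio_proximal: float = 0.6
    ratio_distal: float = 0.3  # distal true ratio = proximal / 2
    depth: int = 100  # reads per isoform before expression scaling
    expression_sigma: float = 0.0  # log-normal sd of per-gene expression weight
    polya_mean_proximal: float = 45.0
    polya_mean_distal: float = 110.0
    polya_sd: float = 10.0
    end_jitter: int = 5  # max 3'-end scatter in nt (well inside the 24-nt window)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dwell_min < 1:
            raise ValueError("dwell_min must be >= 1")
        if self.dwell_mean < self.dwell_min:
            raise ValueError("dwell_mean must be >= dwell_min")
        if not 0.0 <= self.apa_fraction <= 1.0:
            raise ValueError("apa_fraction must be in [0, 1]")
        for name in ("ratio_proximal", "ratio_distal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.utr3_range[0] <= self.apa_offset + 2 * self.end_jitter:
            raise ValueError("3'UTR too short for the proximal/distal cleavage offset")

    def level_lut(self) -> np.ndarray:
        lut = np.zeros(256)
        for b, v in self.base_levels.items():
            lut[ord(b)] = v
        return lut


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) for k in keys])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def simulate_read(rng: np.random.Generator, params: SimParams, read_id: str,
                  transcript_id: str, seq: str,
                  modified_positions: Iterable[int] = ()) -> EventRead:
    """Generate one read's per-base segments over ``seq``.

    ``modified_positions`` are 0-based positions (the central A of a motif)
    carrying the modification on this molecule.
    """
    n = len(seq)
    lut = params.level_lut()
    levels = lut[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    dwell_means = np.full(n, params.dwell_mean)
    for pos in modified_positions:
        levels[pos] += params.mod_shift
        dwell_means[pos] *= params.mod_dwell_factor
        if params.context_spill:
            for off in (-1, 1):
                if 0 <= pos + off < n:
                    levels[pos + off] += params.context_spill * params.mod_shift
    p = 1.0 / (dwell_means - params.dwell_min + 1.0)
    dwells = params.dwell_min - 1 + rng.geometric(p)
    samples = rng.normal(np.repeat(levels, dwells), params.noise_sd)
    return EventRead.from_flat(read_id, transcript_id, 0, seq, samples, dwells)


# ---------------------------------------------------------------------------
# Labeled training events

@dataclass
class LabeledEvents:
    """Training reads with per-read modification labels and ground truth."""

    reads: list[EventRead]
    labels: pd.DataFrame  # read_id, transcript_id, position, motif, label

    def vectors(self) -> list[tuple[SiteFeatureVector, int]]:
        """Normalized center-site feature vectors paired with labels."""
        by_read = dict(zip(self.labels["read_id"], zip(self.labels["position"], self.labels["label"])))
        centers = {r.transcript_id: int(by_read[r.read_id][0]) for r in self.reads}
        vectors = batch_read_site_vectors(self.reads, centers=centers)
        return [(v, int(by_read[v.read_id][1])) for v in vectors]

    def write(self, events_path, labels_path, dialect: str = "raw") -> None:
        write_events(self.reads, events_path, dialect=dialect)
        self.labels.to_csv(labels_path, sep="\t", index=False, lineterminator="\n")


def simulate_labeled_events(params: SimParams, n_per_motif_per_class: int) -> LabeledEvents:
    """n modified + n unmodified single-motif reads for each of the 12 motifs.

    Each read is a planted motif with random flanks; the modification effect
    applies to the central A only.
    """
    if n_per_motif_per_class < 1:
        raise ValueError("need at least one read per motif and class")
    reads: list[EventRead] = []
    rows = []
    center = params.flank + 2
    for mi, motif in enumerate(_model.enumerate_rrach_motifs()):
        for label in (0, 1):
            for i in range(n_per_motif_per_class):
                rng = _rng(params.seed, 1, mi, label, i)
                seq = _random_seq(rng, params.flank) + motif + _random_seq(rng, params.flank)
                read_id = f"{motif}_{'mod' if label else 'unm'}_{i}"
                read = simulate_read(rng, params, read_id, read_id, seq,
                                     modified_positions=[center] if label else [])
                reads.append(read)
                rows.append((read_id, read_id, center, motif, label))
    labels = pd.DataFrame(rows, columns=["read_id", "transcript_id", "position", "motif", "label"])
    return LabeledEvents(reads, labels)


# ---------------------------------------------------------------------------
# Known-ratio mixtures

@dataclass
class MixtureSim:
    """Reads mixed at known per-site stoichiometry."""

    reads: list[EventRead]
    truth: pd.DataFrame  # transcript_id, center_pos, motif, true_ratio, n_mod, depth
    centers: dict[str, int]

    def center_vectors(self) -> list[SiteFeatureVector]:
        return batch_read_site_vectors(self.reads, centers=self.centers)


def simulate_mixture(params: SimParams, true_ratio: float, depth: int,
                     n_sites: int, tag: int = 0, site_offset: int = 0) -> MixtureSim:
    """Per site, Binomial(depth, true_ratio) modified reads among ``depth``.

    Each site lives on its own short synthetic transcript (planted motif,
    random flanks); ``tag`` separates the random streams of independent
    experiments run at the same seed, and ``site_offset`` shifts the site
    indices so an experiment can be generated in chunks without reusing any
    random stream.
    """
    if not 0.0 <= true_ratio <= 1.0:
        raise ValueError("true_ratio must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    motifs = _model.enumerate_rrach_motifs()
    center = params.flank + 2
    reads: list[EventRead] = []
    rows = []
    centers: dict[str, int] = {}
    for si in range(n_sites):
        s = si + site_offset
        site_rng = _rng(params.seed, 2, tag, s)
        motif = motifs[s % len(motifs)]
        seq = _random_seq(site_rng, params.flank) + motif + _random_seq(site_rng, params.flank)
        n_mod = int(site_rng.binomial(depth, true_ratio))
        tid = f"mix{tag}_site{s}"
        centers[tid] = center
        for r in range(depth):
            rng = _rng(params.seed, 2, tag, s, r)
            read = simulate_read(rng, params, f"{tid}_r{r}", tid, seq,
                                 modified_positions=[center] if r < n_mod else [])
            reads.append(read)
        rows.append((tid, center, motif, true_ratio, n_mod, depth))
    truth = pd.DataFrame(
        rows, columns=["transcript_id", "center_pos", "motif", "true_ratio", "n_mod", "depth"]
    )
    return MixtureSim(reads, truth, centers)


def ratio_recovery_experiment(bundle: "_model.ModelBundle", params: SimParams,
                              ratios: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1)),
                              depths: Sequence[int] = (20, 50, 100),
                              reps: int = 200,
                              threshold: float = 0.5) -> pd.DataFrame:
    """Full predict->binarize->aggregate pipeline on known-ratio mixtures.

    ``reps`` replicate sites are simulated per (depth, ratio) cell; the
    returned frame has one row per site with its estimated and true ratio.
    Sites are generated and reduced to feature vectors in small chunks so
    the working set stays bounded regardless of depth and rep count.
    """
    if not bundle.models or not any(m.trainable for m in bundle.models.values()):
        raise ValueError("untrained bundle")
    chunk = max(1, 2000 // max(int(d) for d in depths))
    frames = []
    for di, depth in enumerate(depths):
        for ri, ratio in enumerate(ratios):
            vectors: list[SiteFeatureVector] = []
            truths = []
            for offset in range(0, reps, chunk):
                sim = simulate_mixture(params, float(ratio), int(depth),
                                       min(chunk, reps - offset),
                                       tag=1000 * di + ri, site_offset=offset)
                vectors.extend(sim.center_vectors())
                truths.append(sim.truth)
            calls = _quantify.calls_from_vectors(bundle, vectors, threshold)
            sites = _quantify.aggregate_sites(calls, min_mod_reads=0)
            est = sites.set_index("transcript_id")["ratio"]
            truth = pd.concat(truths, ignore_index=True).set_index("transcript_id")
            frames.append(pd.DataFrame({
                "depth": depth,
                "true_ratio": float(ratio),
                "site": truth.index,
                "sampled_mod_fraction": truth["n_mod"] / truth["depth"],
                "estimate": est.reindex(truth.index).to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per-depth Pearson correlation and mean absolute error vs truth."""
    rows = []
    for depth, grp in table.groupby("depth"):
        if grp["true_ratio"].nunique() < 2:
            corr = math.nan  # degenerate grid: correlation undefined
        else:
            corr = float(np.corrcoef(grp["true_ratio"], grp["estimate"])[0, 1])
        mae = float(np.abs(grp["estimate"] - grp["true_ratio"]).mean())
        rows.append((int(depth), corr, mae))
    return pd.DataFrame(rows, columns=["depth", "pearson", "mae"])


# ---------------------------------------------------------------------------
# Annotated transcriptome with APA isoforms


@dataclass
class _GeneLayout:
    gene_id: str
    chrom: str
    strand: str
    gstart: int  # 0-based genomic start of the gene span
    exon1: int  # genomic length of the left exon
    intron: int
    exon2: int
    utr5: int
    cds: int
    utr3: int
    apa: bool
    cleave_distal: int  # transcript length of the distal isoform
    cleave_proximal: int
    site_positions: list[int]  # transcript coords (distal isoform) of planted sites
    site_motifs: list[str]
    depth: int
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.exon1 + self.exon2

    def t2g(self, tpos: int) -> int:
        """0-based genomic position of a transcript position (distal coords)."""
        q = tpos if self.strand == "+" else self.length - 1 - tpos
        if q < self.exon1:
            return self.gstart + q
        return self.gstart + self.exon1 + self.intron + (q - self.exon1)

    def genomic_intervals(self, tlen: int) -> list[tuple[int, int]]:
        """Sorted 0-based half-open genomic intervals covering [0, tlen)."""
        g = sorted(self.t2g(t) for t in (0, tlen - 1))
        lo, hi = g[0], g[1] + 1
        ex1 = (self.gstart, self.gstart + self.exon1)
        ex2_start = self.gstart + self.exon1 + self.intron
        ex2 = (ex2_start, ex2_start + self.exon2)
        out = []
        for s, e in (ex1, ex2):
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                out.append((cs, ce))
        return out


@dataclass
class TranscriptomeSim:
    """Mutually consistent FASTA/GTF/SAM/event/poly(A) views of one simulation."""

    params: SimParams
    genes: pd.DataFrame
    sites: pd.DataFrame  # per-site truth, transcript coords of the distal isoform
    transcripts: dict[str, str]  # transcript_id -> sequence
    tx2gene: dict[str, str]
    models: dict[str, TranscriptModel]
    reads: list[EventRead]
    read_isoform: dict[str, str]  # read_id -> transcript_id
    polya: list[ReadEndRecord]
    header: pysam.AlignmentHeader
    alignments: list[pysam.AlignedSegment]

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for tid, seq in self.transcripts.items():
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self._gtf_text())

    def _gtf_text(self) -> str:
        lines = []
        for tid, model in self.models.items():
            gid = self.tx2gene[tid]
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            chrom = self.header.references[0]
            for s, e in model.exons:
                lines.append(
                    f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}"
                )
            for s, e in self._cds_intervals(tid):
                lines.append(
                    f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t0\t{attrs}"
                )
        return "\n".join(lines) + "\n"

    def _cds_intervals(self, tid: str) -> list[tuple[int, int]]:
        model = self.models[tid]
        layout = self._layouts[self.tx2gene[tid]]
        g = sorted(layout.t2g(t) for t in (model.cds_start, model.cds_end - 1))
        lo, hi = g[0], g[1] + 1
        return [(max(s, lo), min(e, hi)) for s, e in model.exons if max(s, lo) < min(e, hi)]

    def write_sam(self, path) -> None:
        with pysam.AlignmentFile(str(path), "w", header=self.header) as fh:
            for aln in self.alignments:
                fh.write(aln)

    def write_events(self, path, dialect: str = "raw") -> None:
        write_events(self.reads, path, dialect=dialect)

    def write_polya(self, path) -> None:
        rows = [
            (r.read_id, r.gene_id, r.chrom, r.end_pos, r.strand, r.polya_length, r.qc_tag)
            for r in self.polya
        ]
        pd.DataFrame(rows, columns=["read_id", "gene_id", "chrom", "end_pos", "strand",
                                    "polya_length", "qc_tag"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )

    # populated by the generator
    _layouts: dict[str, _GeneLayout] = None  # type: ignore[assignment]

    def site_vectors(self) -> list[SiteFeatureVector]:
        """Normalized feature vectors for every RRACH hit on every read."""
        return batch_read_site_vectors(self.reads)

    def expression_counts(self) -> pd.Series:
        """Reads per gene (the DRS expression proxy)."""
        counts: dict[str, int] = {}
        for read in self.reads:
            gid = self.tx2gene[read.transcript_id]
            counts[gid] = counts.get(gid, 0) + 1
        return pd.Series(counts).sort_index()


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _draw_site_positions(rng: np.random.Generator, params: SimParams,
                         utr5: int, cds: int, utr3: int) -> list[int]:
    """Stop-codon-biased placement: 70% mass in the last CDS decile and the
    first 3'UTR decile, the rest uniform over the transcript."""
    length = utr5 + cds + utr3
    stop = utr5 + cds
    positions: set[int] = set()
    attempts = 0
    while len(positions) < params.sites_per_gene and attempts < 300:
        attempts += 1
        u = rng.random()
        if u < params.stop_bias / 2:
            pos = int(rng.integers(max(2, stop - max(1, cds // 10)), stop))
        elif u < params.stop_bias:
            pos = int(rng.integers(stop, stop + max(1, utr3 // 10)))
        else:
            pos = int(rng.integers(2, length - 3))
        if all(abs(pos - q) >= 6 for q in positions) and 2 <= pos < length - 3:
            positions.add(pos)
    return sorted(positions)


def simulate_transcriptome(params: SimParams) -> TranscriptomeSim:
    """Genes with UTR/CDS structure, planted m6A sites, and APA isoforms.

    A fraction ``apa_fraction`` of genes carries two poly(A) isoforms whose
    cleavage sites sit ``apa_offset`` nt apart in the 3'UTR; the distal
    isoform's true per-site modification ratio is half the proximal one and
    its poly(A) tails are drawn around a mean more than two-fold longer.
    """
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    motifs = _model.enumerate_rrach_motifs()
    chrom = "chr1"
    layouts: dict[str, _GeneLayout] = {}
    cursor = 1000
    gene_rows = []
    site_rows = []
    transcripts: dict[str, str] = {}
    tx2gene: dict[str, str] = {}
    models: dict[str, TranscriptModel] = {}
    reads: list[EventRead] = []
    read_isoform: dict[str, str] = {}
    polya: list[ReadEndRecord] = []

    for g in range(params.n_genes):
        grng = _rng(params.seed, 3, g)
        gene_id = f"gene{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        utr5 = int(grng.integers(*params.utr5_range))
        cds = int(grng.integers(params.cds_range[0] // 3, params.cds_range[1] // 3)) * 3
        utr3 = int(grng.integers(*params.utr3_range))
        length = utr5 + cds + utr3
        intron = int(grng.integers(*params.intron_range))
        boundary = utr5 + cds // 2  # exon boundary in transcript coords, inside the CDS
        exon1 = boundary if strand == "+" else length - boundary
        exon2 = length - exon1
        apa = bool(grng.random() < params.apa_fraction)
        cleave_proximal = length - params.apa_offset
        depth = params.depth
        if params.expression_sigma > 0:
            depth = max(20, int(round(params.depth * grng.lognormal(0.0, params.expression_sigma))))
        site_positions = _draw_site_positions(grng, params, utr5, cds, utr3)
        site_motifs = [motifs[int(grng.integers(0, len(motifs)))] for _ in site_positions]

        seq = list(_random_seq(grng, length))
        # stop codon closes the CDS; planted motifs stamped afterwards
        seq[utr5 + cds - 3 : utr5 + cds] = list("TAA")
        for pos, motif in zip(site_positions, site_motifs):
            seq[pos - 2 : pos + 3] = list(motif)
        sequence = "".join(seq)

        layout = _GeneLayout(gene_id, chrom, strand, cursor, exon1, intron, exon2,
                             utr5, cds, utr3, apa, length, cleave_proximal,
                             site_positions, site_motifs, depth, sequence)
        layouts[gene_id] = layout
        cursor += exon1 + intron + exon2 + 500

        isoforms = [("D", length, params.ratio_distal if apa else params.ratio_proximal,
                     params.polya_mean_distal)]
        if apa:
            isoforms.append(("P", cleave_proximal, params.ratio_proximal,
                             params.polya_mean_proximal))
        for iso_tag, tlen, ratio, polya_mean in isoforms:
            tid = f"{gene_id}.{iso_tag}"
            iso_seq = sequence[:tlen]
            transcripts[tid] = iso_seq
            tx2gene[tid] = gene_id
            models[tid] = TranscriptModel(
                tid, gene_id, strand, layout.genomic_intervals(tlen),
                cds_start=utr5, cds_end=utr5 + cds,
            )
            covered = [p for p in site_positions if p + 3 <= tlen]
            for ri in range(depth):
                rng = _rng(params.seed, 4, g, 0 if iso_tag == "D" else 1, ri)
                mods = [p for p in covered if rng.random() < ratio]
                read_id = f"{tid}_r{ri}"
                reads.append(simulate_read(rng, params, read_id, tid, iso_seq, mods))
                read_isoform[read_id] = tid
                jitter = int(rng.integers(0, params.end_jitter + 1))
                end_g = layout.t2g(tlen - 1 - jitter) + 1  # 1-based
                tail = max(5.0, float(rng.normal(polya_mean, params.polya_sd)))
                polya.append(ReadEndRecord(read_id, gene_id, chrom, end_g, strand, tail, "PASS"))

        gene_rows.append((gene_id, strand, apa, depth, utr5, cds, utr3,
                          params.ratio_proximal if True else None,
                          params.ratio_distal if apa else math.nan,
                          layout.t2g(utr5 + cds - 1) + 1))
        for pos, motif in zip(site_positions, site_motifs):
            site_rows.append((gene_id, f"{gene_id}.D", pos, motif, layout.t2g(pos) + 1,
                              pos + 3 <= cleave_proximal if apa else True))

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "strand", "apa", "depth", "utr5", "cds", "utr3",
                 "ratio_proximal", "ratio_distal", "stop_codon_genomic"],
    )
    sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "transcript_id", "tpos", "motif", "genomic_pos", "on_proximal"],
    )

    glen = cursor + 1000
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": chrom, "LN": glen}]}
    )
    alignments = []
    for tid, seq in transcripts.items():
        layout = layouts[tx2gene[tid]]
        intervals = models[tid].exons
        aln = pysam.AlignedSegment(header)
        aln.query_name = tid
        aln.flag = 16 if layout.strand == "-" else 0
        aln.reference_id = 0
        aln.reference_start = intervals[0][0]
        cig = []
        for (s1, e1), (s2, _e2) in zip(intervals, intervals[1:]):
            cig.append(f"{e1 - s1}M{s2 - e1}N")
        cig.append(f"{intervals[-1][1] - intervals[-1][0]}M")
        aln.cigarstring = "".join(cig)
        aln.query_sequence = seq if layout.strand == "+" else seq.translate(_REVCOMP)[::-1]
        aln.mapping_quality = 60
        alignments.append(aln)

    sim = TranscriptomeSim(params, genes, sites, transcripts, tx2gene, models,
                           reads, read_isoform, polya, header, alignments)
    sim._layouts = layouts
    return sim
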