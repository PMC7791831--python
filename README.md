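# nanostoich

Single-base, single-read detection of N6-methyladenosine (m6A) from
segmented Nanopore direct-RNA-sequencing (DRS) current signals, with
per-site stoichiometry, metagene profiling, and coupling of methylation to
alternative polyadenylation (APA).

## Who this is for

Groups running Nanopore direct RNA sequencing who want m6A calls at
single-nucleotide, single-molecule resolution — not just "a peak near this
region" — plus the downstream quantities that depend on per-read calls:
the fraction of modified molecules at each site, where modification sits
along transcripts, and whether proximal and distal poly(A) isoforms of the
same gene carry different methylation levels.

## The method

m6A in mRNA occurs almost exclusively in the RRACH context
(R = A/G, H = A/C/U), which expands to 12 concrete 5-mers. A re-squiggle
step upstream (e.g. Tombo) assigns raw pore current samples to individual
reference bases; this package consumes those per-base segments as a
portable TSV event table.

For every read, the current is normalized per read by median shift and
median-absolute-deviation (MAD) scale. Every RRACH occurrence on every
read is summarized by 20 numbers — mean, median, population standard
deviation, and dwell (sample count) for each of the five motif bases —
and scored by a gradient-boosted tree ensemble (XGBoost,
ŷᵢ = Σₖ fₖ(xᵢ) over K trees with a logistic loss plus complexity
penalty). One ensemble is trained per motif; a read's vector is routed to
the model of its own 5-mer.

Per-read probabilities are binarized at 0.5 and aggregated per site:

    m6A ratio = modified reads / total DRS reads

A site is reported as methylated when at least 20 reads carry the
modification. Transcript coordinates are lifted to the genome by a
per-base CIGAR walk over transcript-to-genome alignments (SAM/BAM).
Metagene profiles place sites on a scaled 5'UTR/CDS/3'UTR axis; read
3'-ends are chained into poly(A)-site clusters (gap ≤ 24 nt), proximal
and distal isoforms are assigned relative to the stop codon, genes with a
≥ 2-fold proximal/distal poly(A)-length difference are screened as APA
genes, and methylation coupling is summarized as
log2((ratio_D + ε)/(ratio_P + ε)).

Because real DRS accessions are not bundled, the `simulate` module
generates every input with known ground truth: labeled training events,
read mixtures at known stoichiometry, and an annotated synthetic
transcriptome (FASTA + GTF + SAM + event tables + poly(A) table) with
stop-codon-biased site placement and two poly(A) isoforms per APA gene.

## Worked example

Train on simulated labeled events, then analyze a simulated 10-gene
transcriptome (80 reads per isoform):

```bash
nanostoich simulate labeled --seed 11 --n 150 --out train/
nanostoich train --events train/events.tsv --labels train/labels.tsv \
    --out bundle.nsm --seed 11
# held-out: AUC=0.9583 acc=0.8917 TPR=0.8778 FPR=0.0944

nanostoich simulate transcriptome --seed 11 --genes 10 --depth 80 --out tx/
nanostoich quantify --bundle bundle.nsm --events tx/events.tsv \
    --min-mod-reads 20 --sam tx/tx2genome.sam --out sites.tsv
# 170 sites (94 pass filter) written to sites.tsv
```

The site table gives one row per RRACH position per transcript:

```
chrom  pos   strand  transcript_id  tpos  motif  n_mod  n_total  ratio   pass_filter
chr1   1016  +       gene0000.D     15    GGACT  11     80       0.1375  False
chr1   1044  +       gene0000.D     43    AGACT  36     80       0.45    True
```

`n_mod`/`n_total` are modified and total read counts; `ratio` is the
estimated stoichiometry; `pass_filter` applies the ≥ 20-modified-read
support rule. Continuing with per-read calls, metagene profile, and APA:

```bash
nanostoich predict --bundle bundle.nsm --events tx/events.tsv --out readcalls.tsv
nanostoich profile --sites sites.tsv --gtf tx/annotation.gtf --bins 20 --out profile.tsv
nanostoich apa --readcalls readcalls.tsv --sites sites.tsv \
    --polya tx/polya.tsv --gtf tx/annotation.gtf --out apa/
```

`apa/foldchange.tsv` then reports, per APA gene, the m6A ratio of each
isoform's own reads and the distal-vs-proximal log2 fold change:

```
gene_id   ratio_proximal  ratio_distal  log2_fc
gene0000  0.629           0.369         -0.755
gene0001  0.521           0.308         -0.738
gene0006  0.620           0.329         -0.893
```

All six simulated APA genes are flagged by the two-fold poly(A)-length
screen (observed folds ≈ 2.35–2.45), and the negative fold changes
recover the simulated design in which distal isoforms carry half the
methylation of proximal ones (true ratios 0.3 vs 0.6; the residual offset
from log2(0.5) is the classifier's calibration bias, which shrinks as the
classifier improves).

The same workflow is available as library calls (`nanostoich.simulate`,
`.model`, `.quantify`, `.meta`, `.polya_apa`) for scripted analyses.

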