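# Methods

## Signal model and feature extraction

A direct-RNA read enters the pipeline already segmented: each reference
base owns a contiguous run of raw current samples (the output of a
re-squiggle step such as Tombo's). The pipeline never sees FAST5 files;
the portable event table (raw dialect: one row per base with its
comma-separated samples; feature dialect: one row per base with mean,
median, std, dwell) is the interchange format.

Each read is normalized independently: every sample x becomes
(x − shift)/scale with shift = median and scale = MAD over the pooled
samples of that read. The MAD is unscaled (no 1.4826 normal-consistency
factor), matching the usual re-squiggle convention. A read whose samples
are all identical has MAD 0; the scale falls back to 1 and the read is
flagged rather than dropped. Because the transform is affine and
monotone, mean and median transform exactly and std scales by 1/scale;
the batched extraction path exploits this by computing raw segment
statistics first and normalizing the statistics, which the test suite
verifies agrees with the per-read path to 1e-9.

Each RRACH occurrence (the 12 expansions of [AG][AG]AC[ACT]; U read as
T; windows containing N skipped; overlapping hits all reported) is
described by 20 features: mean, median, population standard deviation,
and dwell (raw sample count) for each of the five motif bases, positions
−2..+2 around the central A. Dwell is a single feature; sample count and
duration are proportional at a fixed sampling rate, so they are not
carried separately. Windows truncated by a read boundary are skipped with
reason "edge".

Coordinates are 0-based in transcript space throughout; genomic output is
1-based.

## Per-motif classifiers

One gradient-boosted tree ensemble (XGBoost, `binary:logistic`, histogram
tree method) is trained per motif; prediction routes a vector to its own
motif's model and fails loudly for a motif with no trainable model.
Pooling across motifs is deliberately avoided: the five base identities
— and therefore the expected current levels of every window position —
differ by motif, so per-motif models see a homogeneous context.

Defaults: 100 trees, depth 6, learning rate 0.3, no class reweighting;
all overridable through `TrainConfig`. Training uses a stratified shuffle
split at a 4:1 train:test ratio; evaluation reports TP/FP/TN/FN,
TPR = TP/(TP+FN), FPR = FP/(FP+TN), accuracy, and ROC/AUC pooled over
motifs. The AUC sweeps thresholds over distinct scores with ties grouped,
making it exactly the Mann–Whitney pair statistic; the tests check this
against exhaustive pair counting. (Some descriptions of this evaluation
print TN/(FP+TN) under the name FPR; that expression is the specificity,
and the standard FPR is what a ROC curve requires, so the standard form
is implemented.) Cross-validation is stratified k-fold per motif with a
single pooled ROC over out-of-fold scores. Bundles serialize to a zip of
12 UBJ boosters plus JSON metadata (schema version, config, training-data
digest); reloading reproduces predictions bit for bit, and a schema
mismatch refuses to predict.

## Stoichiometry and genomic mapping

A read-site call is modified iff its probability ≥ 0.5 (ties modified;
threshold configurable). Per site, the m6A ratio is modified/total reads;
a site passes the support filter when at least 20 *modified* reads cover
it (`min_mod_reads`; interpreting modified-transcript support as a count
of modified reads, distinct from total-coverage cutoffs used for
cross-method comparisons). All sites are retained in the table with the
filter recorded; downstream analyses default to passing sites.

Transcript positions lift to the genome by a per-base walk of the
transcript-to-genome CIGAR (M/=/X advance both coordinates, I advances
the transcript, D/N advance the genome); reverse-strand alignments store
the reverse complement, so transcript position t maps to query position
L−1−t. Positions landing in insertions or outside the alignment are
kept in transcript space and excluded from genome-keyed analyses. Reads
from transcripts sharing a genomic A can be pooled by genomic coordinate
(`pool_genomic`); the transcript-level table is retained because APA
coupling needs it. Condition comparisons intersect pass-filter sites on
exact coordinates (genomic when available, else transcript) and report
per-site ratio deltas; no significance testing is attached.

## Metagene, exon lengths, correlation

Sites map to a scaled coordinate u ∈ [0,3): position/length within the
5'UTR, 1 + offset/length within the CDS, 2 + offset/length within the
3'UTR; a site exactly at the stop boundary lands at u = 2.0. Each region
gets `bins_per_region` equal bins (default 100); densities integrate to
1; bin counts always sum to the site count. Transcripts lacking a UTR
contribute nothing to that region's denominator. Exon-length comparison
reports medians and a Mann–Whitney U statistic without a p-value
interpretation. Gene expression is proxied by DRS read count per gene,
log10(count+1)-transformed for Pearson correlations against per-gene mean
m6A ratio (unweighted mean of passing site ratios).

## Poly(A) clusters and APA coupling

PASS-tagged read 3'-ends of a gene are clustered by single-linkage
chaining: sorted consecutive ends join one cluster while each gap is
≤ 24 nt (inclusive). Chaining, rather than a 24-nt diameter bound, is the
common poly(A)-cluster convention and is contract-tested against a
connected-components oracle. The representative site is the modal end,
ties broken toward the most 3' position. Among clusters with ≥ 10 reads
(the APA support default; chosen here, as the source text leaves it
open), the cluster nearest the stop codon in the direction of
transcription is proximal and the farthest distal; genes with fewer than
two qualifying clusters are non-APA. A gene is screened as an APA gene
when max(meanP, meanD)/min(meanP, meanD) ≥ 2 for the mean poly(A) tail
lengths (inclusive at exactly 2; undefined if a mean is 0). Methylation
coupling uses each cluster's own reads: the cluster ratio is modified
calls / total calls over those reads at passing sites, and the reported
statistic is log2((ratio_D + ε)/(ratio_P + ε)) with ε = 0.01 so zero
ratios stay finite.

## The synthetic-data generator

The generator emulates the statistical structure of segmented DRS
current, not pore physics. Per base: dwell ~ dwell_min − 1 + Geometric(p)
with mean 8 samples and minimum 3; samples ~ Normal(level, 2.0) in
arbitrary picoampere-like units with levels A=100, C=90, G=110, T=80.
Methylation of the central A shifts its segment mean by +3.0 raw units
and multiplies its expected dwell by 1.5; by default neighbors are
untouched (a context-spill option perturbs ±1 neighbors, off by
default). Every generator is a pure function of (params, seed), with
random streams split per (site, read) so changing one site's depth never
reshuffles another's draws; chunked generation reproduces monolithic runs
exactly.

Training/mixture reads plant one motif with 100 random flanking bases per
side (~200-nt reads). The flank length matters because normalization is
per read: with very short reads the median/MAD estimates themselves are
noisy and that noise, shared across the whole window, dominates the
feature variance; ~200 nt is short for real DRS but long enough that
normalization is stable, which is the regime real full-length reads live
in.

Mixtures draw each site's modified-read count as Binomial(depth, ratio).
The transcriptome generator builds genes with 5'UTR (30–60 nt), CDS
(120–240 nt, stop codon planted), 3'UTR (150–250 nt), one intron (60–200
nt) splitting the CDS, alternating strands; 6 RRACH sites per gene are
planted with 70% of their mass split between the last CDS decile and the
first 3'UTR decile (the rest uniform), emulating stop-codon-proximal
enrichment. Half the genes (configurable) carry two isoforms whose
cleavage sites sit 80 nt apart; proximal/distal true per-site ratios are
0.6/0.3 and poly(A) tail lengths Normal(45, 10)/Normal(110, 10) nt, so
the true length fold (~2.4) does not sit on the two-fold screen boundary.
Read 3'-ends jitter 0–5 nt, well inside the 24-nt window. FASTA, GTF,
SAM, event tables, and the poly(A) TSV are mutually consistent; the tests
round-trip planted site coordinates through the SAM and GTF exactly.

What the generator does not emulate: k-mer-dependent pore models beyond
single-base levels, re-squiggle segmentation errors, basecalling errors,
truncated or 3'-biased reads, multiple modification types sharing the
motif, and biological heterogeneity of per-site stoichiometry. Passing
tests therefore demonstrate that the pipeline's logic is correct and
recovers known truth under its stated signal model — not that any
particular accuracy will transfer to real flow-cell data.

## Numerical and design notes

- Population std (divide by n); dwell of a 1-sample segment is 1.
- Batched extraction pads segments into chunked matrices (~8M elements
  per chunk) and uses masked row reductions and row sorts; medians of
  even-length segments average the two central order statistics exactly
  as the reference implementation does.
- Stoichiometry recovery is evaluated against the binomial sampling band
  3·sqrt(r(1−r)/d) plus a classifier allowance fpr·(1−r) + fnr·r
  (+0.02 slack) with fpr/fnr measured on the held-out split: a binarizing
  caller estimates tpr·r + fpr·(1−r) in expectation, so the allowance is
  the systematic part of the error, not a fudge factor. The same
  calibration explains why the recovered distal/proximal APA fold change
  sits above log2(0.5): with held-out TPR ≈ 0.93 and FPR ≈ 0.07 the
  expected median is ≈ −0.8 rather than −1.
  Replicate counts in the bundled experiments are scaled to
  200 sites per condition (the underlying design used thousands); both
  are exposed as parameters.
- Degenerate inputs: empty reads and empty segments raise; MAD = 0 reads
  are flagged, not dropped; a single-ratio recovery grid yields an
  undefined (NaN) correlation rather than an error; motifs lacking two
  examples of each class are flagged untrainable and refuse to predict.
- The command-line interface is a thin layer over the library; every
  subcommand echoes its configuration as JSON next to its outputs and is
  deterministic given (config, seed).

## Known limitations

Single-modification model (m6A vs unmodified only); no statistical test
for differential methylation between conditions (descriptive deltas
only); reads are treated as full-length transcripts in the simulator;
per-site classifier calibration varies with sequence context, so
individual site ratios carry a context-dependent bias that averages out
across sites but is visible in small examples.
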