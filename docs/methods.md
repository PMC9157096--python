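# Methods

## The inference

In a total-RNA, rRNA-depleted sequencing library, reads mapping to introns
come almost entirely from nascent (not yet spliced) pre-mRNA, while reads
mapping to exons come from both nascent and mature transcripts. Between two
conditions, a gene whose *intron* signal changes is therefore undergoing a
change in transcription; a gene whose *exon* signal changes while its
intron signal does not is changing in mature-mRNA abundance only, i.e. is
regulated post-transcriptionally (stability/degradation). Single-exon
genes carry no intron evidence and are inherently inconclusive.

The pipeline implements this inference in five stages.

### 1. Feature catalog

Gene models are read from GFF3 (1-based closed coordinates converted to
0-based half-open at the boundary, and nowhere else). Per gene, the exon
territory is the union of all isoforms' exons — an exon skipped by one
isoform therefore stays exonic — and the intron territory is the gene span
minus that union. A genome-wide purge then removes from every gene's
introns any region that overlaps *any* gene's exon territory, so no base
is simultaneously exonic and intronic anywhere in the genome.

Design choices made here:

* **Exon-over-intron precedence.** Exon segments are never trimmed: an
  exonic base is unambiguous evidence of transcript sequence, whereas
  intron signal must be uncontaminated by mature-mRNA reads, so the intron
  side yields.
* **Strand-blind purge by default.** A nested gene on the opposite strand
  still removes its host's intron bases, because with a stranded protocol
  the read-level strand filter already separates the genes but boundary
  errors and antisense transcription make shared bases unsafe as intron
  evidence. `strand_aware=True` (CLI `--stranded-catalog`) restricts the
  purge to same-strand conflicts.
* **Same-class overlaps are shared.** Two genes' introns over the same
  bases remain intron territory of both; ambiguity is resolved per read
  (below), not by discarding annotation.
* Gene span is min-start to max-end over isoform exons; no minimum
  segment length is enforced by default.

The implementation is interval arithmetic (merge/subtract sweeps); its
correctness contract is exact agreement with a brute-force per-base
labeler, which the test suite checks on hundreds of random small genomes
with nesting and alternative isoforms enabled.

### 2. Read counting

Each retained single-end read is assigned to at most one (gene, class):
overlap base-counts are accumulated over the read's aligned blocks against
an interval index of the catalog, reads touching more than one gene are
dropped as ambiguous, and otherwise the class with the larger overlap wins
with ties going to exon (so 1-bp boundary jitter never inflates the intron
signal). Gapped (junction) reads contribute each block independently.

Defaults: reverse-stranded libraries (dUTP protocols — a read counts for
genes on the opposite strand); unique alignments only, judged by the NH
tag when present and by MAPQ ≥ 20 otherwise. Six read dispositions
(non-unique, low MAPQ, exon, intron, ambiguous, unassigned) are reported
per sample and must sum exactly to the record total; this conservation is
asserted at run time.

### 3. Differential testing

Each feature-class table is tested independently, in the DESeq tradition
but self-contained:

* **Size factors**: median-of-ratios over genes positive in every sample,
  rescaled to geometric mean 1.
* **Dispersion**: the per-gene method-of-moments value
  `(s² − μ)/μ²` (s² = pooled within-condition variance of normalized
  counts, μ = grand mean) is computed, and a mean–dispersion trend
  `a₀/μ + a₁` is fitted by least squares to the *untruncated* moment
  values of genes with μ > 1. Fitting only the positive values would bias
  the trend upward by selection. The working dispersion is the trend
  itself (`mode="trended"`): with 3 replicates per condition the gene-wise
  moment estimate has ~70 % coefficient of variation and feeding it into a
  Wald denominator miscalibrates the test in whichever direction it is
  combined — the gene-wise blend is anti-conservative, and flooring the
  blend at the trend over-corrects at low means. A trended (common)
  dispersion is the standard minimal-replicate choice; `"maximum"`
  (gene-wise floored at the trend) and `"blend"`
  (`w·α̂ + (1−w)·trend`, `w = n/(n+4)`) remain selectable for designs
  with more replicates or heavy-tailed gene-wise dispersion.
* **Wald test**: per gene, `z = log2(μ̂_A/μ̂_B) / SE` with the
  delta-method standard error of the log2 mean ratio on the normalized
  scale, `Var(μ̂_c) = (μ_c + α μ_c²)/n_c`; two-sided p from the standard
  normal; Benjamini–Hochberg adjustment within each table. Keeping the
  variance on the normalized scale makes every statistic invariant to
  rescaling a sample's column together with its size factor.
* The reported fold-change adds a pseudo-count of 0.5 to each condition
  mean so it stays finite; the test statistic never uses the pseudo-count.
* Genes with mean normalized count < 1 are marked untested (not dropped);
  non-integer input counts are rejected.

### 4. Classification

A gene is significant *for tissue A* in a table when tested,
`p_adjusted < 0.05` and `log2_fc > 1` (tissue B: `< −1`); all inequalities
strict, A being the numerator condition. Per tissue, the evidence is the
set of tables in which the gene is significant for that tissue:

| evidence | exons | call |
|---|---|---|
| intron-only or both | any | transcriptional |
| exon-only | ≥ 2 | post-transcriptional (multi-exon) |
| exon-only | 1 | inconclusive (single-exon) |

"Intron-only / exon-only / both" refers to significance status in the two
differential tables, not to raw read presence — the thresholds are applied
to the test output files and the sorting happens afterwards. A gene
significant for different tissues in the two tables receives one call per
tissue, each conflict-flagged; each call participates in its own tissue's
downstream sets.

### 5. Downstream joins

Overlap summaries (enhancer-linked gene lists, TF→target network coverage,
subgenome composition, per-TF target splits) are numerator/denominator
pairs whose percentages are re-rounded at the precision of the table they
feed (1 decimal, except subgenome composition at 2). A zero denominator is
reported as undefined, never as 0 %. Single-exon genes are removed from
enhancer lists before comparison, since they can never be called
transcriptional. GO-term enrichment is the one-sided Fisher exact
(hypergeometric upper tail) with Benjamini–Yekutieli control (valid under
dependence, matching agriGO-style tools), significance level 0.01,
and terms with fewer than 10 annotated background genes excluded. The
default background is the set of genes with at least one GO annotation;
gene-id translation across annotation versions is an optional two-column
synonym table applied at load (no remote lookups).

## The synthetic-data generator

The generator emulates the study design the method targets: two conditions
× 3 replicates of single-end 100-bp reverse-stranded reads. Per gene g and
condition c it posits a transcription rate τ_gc and a stability s_gc;
intron abundance ∝ τ, exon abundance ∝ τ·s. A transcriptional effect
multiplies τ by 2^lfc in the up tissue (moving intron and exon jointly), a
post-transcriptional effect multiplies s only (moving exon alone). Counts
are negative-binomial with shared dispersion.

Defaults and why:

* 10 % of genes transcriptionally and 5 % post-transcriptionally
  differential per tissue, |log2 FC| = 2, dispersion α = 0.05 — typical
  clean bulk-RNA-seq effect and noise levels.
* Baseline exon mean 500; intron:exon abundance ratio 0.1, reflecting the
  scarcity of the nascent fraction. Means are per-gene rate totals: τ
  absorbs feature length, so the configured means are what the count
  tables actually exhibit rather than depending on simulated segment
  lengths.
* Gene structure: single-exon probability 0.15, otherwise 2–20 exons
  uniform; genes nest inside other genes' introns at rate 0.05 when the
  drawn structure fits; 20 % of eligible genes get a second isoform
  skipping one internal exon.
* Auxiliary tables are enriched for the true classes (enhancer lists lean
  9:1 toward true transcriptional genes of their tissue; network targets
  6:1 toward DE genes; one spiked GO term is planted on 40 true
  transcriptional genes) so every downstream join has signal whose
  recovery can be asserted.

Alignment emission places each read wholly inside territory attributable
to exactly one (gene, class), and records the placement, so counting the
emitted SAM must reproduce the record exactly — an end-to-end identity the
tests assert. Every output is byte-identical under a fixed seed; each
stage draws from its own seed stream.

What the generator does **not** emulate: nucleotide content and sequencing
error, alignment uncertainty and multimapping structure, fragment-length
and positional biases, per-gene dispersion heterogeneity, correlated
replicates, partial intron retention. Passing recovery tests therefore
demonstrates the pipeline's logic and calibration under its own model
assumptions, not performance on real libraries.

## Problem sizes and numerical notes

The test suite and the acceptance script run the statistical checks at
2,000 genes × 6 samples (the calibration and recovery simulations), the
catalog-vs-per-base oracle at 120–200 genomes of ≤ 20 genes each, and the
counting identity at 150 genes (~35,000 reads) — sizes at which the
binomial noise of the measured rates sits comfortably inside the asserted
bands. Ties in read assignment go to exon; BH/BY adjustments enforce
step-up monotonicity; dispersions are floored at 1e-8; fold-change
pseudo-counts are 0.5 per condition mean; percentages are recomputable
from their stored numerator/denominator pairs.

Known limitations: single-end counting units only (paired-end mates would
need fragment-level deduplication); no GLM covariates, shrunken
fold-changes or outlier handling in the test; enrichment treats terms
independently (no ontology-graph propagation).
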