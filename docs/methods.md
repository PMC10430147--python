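# Methods

## Problem

Genome projects often hold two partially conflicting gene annotations: a
curated reference set (e.g. from NCBI) and a fresh pipeline-derived set
(e.g. from Maker fed with an RNA-seq-guided transcriptome).  `annomerge`
merges them into one annotation using interval overlap to pair up gene
models and protein homology to arbitrate disagreements, then prepares the
downstream expression matrix with TMM/FPKM normalization and a
replicate-similarity filter that removes uninformative genes.

## Annotation reconciliation

### Overlap components

Genes are compared on their genomic spans (1-based, closed GTF intervals).
Two genes from opposite annotations are linked when they share a seqid,
strand (by default), and overlap by at least `min_overlap_bp` (default 1).
Connected components of this bipartite graph are classified by side sizes
into `ref_only`, `pipe_only`, `one_to_one`, `one_to_many`, `many_to_one`
and `many_to_many`.  Span-level (rather than exon-level) comparison is
deliberate: the question at this stage is whether two models describe the
same locus; structural disagreement within a shared locus is settled by
homology, not geometry.

### Decision rules

* reference-only genes are always kept;
* pipeline-only genes are kept only with a significant homology hit
  (e-value ≤ `evalue_max`, default 1e-5 — a conventional protein-BLAST
  cutoff; the threshold is configurable and echoed in every report);
* one-to-one matches keep the reference structure;
* many-type components are arbitrated: genes without a significant hit are
  dropped; hit coordinates are scanned for fusion/fragmentation events
  (below); otherwise the side with the higher mean query coverage wins,
  exact ties going to the `coverage_tie_policy` (default
  `prefer_reference`, consistent with the one-to-one rule).

"Coverage" is query coverage: the fraction of a gene's protein length
covered by the union of its HSP query intervals, pooled across database
subjects.  Pooling reflects what the quantity measures — how much of the
locus is protein-supported — rather than per-subject identity.  Subject
coverage is computed but plays no role in arbitration.  Multi-gene sides
are aggregated by the unweighted mean of their genes' coverages.

The significance filter is applied before the "no hit ⇒ removed" rule, so
a gene whose only hits are insignificant is treated as unsupported; this
keeps the many-type rule consistent with the pipeline-only rule.

### Fusion and fragmentation

Two systematic annotation errors leave recognizable homology footprints:

* **fragmentation** — one true locus split into several models.  Detected
  when ≥ 2 genes on one side have best hits to the *same* subject protein
  over mutually non-overlapping subject intervals, jointly ordered, with
  inter-fragment gaps ≤ `fragmentation_gap_max` (default 50 residues —
  roughly a missed internal exon's worth of protein).  The fragmented side
  loses.
* **fusion** — two true loci glued into one model.  Detected when one
  gene's merged query intervals to two distinct subjects are mostly
  disjoint: the query-length fraction covered by exactly one of the two
  subjects, `(|U1 ∪ U2| − |U1 ∩ U2|) / qlen`, is ≥
  `fusion_min_disjoint_fraction` (default 0.8).  The fused gene's side
  loses.

Events override the coverage comparison.  If both sides are flagged
(conflicting evidence) or the winning side retains no homology-supported
gene, arbitration falls back to coverage.  When every gene of a many-type
component lacks a hit the component contributes nothing to the merge; its
reference genes count as removed.

The merge is fully deterministic — components are processed in positional
order and no randomness is involved — and the report satisfies
`n_merged = n_ref_total − n_removed_ref + n_added_pipe` by construction,
which is asserted on every run.

## Expression post-processing

### TMM

Scale factors follow the trimmed mean of M-values scheme as implemented in
edgeR: the reference sample is the one whose 75th percentile of
library-size-scaled counts is closest to the mean such percentile; each
sample's factor is `2^f` with `f` the inverse-variance-weighted mean of
gene-wise log2 ratios after trimming the extreme 30% of M values
(`trim_m`) and 5% of A values (`trim_a`) on each tail (rank-based, average
ranks on ties); variances are delta-method binomial approximations;
factors are rescaled to geometric mean 1.  Genes with a zero count in
either column are excluded from the comparison (infinite M/A).  An
all-zero sample is an error.  The implementation agrees with edgeR's
`calcNormFactors(method="TMM")` to ~1e-16 on random matrices (one test
runs edgeR through Rscript as an independent cross-check) and with a
direct scalar transcription of the formula to 1e-9.

### FPKM

`fpkm[g,s] = counts[g,s] × 1e9 / (gene_length_bp[g] × total_counts[s])` —
plain library-size FPKM, no TMM adjustment, requiring positive gene
lengths.

### Replicate-Jaccard filter

Counts are put on a per-library-scaled TMM scale:
`counts / (library_size × factor) × mean(library_size)`, so a threshold
reads as a count in an average-sized library.  For each candidate
threshold `s` the matrix is binarized — a gene is *present* in a sample
when it is detected (nonzero) and its normalized value is ≥ `s` — and the
global Jaccard index is the unweighted mean over all within-condition
replicate pairs of |both present| / |either present| (a pair with no
present gene at all scores 0, with a warning).  `s*` is the smallest
threshold attaining the maximal global index; a gene is removed iff its
normalized value is < `s*` in **all** samples, so one confident
observation suffices to keep a gene.

The detection clause in the presence rule only matters at `s = 0`: a
threshold of zero cannot mark an unobserved gene as present, otherwise the
trivial "everything present" binarization would always win the argmax.
For every `s > 0` the rule is exactly "normalized value ≥ s".

The default grid is the 200 quantiles of the distinct normalized values
plus 0, giving a data-adaptive resolution without scanning every value on
large matrices.  Each condition needs ≥ 2 replicates.  The choice of the
smallest `s` on ties is the least destructive resolution.

## Synthetic fixtures

`fixtures` emulates the real inputs at desk scale with planted ground
truth.  Each overlap category is realized in its own genomic window
(20 kb stride, so no accidental cross-component overlaps), with homology
evidence constructed to force the intended decision: fragmentation plants
tile one subject protein with a 5-residue gap; fusion plants give the
fused model two subjects disjoint over 90% of its query; coverage plants
separate the sides by 0.4–0.5 in mean coverage.  In the fusion and
fragmentation plants the *losing* side carries the higher coverage, so the
tests confirm the event logic, not the coverage fallback.  Significant
hits use e-value 1e-30, insignificant ones 10.

Counts use the standard negative-binomial RNA-seq model, parameterized by
(mean, dispersion) with `r = 1/dispersion`, `p = r/(r+mean)`: signal genes
have per-gene means lognormally scattered around 200 (dispersion 0.1) and
are concordant across replicates; noise genes are present per sample with
probability 0.5 at mean 2, an uninformative on/off signal.  Defaults are 2
conditions × 3 replicates, 100 signal + 100 noise genes — the replicate
structure of a typical two-timepoint bulk RNA-seq design at a size where
the whole suite runs in seconds.

What the fixtures do **not** emulate: exon-level structural disagreement
(arbitration uses gene spans and protein hits only), realistic BLAST HSP
noise (chimeric or partial hits), between-replicate library-size extremes,
count correlation structure between genes, and genuinely ambiguous
components where homology evidence conflicts.  Passing tests therefore
demonstrate that the rules are implemented as specified and behave
correctly on unambiguous evidence; they do not measure accuracy on real,
messy annotations.

## Numerical and design notes

* All interval arithmetic is 1-based closed; interval-tree lookups convert
  to half-open internally.
* Duplicate `gene_id` across seqids is an error (identity is the merge
  key); duplicate within a seqid extends the gene's span.
* Component and gene iteration orders are fully specified (seqid, start,
  id), so outputs are byte-stable.
* `query_coverage` is capped at 1.0 to guard against over-counting from
  hit coordinates slightly exceeding the stated query length.
* The whole merge is deterministic; only fixture generation consumes a
  seed, and identical seeds give byte-identical files.

## Known limitations

* Arbitration ignores exon structure; a pipeline model with better exon
  evidence but equal span/coverage loses to the reference.
* The fusion detector compares subjects pairwise; a model fusing three or
  more loci is still flagged (by some pair) but the event lists only that
  pair's subjects.
* Mean query coverage as the multi-gene aggregate is one of several
  defensible choices (length-weighted mean and maximum being others); it
  is exposed in the report reasons so decisions are auditable.
* FPKM uses raw library sizes; TMM-adjusted FPKM is intentionally not
  conflated with it.
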