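# Methods

This note documents the model, the conventions and numerical choices behind
`pollenscreen`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Expressed-gene filtering and abundance bins

The expressed-gene (EG) threshold is `FPKM >= 1.0`, non-strict, and
configurable (`AbundanceScheme.eg_min`). One FPKM corresponds roughly to one
mRNA molecule per cell in bulk tissue, which is the conventional floor for
calling a gene expressed in FPKM atlases.

Abundance bins are half-open `[edge_i, edge_{i+1})` with the top bin closed
below (`[last_edge, inf)`), matching the ">= 400 FPKM" phrasing of the VHEG
class; every non-negative FPKM therefore maps to exactly one of
`{trace, LEG, MEG, HEG, VHEG}`. Two presets ship: edges `(1, 10, 40, 400)`
for pollen-scale atlases and `(1, 50, 200, 2000)` for higher-FPKM atlases —
different RNA-seq experiments put very different absolute FPKM mass on their
top genes, so the bin scale is a property of the dataset, not of the method.

The top-N concentration statistic divides the FPKM mass of the N most
abundant expressed genes by the **whole-transcriptome** mass of that tissue
(all genes, trace included), reading "percentage of the transcriptome"
literally; an EG-only denominator is a one-line change and deliberately not
the default. When a tissue has no transcript mass the percentage is reported
as missing, never as 0. If N exceeds the EG count, all expressed genes are
used.

## Inter-tissue correlation and redundancy pruning

Pearson correlation between tissue profiles is computed over genes on raw
FPKM by default (`transform="identity"`); `log2(x+1)` is offered because raw
FPKM correlation is dominated by a handful of very large genes. Zero-variance
profiles cannot be correlated: their rows and columns are reported as missing
(NaN) and the tissue is flagged, never silently set to r = 0.

Tissue panels in public atlases contain near-duplicates (successive
internodes, for example). Pruning is greedy in a caller-supplied priority
order: a tissue is dropped iff its correlation with an already-retained
tissue reaches the threshold. Greedy-by-priority is not optimal in the
set-cover sense, but it is deterministic and auditable, which matters more
for a screening pipeline whose tissue panel a human will review anyway.

## The specificity screen

The denominator of the specificity ratio is the arithmetic mean FPKM over
the other selected tissues (the quantity the screen's scatter plots put on
their x-axis). The stricter reading — at least `fold` above *every* other
tissue — is available as `denominator="max"`. All threshold comparisons are
non-strict ("at least").

Degenerate denominators are resolved explicitly: denominator 0 with a
positive target FPKM gives ratio +inf and (if the expression gate passes) a
specific call, because no detectable expression elsewhere is the strongest
specificity evidence an atlas can offer; 0/0 is an undefined ratio, reported
as missing and never specific. A pseudocount `eps` added to the denominator
is available to soften the infinite-ratio rule. Records are emitted for
every gene, including never-expressed ones, so the output table is a full
audit trail.

With zero pseudocount the specific calls are invariant to a global rescaling
of the matrix and to the order of the non-target tissues; raising any of
`fold`, `min_expr`, `abundant_min` can only shrink the corresponding set.
These invariants are asserted over randomized atlases in the test suite.

The screen is a deterministic threshold rule, exactly as practised for this
kind of atlas mining — no variance model, no p-values, no multiple-testing
correction. Abundant calls (`target FPKM >= 400` or `2000`, by dataset
scale) are independent of specific calls, and the two-dataset intersection
(the "shared-specific" or MAPS-style set) is plain set intersection.

## Promoters

A promoter is the `length` bases (default 2000) immediately upstream of the
**translation start codon**, not the transcription start site: 5' UTR
annotation is unreliable in exactly the genomes this screen targets, whereas
the ATG of an annotated CDS is well-defined. The representative transcript
of a gene is the mRNA with the longest summed CDS; ties break to the
lexicographically smallest transcript id. The translation start is the
minimum CDS coordinate on the + strand and the maximum on the − strand.

Coordinates follow GFF3 (1-based, fully closed) throughout, including the
provenance intervals written next to every extracted sequence. A + strand
gene with translation start `s` yields `contig[max(1, s-length) .. s-1]`
verbatim; a − strand gene yields the reverse complement of
`contig[s+1 .. min(L, s+length)]`. Promoters cut short by a contig edge are
kept and flagged `truncated` (enrichment uses actual lengths); a start codon
at the very edge yields an empty promoter with a warning rather than an
error, so per-gene extraction failures are visible and counts fall where
they may. N bases are preserved and never match any motif.

## Motif scanning and the enrichment index

Motif patterns allow single bases and bracketed classes (`[TA]`, also
spelled `[T/A]`); a pattern with `m` concrete words of length `k` has
degeneracy `m` = product of class sizes. Scanning is forward-strand only —
a motif and its reverse complement are separate registry entries (the
registry lists both AGAAA and its reverse complement TTTCT), which keeps
double-strand bookkeeping out of the scanner. Overlapping occurrences all
count; this matches the sliding-window null expectation most closely and is
the simpler contract. A non-overlapping (left-to-right) mode exists behind a
flag.

The expected count in `L` bp of uniform random DNA is taken as
`L * m / 4^k` — one expected hit of a fully specified k-mer per `4^k` bp.
The exact sliding-window expectation is `(L - k + 1) * m / 4^k`; the
difference is an edge-effect bias of factor `(L-k+1)/L` (~0.998 for k = 5,
L = 2000), documented here, tested by Monte Carlo calibration, and available
as `mode="windows"`. "Enriched" is strictly index > 1.

The shipped registry carries 10 pollen-specific elements (AGAAA, TCCACCA,
TGTGGTT, [TA]AAAG, AAATGA, TTTCT, TGTGA, AGGTCA, GAAACG, GAATAT), three
JA-responsive elements (GCCGCC, CGTCA, TGACG) and one ABA-responsive element
(CCACC), each with its literature source string. Position-weight-matrix
scanning and database-backed CRE classification (PlantCARE-style) are out of
scope; users can extend the registry TSV with any exact/class pattern.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their spec, seed included; no global
random state is touched.

**Atlases** (`simulate_atlas`). Background genes draw a shared log-normal
base level (`exp(N(log 60, 1.0))` FPKM for the pollen-scale preset) jittered
per tissue by a bounded factor in `[1/2, 2]`, which caps every background
gene's true target-vs-mean ratio at 4 — safely below any screening fold.
Planted specific genes draw a log-normal target FPKM (median 200,
floor 4) and have every other tissue forced below `target / planted_fold`
(default fold 1000), so their true ratio clears the planted fold by
construction. 70% of background genes are forced below 1 FPKM in the target
tissue only, reproducing mature pollen's reduced transcriptome diversity
(~30% of genes expressed). The target tissue's top-300 mass share is then
solved to `concentration` (default 0.755, the observed pollen value) by
whole-row rescaling, which preserves every true ratio exactly; the solve
iterates the analytic one-step factor because scaling the top set down can
swap boundary genes. The planted floor of 4 FPKM gives the rescaling
headroom so planted genes never drop through the 1-FPKM expression gate.

Because the ratio denominator contains every other tissue, a gene cannot be
100-fold specific to two tissues of the *same* panel; genuinely shared
pollen/anther-specific genes only exist across two separately profiled
datasets (the real anther atlas contains no pollen sample). The paired
generator (`simulate_paired_atlases`) therefore plants the overlap across
two atlases sharing a gene universe: 150 pollen-specific, 120
anther-specific, 80 shared by default. The anther-scale preset uses 14
tissues, higher FPKM levels, a 2000-FPKM abundance line, a 25% trace
fraction and a 0.40 top-300 concentration — anther transcriptomes look like
ordinary tissues, unlike pollen.

What the atlas generator does **not** emulate: read-level sampling noise,
FPKM estimation error, correlated co-expression modules, batch structure
between datasets, or genes whose specificity is borderline (background
ratios are bounded at 4, planted ratios at >= 1000). Passing the
planted-recovery tests therefore shows the screen's logic is exact under
separable conditions; it says nothing about threshold sensitivity on real
borderline genes, which is why the fold threshold remains a user-visible
parameter.

**Promoters** (`simulate_promoters`). Uniform (configurable) background
sequence with a fixed number of non-overlapping motif insertions per
promoter, each insertion drawing one concrete word of the motif. Truth
counts are recomputed *after* insertion by an independent position-by-
position brute-force scanner, so chance background hits are part of the
truth — the generator is an end-to-end oracle for the production scanner,
not a bookkeeping of insertions.

**Genome + annotation** (`simulate_genome_annotation`). Genes laid out on a
single contig on both strands, with an ATG written at every translation
start, a second shorter isoform on some genes (exercising the longest-CDS
rule), a spliced two-segment CDS on others, and the first gene placed close
enough to the contig start to force promoter truncation. Truth promoters
are recorded at generation time through an independent slicing path
(Biopython reverse complement), and extraction must reproduce them byte for
byte.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
these sizes: paired atlases of 2000 genes x 12/14 tissues; 618 promoters of
2 kb for enrichment demonstrations; 2000 uniform 2-kb sequences for null
calibration; exhaustive scanner/oracle equivalence over all ACGT sequences
of length <= 10 against all 84 fully specified motifs of k <= 3 (117 million
pairs, batched), plus 10,000 randomized degenerate-motif pairs; 100
randomized atlases for the structural invariants. Floating-point reports
round to 6 significant digits; machine-readable TSVs keep full `repr`
precision, which round-trips exactly.

## Known limitations

- FPKM is taken as given; no normalisation across datasets, no
  between-sample scaling, no id mapping between gene-model versions.
- The screen has no uncertainty quantification by design; bootstrap or
  variance-aware extensions would need replicate-level data the published
  atlas exports do not carry.
- The enrichment null assumes uniform base composition; promoters are
  AT-rich in many plants, so absolute indices on real promoters should be
  compared between motifs rather than read as calibrated significance.
- Promoter extraction does not handle trans-spliced or fragmented gene
  models and makes no attempt at repeat masking.
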