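# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the design choices made where the procedure was
genuinely open, and what the synthetic benchmarks do and do not show.

## Barcode scheme and demultiplexing

A tagmentation plate carries an 8×12 grid of s5 adapter barcodes 1–8
(rows A–H) and s7 barcodes 1–12 (columns) for the first transposase, and
s5 9–16 / s7 13–24 for the second transposase over the same physical
wells. A read's s5/s7 combination therefore encodes both its well and its
stream: same-set pairs are mono-occupancy (`target1`, `target2`), mixed
pairs are co-occupancy (`co1` = s5 set A with s7 set B, `co2` = the
reverse). Keeping `co1`/`co2` separate preserves which mate of a
co-occupancy fragment belongs to which target; downstream they are usually
concatenated. The rewritten cell barcode is `WELL+p5+p7` (well ID plus the
two nanowell PCR indices), identical across all four streams of a cell.

Barcode matching accepts the unique whitelist member within Hamming
distance ≤ `max_mismatch` (default 1; ties → unassigned). Whitelists are
validated at load: pairwise Hamming distance must exceed 2·`max_mismatch`
so the match is unambiguous by construction. Barcode positions within the
two index reads are configuration, not inference: instruments differ in
where the adapter and nanowell barcodes sit, so the scheme JSON carries
offsets and lengths.

**Substitution-noise model.** `barcode_error_rate` is the *expected number
of substitutions per barcode*: each base is substituted independently with
probability rate/length. This makes the corrupted-barcode fraction ≈ the
configured rate while still producing the occasional multi-error barcode,
so the assignment rate under noise has a closed analytic form — the
product over the four barcodes of P(≤ 1 substitution) — which the
validation suite checks against a binomial 99% interval. Indels are not
modeled (the matcher is a fixed-offset Hamming matcher).

## Fragments and coverage normalization

Fragments are BED 0-based half-open intervals spanning both mates of a
pair; cross-chromosome pairs are skipped and counted, and fragments longer
than the paired-end insert cap (default 1000 bp) are dropped. Single-cell
data is deduplicated on (chrom, start, end, cell) — within one cell an
exact coordinate duplicate is almost surely a PCR duplicate — while bulk
data retains duplicates.

Coverage tracks multiply per-base fragment pileup by a scale factor:

- per-sample: 1e10 / Σ fragment lengths;
- anchor-normalized: the same factor computed once on an anchor mark
  (H3K27ac in the assay's paired designs) and applied to all tracks of the
  sample, so mono- and co-occupancy tracks stay on one scale;
- pseudobulk: 1e4 / cells-per-cluster.

BedGraph emission uses an event sweep (+1/−1 at fragment bounds), merges
equal-valued adjacent intervals, clips to chromosome sizes, and rounds to
a fixed number of decimals (default 5) for byte-stable output. Mass
conservation (Σ value·length = factor · Σ fragment lengths) is asserted in
tests. Pileup counts fragments, not read ends. BigWig conversion is left
to `bedGraphToBigWig`; the BedGraph is the canonical artifact.

## Chromatin-state model

Pseudobulk gene scores are transformed to log10(score + 0.1) and fitted
per mark with a two-component Gaussian mixture. The fit is deterministic:
initialization splits the data at the median (the two halves provide
starting means and variances, weights start at ½), EM runs to a
log-likelihood tolerance of 1e-8 with at most 500 iterations, and
components are canonically reordered so μ₁ < μ₂. The threshold is the
density intersection — the root of w₁φ₁(x) = w₂φ₂(x) between the means,
which is a quadratic in x (closed form (μ₁+μ₂)/2 + σ²ln(w₁/w₂)/(μ₂−μ₁)
when σ₁ = σ₂). If no root lies between the means (extreme weight/variance
combinations) the threshold falls back to the midpoint of the means and
the fit is flagged; the pipeline never aborts per mark.

One mixture is fitted per mark on values pooled across clusters;
per-cluster fitting is available by applying `fit_mixture` to single
columns. "Above threshold" is strict (>): a score exactly at the threshold
counts as below, matching the verbs used throughout (exceed, above).

State rule per (H3K4 mark, H3K27me3) pair: bivalent requires H3K4,
H3K27me3 *and* co-occupancy above threshold; active = H3K4 above and
H3K27me3 below; repressed = the reverse; unmarked = both below; other =
both above without co-occupancy support. The consensus over the three
H3K4me1/2/3 pairs requires agreement of at least two; "other" votes like
any label (the alternative — excluding "other" votes — is not
implemented because it would make the 2-of-3 rule asymmetric across
labels). Fate maps count root-state → downstream-state transitions per
lineage, the per-root-state fraction of genes active in ≥ 1 lineage, and
lineage-specificity (active in exactly k lineages).

## QC and embedding fidelity

Retention requires **more than** 250 fragments in at least one of the
three modalities (strict boundary, configurable). Cluster-level doublet
filtering removes clusters whose fraction of cells above a doublet-score
threshold exceeds a fraction threshold (both strict). Genotype-doublet
neighborhoods are found by seeded k-means (default 100 groups, 10
restarts) on the reduced embedding; groups with strictly more than 15%
genotype-labeled doublets are removed wholesale, and the resulting keep
mask applies to every modality, so the removed cell set is identical
across modalities by construction.

S_pair: for each member c of a matched pair (c, p), sample up to 5,000
other cells without replacement (excluding c and p; all cells when fewer
are available) and compute the fraction closer to c than p is, using
Euclidean distance over the first 15 embedding dimensions (configurable).
S_pair averages the two members' fractions — averaging over members rather
than over resamples, a documented choice where either reading is
defensible. Under random pairing the expected value is 0.5; coincident
partners give exactly 0.

Annotation scores z-scale each reference-expression gene across cell
types (zero-variance genes → 0 rather than NaN) and average the scaled
values over a cluster's marker genes; markers missing from the reference
are dropped and counted.

## Pseudotime and activation timing

Pseudotime is the average rank of each cell along a precomputed
trajectory scaled to [0, 100] (τ = 100(rank−1)/(n−1); a single cell gets
0). Gene-module scores are the per-cell median of per-gene z-scores.

Activation timing smooths each gene's profile with loess — tricube
weights over the ⌊span·n⌋ nearest points, locally quadratic, evaluated
directly at the observed pseudotimes (the implementation reproduces R's
`loess(..., degree = 2, surface = "direct")` to ~1e-10 on test fixtures)
— then clamps non-positive predictions to 0, min-max rescales to [0, 1],
and reports the first observed pseudotime whose scaled value strictly
exceeds 0.5. Flat profiles have no defined activation time. The span
default is 0.75, the smoother's conventional default; plotting-oriented
spans (0.3/0.15/0.7 in various figures) do not affect timing. Min-max
rescaling makes the statistic invariant to positive affine transforms of
the raw scores, which the property tests assert. Note the rescaling is
min-max, not a z-score: subtracting the minimum and dividing by the range
is the operation that makes "exceeds 0.5" a half-max criterion.

## Cis-regulatory element pipeline

*Gene domains.* Transcript records are collapsed per gene to the union
span; each gene's domain runs from the end of the nearest upstream
non-overlapping gene (the largest end ≤ the gene's start — not
necessarily the adjacent record when neighbors overlap each other) to the
start of the nearest downstream non-overlapping gene, with chromosome-edge
genes bounded by the min/max annotated coordinate. Invalid domains are
dropped and counted.

*Summits → windows.* Summits within 100 bp of the currently retained
summit are collapsed by a single greedy sweep that keeps the
higher-scoring summit's position and score; distances are measured from
the retained (possibly updated) summit, the simplest reading of a greedy
sweep, and the implementation is property-tested against an independent
restatement on random small instances. Retained summits become 200-bp
centered windows clipped to chromosome bounds. Cross-lineage merging
unions the per-lineage windows; merged intervals wider than 200 bp are
re-centered on the highest-scoring original summit they contain.

*Quantification.* Window counts use ≥ 1 bp half-open overlap (an abutting
fragment does not count), scaled to CPM by the total fragment count of
each (cluster, mark) file. Rows in the lowest or highest 5% of cumulative
signal (row sums; linear-interpolation percentiles, strict inequalities so
a fully tied matrix survives) are removed.

*Clustering.* Columns are standardized (zero-variance → 0); columns are
then grouped by histone mark and each mark block is rescaled to the median
block Frobenius norm so no mark dominates. PCA (default 16 components,
lowered with a warning when the matrix is smaller), kNN graph (30
neighbors, edge weight 1/d with d floored at 1e-12), Leiden partition
(RB-configuration objective, seeded), labels canonicalized by descending
class size. Resolution defaults to 4, appropriate for genome-scale
element sets (tens of thousands of windows); the synthetic end-to-end
benchmark (~300 windows, 3 planted classes) uses 0.25, scaled down roughly
in proportion to the element count — at high resolution the RB objective
deliberately over-partitions near-clique components. Re-clustering runs
the same machinery on a selected label subset at resolution 0.5 and
overwrites only the selected rows with namespaced sublabels. UMAP (40
neighbors, min-dist 0.25) is computed only on request, for reporting.

*Statistics.* Promoter fraction is the share of a class's windows
overlapping TSS ± 2 kb. Domain enrichment compares observed class ×
domain-group overlap counts with expected N_class · f_group (f_group =
genome-wide fraction of windows overlapping the group), reported as
log2((O + 0.5)/(E + 0.5)) — the 0.5 pseudocount is added to both observed
and expected — and converted to row-softmax weights; gene membership
across domain groups is verified disjoint first. Co-occurrence tests each
class pair's presence/absence across gene domains with a two-sided Fisher
exact test (p = sum of hypergeometric probabilities ≤ the observed
table's) and a Haldane-corrected log2 odds ratio (+0.5 in all four
cells), BH-adjusted with significance at FDR < 0.05; the network view
keeps significant positive edges, trims to the 50 strongest by |log2 OR|
and drops nodes below degree 1 (both exposed as flags — the backbone
parameters are presentation choices). Per-gene element counts and
per-window maximum signal (H3K4me1 for enhancer analyses, H3K4me3 for
promoter analyses) are compared between gene groups with two-sided
Mann-Whitney U (exact for small untied samples, tie-corrected normal
approximation otherwise), BH-adjusted.

Interval arithmetic throughout uses sorted-array counting on half-open
coordinates rather than an external interval engine; every interval
operation is tested against an O(n·m) brute-force oracle.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed) and come with ground
truth.

- **Reads**: genomic sequence is uniform random A/C/G/T — everything
  downstream of demultiplexing works from barcodes, so no genome is
  simulated, and alignment is out of scope. Stream proportions default to
  40/40/10/10% (mono/mono/co/co). Substitution noise as described above.
- **Gene scores**: each (gene, cluster) draws a planted state
  (active 0.30 / repressed 0.25 / bivalent 0.15 / unmarked 0.25 / other
  0.05) and each mark draws from the high or low component of its
  log-scale mixture according to the state rule; defaults μ_low = 0,
  μ_high = 2, σ = 0.5 put the components 4σ apart, at which separation
  the expected consensus recovery is ~97% (per-mark tail error Φ(−2) ≈
  2.3%, shared across the three pairs through the common H3K27me3 and
  co-occupancy draws). Scores are emitted as max(10^x − 0.1, 0) so the
  modeling transform recovers the mixture; the clamp affects only the
  extreme low tail.
- **Embeddings**: Gaussian cluster blobs (default 4, spread 20, sd 1) in
  15 dimensions; each cell has a matched partner displaced by 0.5× the
  within-blob sd; a compact doublet neighborhood is planted at the
  midpoint of two blob centroids (how synthetic doublets project) with
  30% genotype-doublet labels against a 2% background rate. The
  benchmark uses 2,000 cells so the 100 k-means groups hold ~40 cells
  each; with 20-cell groups the 2% background generates occasional
  false-positive groups by small-sample noise, which is a property of
  group size, not of the filter.
- **Summits/elements**: ~300 elements on one 10-Mb chromosome, one third
  planted promoters (H3K4me3-high in every cluster) and the rest split
  into two lineage-specific enhancer classes (H3K4me1-high only in their
  lineage); every element is called in every lineage with ±20 bp summit
  jitter so cross-lineage merging is exercised; fragment counts are
  Poisson (mean 200 high / 5 low) with ±300 bp positional jitter.

The generators reproduce the *statistical structure the estimators
assume* — mixture-separated scores, well-separated blobs, block-structured
signal. Passing benchmarks therefore demonstrates correctness of the
implementations and their numerical behavior, not robustness to the
failure modes of real chromatin data (overlapping states, continuous
lineage gradients, batch effects, fragment-count confounds), which the
synthetic distributions deliberately do not contain.

## Problem sizes of the validation script

`scripts/acceptance.py` uses ~50,000 reads (1,250 cells × ~40 reads) for
the demultiplexing checks, 5,000 draws for mixture recovery, 2,000 genes ×
6 clusters for state recovery, 1,000 cells / 500 random pairs for S_pair,
2,000 cells for doublet neighborhoods, 1,000 random instances of ≤ 6
summits for the merge oracle, and ~300 planted elements for the
element-class benchmark — sizes at which every stochastic quantity is
stable to well within the margins asserted, while the whole script runs
in well under a minute of CPU.
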