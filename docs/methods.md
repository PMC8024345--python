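# Methods

This note documents the models, rules and numerical choices behind
`crossatlas`, in the order data flows through the pipeline.

## Inputs and conventions

Count matrices are 10x-style sparse triplets (MatrixMarket features ×
barcodes plus `barcodes.tsv` / `features.tsv`, optionally gzipped); the
features file may have one to three columns and only the first is used as
the gene id.  All other inputs are headered TSVs validated against explicit
schemas.  Genomic coordinates are 0-based half-open (BED convention)
everywhere internally; 1-based inputs must be converted at the boundary.
Every pipeline stage emits one structured log line with input shapes, filter
counts and the seed in use.

## QC, normalization, pseudobulk

Cells are kept when (inclusive bounds throughout): detected genes in
[500, 6000], total UMIs in [500, 40,000], and mitochondrial UMI fraction
≤ 10% (vacuous when no mitochondrial gene set is given).  "Between",
"above/below" and "no more than" are read inclusively/strictly exactly as
stated by those bounds; all six thresholds are configuration.  Cell filters
run first; genes detected in fewer than three *surviving* cells are then
removed.  This single pass is not a fixpoint iteration: removing genes can
in principle push a borderline cell below the detected-gene bound, so exact
idempotence is guaranteed only when, as in realistic data, the removed genes
are not load-bearing for any retained cell; the property test checks it on
the synthetic atlas.

Normalization is LogNormalize, `ln(1 + count / cell_total * scale)` with
scale 10,000; zero counts stay exactly zero and the sparsity pattern is
preserved.  Pseudobulk profiles are per-cluster arithmetic means with
clusters ordered lexicographically.  By default the log values are averaged
directly; averaging de-logged values (`expm1` then mean, the convention of
some toolkits' "average expression") is selectable via `space="delog"`.  The
choice is recorded in the profile's provenance and is immaterial to the
correspondence stage, which is rank-based per cell type: both variants are
monotone transformations of the same per-gene ordering.

## Orthology

OrthoMCL-style group lines are parsed with species assignment by id prefix
(an explicit mapping dialect can be emulated by prefixing upstream).  A gene
appearing in more than one group is excluded from all of them — conservative
and deterministic — and genes matching neither prefix are counted and
ignored.  Only groups with exactly one gene per species become ortholog
pairs; one-to-many and many-to-many groups are dropped because duplicated
genes commonly neofunctionalize and cannot be assumed functionally
equivalent.  The extracted map is checked to be a bijection on every run.
Counts are reported both before and after intersecting with the expressed
genes of each profile, so the effect of expression filtering on the usable
ortholog set is always visible in the alignment report.

## Marker detection

The one-vs-rest enrichment test is the two-sided Wilcoxon rank-sum on
log-normalized values.  A gene enters the test when detected in ≥ 10% of
cells in either group (the usual `min.pct` semantics) and
|log2FC| > 0.58 (≈ 1.5-fold).  log2FC is computed on de-logged group means
with a pseudocount of 1 — the era convention of the tools this mirrors — and
is configurable.  P-values: for groups of at most 8 cells each, the exact
tie-aware enumeration over all C(n1+n2, n1) assignments of the mid-rank
rank-sum statistic (two-sided tail measured as deviation from its mean);
otherwise the normal approximation with tie correction and a 0.5 continuity
correction.  Adjustment is Bonferroni over the genes tested within the
cluster comparison (Benjamini–Hochberg selectable).

Cluster-specific markers additionally require log2FC > 0.25 and PCT2 < 10%
(both strict), i.e. detection in under 10% of all cells outside the cluster.
Conserved markers are the intersection rule: an ortholog pair is conserved
for a paired cluster when both genes pass the enrichment criteria in their
respective clusters; the combined p-value is the maximum of the two species'
p-values.

Gene modules: conserved-gene profiles from the two species are concatenated
column-wise (species-A clusters then species-B clusters) — a single joint
clustering rather than two per-species ones, so a module can be read
directly as a cross-species expression program.  Rows are z-scored, then
k-means (default k = 4) with seeded initialization and a fixed restart count
(`n_init = 10`).  Rows are fitted in canonical sorted order and modules
renumbered by first appearance, making the partition deterministic under the
seed and invariant to input gene ordering.

## Cell-type correspondence

The specificity index of gene g in cluster c is its pseudobulk expression
divided by the gene's mean across clusters, so every expressed gene has mean
SI exactly 1 and an exclusive gene scores C in its only cluster.  The
normalizer (per-gene mean vs per-gene sum) is configurable; the two differ
by a per-gene constant and give identical rank correlations.  The upstream
source of this transform is cited to a paper we could not consult for the
printed equation, so the mean-normalized ratio — the canonical reading of a
"specificity index" — is a documented package choice.  All-zero genes get a
zero row and a flag, and are excluded from correlations when flagged in
either species.

Spearman rho uses mid-ranks for ties and is computed as the product-moment
correlation of row-ranked matrices (one matmul per replicate); constant
cluster vectors give an undefined (NaN) rho that is never significant.  The
permutation null shuffles each gene's values independently across the
cell-type axis — a fresh permutation per gene per replicate, applied to both
species' matrices by default (`shuffle_both=False` shuffles species A only).
Shuffling per gene preserves each gene's value set while destroying its
association with cell types, which is exactly the exchangeability the test
needs.  The p-value is the plain fraction of replicates with
|rho_shuffled| ≥ |rho_observed| over `n_perm` (default 1000) replicates, so
p = 0 is attainable; the (count+1)/(n_perm+1) correction is available but
off by default to keep the quoted estimator.  Calls use strict p < alpha
(default 0.05), and mutual best matches are annotated on the rho matrix.

RNG: each replicate draws from its own `numpy` SeedSequence stream keyed by
(seed, stream-tag, replicate), so results are independent of any parallel
execution layout and adding replicates never perturbs earlier ones.  Cluster
rows are sorted lexicographically before analysis, keying the RNG pairing to
canonical order: shuffling input row order cannot change the result
(renaming clusters re-keys the stream, changing p-values only within
Monte-Carlo noise).

## ATAC/scRNA concordance

Differential peaks are kept when |log2FC| ≥ 0.58 and FDR < 0.05.  The
fold-change comparator is `>=` by default with `>` selectable, because the
two conventions circulate for the same threshold; FDR is always strict.
Kept peaks are labelled MZ_open (log2FC > 0, fold changes oriented MZ vs EZ)
or EZ_open.

Peak-to-gene assignment is a deliberate re-implementation of
annotation-package behaviour as a fully specified rule: each peak, summarized
by its midpoint (summit coordinates are not in the consumed table), goes to
the gene with the nearest TSS, preferring genes within ± 3 kb (mirroring the
± 3 kb windows used for accessibility pileups).  Equidistant TSSs break to
the lexicographically smaller gene id.  Strand affects only which end of a
gene is its TSS and the consumed annotation carries the TSS explicitly;
distances are unsigned.  When several significant peaks land on one gene,
the smallest-FDR peak is retained (ties: largest |log2FC|, then
lexicographic peak id) — a documented choice, since how multi-peak genes
were summarized upstream is not specified, and the chosen peak id is kept in
the output for audit.

Correlation sign per marker gene: positive when accessibility log2FC
(MZ-positive) and the marker's expression log2FC are both positive or both
negative, negative for opposite signs, undetermined when the gene lacks a
significant peak or either value is zero.  An optional cluster→zone map
negates accessibility for EZ-identity clusters first, so signs read relative
to the cluster's own zone; the default is the raw MZ-positive orientation.
The per-cluster summary counts marker genes by direction and reports
`ratio = n_direction / n_markers_total` with the full marker list as
denominator; clusters with no markers, or none with any accessibility
record, are flagged.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, not any real
species' expression distributions (no batch effects, doublets, or realistic
mean-variance relationships beyond the negative binomial).  Counts are
negative binomial parameterized by mean μ and dispersion φ (variance
μ + φμ²), the simplest overdispersed model for UMI data.  Default study
conditions: 8 fully paired clusters per species, 100 cells per cluster,
2000 one-to-one orthologs plus 200 private genes per species, 50 markers per
cluster boosted 2² = 4-fold in their cluster, baseline mean 0.5, φ = 0.5,
10% dropout (independent zero-masking after sampling), and lognormal(0, 0.3)
per-cell library-size multipliers — values chosen once as representative of
a well-powered droplet experiment at desk scale.  Marker blocks are disjoint
within a species; a homologous cluster pair boosts the same ortholog block
in both species, and unpaired clusters take blocks no other cluster uses, so
planted correspondence is exactly the pair list.  Ortholog-group lines
contain every one-to-one pair plus injected one-to-many, many-to-many and
single-species groups built from private genes, making the planted
one-to-one set the provable extraction target.

The peak simulator places one peak within ± 1 kb of each species-A marker
TSS.  Per cluster, exactly `floor(frac_concordant × n_markers)` markers —
a seeded sample — get a significant peak whose sign matches the cluster's
planted zone (clusters alternate MZ/EZ identity by index); the rest
alternate between significant-but-opposite-sign and right-sign-but-non-
significant peaks, so the planted-direction ratio downstream is exactly the
floor expression.  Every output object draws from its own stream derived
from the master seed (library sizes, counts and dropout separately per
species), making outputs byte-reproducible and mutually independent.

What passing tests on this generator shows: the pipeline's bookkeeping,
statistics and thresholds behave exactly as specified under a known model.
What it does not show: robustness to batch structure, ambient RNA, doublets,
annotation errors, or distributional features of real rice/Arabidopsis data.

## Problem sizes and tolerances

The test suite and the acceptance script run the null-calibration analysis
at 10×10 clusters × 2000 orthologs × 500 permutations (the type-I fraction
is pooled over three independent simulations to stabilize the estimate) and
the homology-recovery analysis over 20 seeded replicates at the default
conditions with 300 permutations — sizes chosen so the full suite completes
in minutes on one CPU while keeping the Monte-Carlo error of each estimate
well inside the bands being checked.  Oracle agreement for Spearman and for
the exact rank-sum is asserted to 1e-12; the specificity mean-1 invariant to
1e-12; exactness checks (QC, one-to-one extraction, concordance ratios) to
equality.

## Known limitations

* The permutation test shares its replicate set across all cluster pairs of
  one analysis; p-values are therefore positively dependent across pairs
  (each pair's marginal calibration is unaffected).
* Exact rank-sum enumeration is O(C(n1+n2, n1)) and is capped at groups of
  8; beyond that the tie-corrected normal approximation is used.
* The nearest-TSS rule considers TSS distance only — no gene-body overlap,
  no multi-gene ambiguity reporting beyond the deterministic tie-break.
* `qc_filter` is a single pass, not a fixpoint (see above).
* One-to-one orthology treats the group file as ground truth; no sequence
  evidence is re-examined.
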