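# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## UMI quantification and collision correction

Left reads are parsed positionally: bases 1–6 are the unique molecular
identifier, bases 7–12 the cell barcode, and the remainder must begin with a
polyT stretch (≥ 4 T by default; the toy generator emits a fixed 12 nt tail).
Reads with N in the UMI or barcode, without the polyT anchor, or with a
barcode absent from the plate whitelist are excluded and tallied in the QC
report. The right mate is assigned to gene loci in sense orientation only;
reads matching more than one locus are discarded as MULTI. In place of a
genomic aligner the package ships an exact-substring assigner with the same
output contract (a read maps to every locus whose sense sequence contains
it), and accepts precomputed read → locus tables for real data.

Gene loci are merged transitively (union–find) when their overlap strictly
exceeds a configurable fraction of the **shorter** locus (default 0.75); the
denominator convention is configurable because "overlap by more than 75%"
does not by itself fix one. Merging is restricted to the same chromosome and
strand, and the merged interval is the union.

Distinct UMIs k per (gene, cell) are converted to transcript counts by the
binomial collision correction for a K-state UMI space,

    t(k) = ln(1 − k′/K) / ln(1 − 1/K),  k′ = min(k, K − 1),  K = 4⁶ = 4096,

the expected number of molecules that would leave k distinct UMIs when each
molecule draws a tag uniformly. t(0) = 0 and t(1) = 1 exactly; k is clamped
to K − 1 to avoid the logarithmic singularity at full saturation; t → k as
K → ∞.

## QC cascade and normalization

Cell filters operate on corrected, pre-normalization counts with strict
inequalities: a cell is removed iff its total is **below** `mintotal` or its
*Kcnq1ot1* fraction **exceeds** `kcnq_fraction` (default 0.02). *Kcnq1ot1*
marks low-quality cells; the fraction is computed on corrected transcript
counts (configurable). A cell failing both filters is reported once, under
the total filter, so report counts partition the input. Named profiles carry
the dataset-specific thresholds used in the study design (thymus 2,500,
frozen-material variants 1,500/1,000, blood 800, stimulated and combined
blood/lymph-node sets 500).

Downscaling multiplies each retained cell by `reference_total / cell_total`.
The reference is the minimum retained total by default (a common floor;
median available), which preserves within-cell gene proportions exactly and
is idempotent.

The downstream feature set removes: ribosomal subunit genes (`Rps*/Rpl*`),
predicted `Gm`-identifier genes, ERCC spike-ins, an explicit exclusion list
(`fgenes`, default Malat1 and Xist), and — the `cgenes` mechanism — every
gene whose Pearson correlation with any anchor gene (cell-cycle and batch
markers plus *Kcnq1ot1*) strictly exceeds 0.65, along with the anchors
themselves. Excluded genes stay in the matrix for reporting and differential
testing; only the feature set used for distances and the QP mapping shrinks.
Zero-variance genes get correlation 0. A pseudocount of 0.1 is added before
any log transform downstream (configurable).

## Background noise model

Across genes, log2 variance is regressed on log2 mean with a second-order
polynomial (genes with zero mean or variance excluded; at least three
distinct means required). Predicted variance is clamped below at the mean —
a Poisson floor — so the implied NB size r = m²/(v − m) is always positive.
On simulated Poisson data the fit recovers slope ≈ 1 and curvature ≈ 0; on
NB data with size 2 the predicted variance tracks m + m²/2 within 20% over
the fit domain (both are test assertions).

## Medoid clustering and outliers

Cell–cell dissimilarity is 1 − Pearson correlation of log2(x + 0.1) feature
profiles (Spearman available). Partitioning uses PAM with a deterministic
BUILD initialization and alternating medoid refinement; ties in medoid
choice and assignment break toward the lowest cell index, the objective is
non-increasing, and the whole fit is deterministic — the `random_state`
parameter exists only for API compatibility.

**Cluster-number selection.** Within-cluster dispersion saturation at a 1%
relative-improvement tolerance systematically over-splits NB data: on
synthetic three-cluster data, splitting pure noise keeps removing 1.3–1.7%
of the total dispersion well past the planted k. The default selector is
therefore the mean-silhouette maximum over k = 2..k_max on the precomputed
dissimilarity (deterministic, and sharply peaked at the planted k on two-
and three-cluster synthetic data), preceded by a saturation test for the
k = 1 decision; the pure saturation rule remains available via
`k_select="saturation"`. For trajectory analyses whose cluster chains are
specified by the user, a fixed `n_clusters` can be passed instead.

**Outliers.** For each cell, each gene's count is scored by a two-sided NB
tail probability under the cluster mean and the background-model variance;
a cell with at least `min_outlier_genes` (default 2) genes below `probthr`
(default 10⁻⁴) is flagged. Flagged cells are excluded from the final medoid
computation but are not re-clustered — full outlier re-seeding is out of
scope. `probthr = 0` flags nothing, since tail probabilities are strictly
positive. The tail probability is unimodal around the cluster mean rather
than strictly monotone in |count − mean| (a discreteness effect of min(lower
tail, upper tail)).

Clusters smaller than `cthr` (default 15) remain in the partition but are
excluded from lineage analysis.

## NB exact test for differential expression

Normalized counts are summed per group and rounded (the conditional argument
requires integers; non-integer sums trigger a single warning). Under the
null both group sums are NB with the pooled per-cell mean m: an n-cell sum
is approximated by NB with matched moments, mean n·m and variance n·v(m)
from the background model. With P_A, P_B the two mass functions and
T = kA + kB,

    p = Σ {P_A(a)·P_B(b) : a+b = T, P_A(a)P_B(b) ≤ P_A(kA)P_B(kB)} /
        Σ {P_A(a)·P_B(b) : a+b = T},

computed in log space with logsumexp. The test is symmetric under group
swap, returns 1 for a zero total, and equals brute-force enumeration to
10⁻¹⁰ relative for all totals ≤ 50 (asserted). For totals above 5,000 the
conditional distribution is replaced by a normal approximation with a 0.5
continuity correction (conditional mean mA + (T − mA − mB)·vA/(vA+vB),
variance vA·vB/(vA+vB)); continuity at the crossover is tested. Empirical
type-I error at α = 0.05 on 500 null NB genes lands near nominal (0.04–0.06
across seeds). Benjamini–Hochberg correction is applied across genes
(statsmodels step-up); genes are shortlisted at adjusted p < 0.05.

## Simplex-constrained QP projection

Each query cell x over the shared feature genes (the intersection of the two
datasets' feature sets, minimum 10 genes) is projected onto the reference
medoid matrix M by minimizing ‖x − Mw‖² subject to w ≥ 0 and Σw = 1. The
solver is a primal active-set method on the strictly convex QP obtained
after a relative ridge of 10⁻¹⁰ on Q = MᵀM: starting from the uniform
feasible point it solves the equality-constrained subproblem on the free
set, steps to the first blocking bound, and releases the most negative
multiplier until the KKT conditions hold. It terminates finitely, is
deterministic (ties toward the lowest index), and on random instances
matches a step-0.01 simplex grid oracle to machine precision with KKT
residuals ~10⁻¹³. Rank-deficient or duplicate medoids are handled by the
ridge; for duplicate-identical columns the stable quantity is the summed
weight, which the tests assert. Profiles enter in linear normalized space by
default (log2 space behind a flag). A query cell with zero expression on the
shared features receives a uniform weight row and is flagged.

## Lineage graph, pseudotime, SOM modules

**Lineage links.** In log feature space, each cell of cluster a is projected
onto the segments from its medoid to every other eligible medoid
(clusters ≥ cthr cells); the cell is assigned to the link with the largest
positive projection coordinate. A link's score is the fraction of its two
flanking clusters' cells assigned to it. Significance is a binomial tail
with null probability 1/(2(k−1)) per cell — the projection sign is
symmetric under the null and the target uniform among the k − 1
alternatives. This form keeps the forced two-cluster topology significant
(every cell lands on the single link, p = 0.5ⁿ) while a skipped middle
cluster in a collinear chain starves the terminal link, which the tests
assert. The stored `pthr` (0.01) marks significant edges; `scthr` (0.6) is
an export threshold for strongly covered links and `pethr` (0.05) a
secondary export level; neither affects the p-values. A seeded permutation
null is available behind a flag.

**Median transcriptome entropy** per cluster is Shannon entropy (nats) of
each cell's transcript fractions, H = −Σ p_g ln p_g.

**Pseudotime.** Cells of a user-specified cluster chain are ordered by
(chain position, projection onto the local chain direction). The local
direction is m_next − m_prev for interior clusters and the single adjacent
difference at the ends, so reversing the chain reverses the order exactly
(up to ties, which break by cell index). Per-gene profiles of
log2(x + 0.1) over the order are smoothed by local quadratic regression
with tricube weights (span 0.75), solved as 3×3 weighted normal equations
vectorized across genes.

**SOM modules.** Smoothed profiles are z-scored per gene and quantized by a
one-dimensional self-organizing map (default 50 nodes). Prototypes are
initialized by linear interpolation along the first principal component — a
deterministic, topology-respecting start — and refined by seeded online
training (2,000 epochs, learning rate 0.5 → 0.01, Gaussian neighborhood
σ = n_nodes/4 → 0.5, both decaying linearly). Adjacent occupied nodes whose
prototypes correlate above 0.85 merge into one module (maximal runs), so
the module count is non-increasing in the merge threshold. On a planted
two-wave trajectory (anti-correlated early and late genes) the map yields
exactly two modules at purity ≥ 0.95.

## GRN inference

Genes pass the expression filter when strictly more than `min_transcripts`
are seen in at least `min_cells` cells; the two stage profiles are
(4 transcripts, 2 cells, top 1,000 edges) and (5 transcripts, 1 cell, top
1,500 edges). For each target, a random forest (default 1,000 trees, √p
candidate features per split) regresses the standardized target on all
other genes; impurity-reduction importances are normalized per target to
sum to one, pooled, ranked by weight with lexicographic tie-breaking, and
truncated. Per-target forest seeds derive deterministically from the
configured seed and the target index, and cells are sorted canonically
before fitting so edge weights are invariant to input cell order. Constant
targets contribute no edges. Network modules are connected components of
the undirected top-N graph; per-module aggregated expression is the mean
member z-score per cell, exportable for embedding overlays. All genes act
as candidate regulators by default (a TF-list restriction is a flag).

## Synthetic data: what it emulates and what it does not

Counts are NB(m, r) via a gamma–Poisson mixture (variance m + m²/r,
dispersion r = 2 by default — strong overdispersion typical of UMI data).
Baseline gene means are log-uniform over roughly 0.1–20 transcripts per
cell; each cluster up-regulates a disjoint marker block (default 20 genes,
fold 8); shared clusters reuse one mean vector across stages up to a single
stage-wide scalar (1.5), the simplest structure under which the planted
correspondence is recoverable. Gradient genes vary log-linearly with planted
pseudotime (half increasing, half decreasing, amplitude 3 in log2); planted
regulator → target edges draw the target as Poisson(coef · regulator).
Toy FASTQ reads have exact barcodes, uniform coverage, constant quality and
configurable fractions of multimappers and off-whitelist barcodes.

Not emulated: barcode sequencing errors, gene-length and positional
coverage bias, ambient RNA, doublets, batch structure beyond the stage
scalar, ERCC titrations, and realistic quality scores. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not robustness to these artefacts of real libraries.

## Problem sizes and determinism

The test suite and acceptance script run the study conditions at desk scale:
600 cells per stage (200 per cluster) for correspondence recovery, 100 cells
per group for DE power, 500 genes for type-I calibration, 100 gradient genes
over 300 cells for trajectories, and 20 seeded replicates for GRN top-edge
recovery. All generators, the clusterer, the QP solver, the SOM and the
forests are deterministic given their seeds; pipeline outputs re-run
byte-identically, which the CLI test asserts.

## Known limitations

* Outlier cells are flagged, not re-clustered; cluster counts on data with
  many genuine outliers may differ from a full outlier-re-seeding scheme.
* The NB moment-matching for group sums treats cells as iid within a group;
  strong within-group heterogeneity inflates the effective dispersion only
  through the global background fit.
* The binomial link null is a simplification of randomization-based link
  significance; it is deterministic and calibrated on the synthetic
  geometry, but p-values on strongly non-convex cluster layouts should be
  read comparatively.
* Cluster chains are user-specified; the package scores and orders them but
  does not discover them.
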