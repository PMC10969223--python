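# Methods

This note records the modeling assumptions, parameter choices and known
limitations behind `sctme`, at the level of detail a user needs to judge
what the package's validation does and does not demonstrate.

## Data model and conventions

A dataset is a sparse non-negative integer cell×gene count matrix with
per-cell metadata (sample, condition ∈ {HRpos, HER2pos, TNBC, Normal},
major and minor cell type) and per-gene genomic coordinates. Coordinates
are 1-based inclusive (GTF convention), enforced at load. Chromosomes
order naturally (chr2 before chr10), then X, then Y; mitochondrial and
unplaced contigs are retained in the matrix but excluded from CNV windows,
with a log message rather than an error. Cell-type annotation is consumed,
never computed: it is an upstream problem with dedicated tools.

All randomness flows from a single root seed through named substreams
(SHA-256 of the stream name folded into a `SeedSequence`), so any stage can
be re-run in isolation with identical results and no stage perturbs
another's stream.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
biology. Counts are negative binomial via gamma–Poisson with gene-shared
dispersion θ = 2 (field-typical for UMI data) and log-normal library-size
factors (σ = 0.3). Gene baselines are log-normal (σ = 1), scaled to
6,000 expected counts per cell. Per-sample cell-type proportions are
Dirichlet perturbations of the base mixture (α_i = 5·K·p_i, so a uniform
base gives the conventional α = 5), which produces the across-sample
immune-fraction heterogeneity the cohort statistics need. Tumor-condition
samples keep 10% of their epithelium normal so the "tumor call in normal
epithelium" pathway is exercised; normal-tissue samples contain no tumor
cells.

Injected signals multiply expected expression: CNV segments by
2^(log2 CNR) in tumor cells of their conditions, markers and
ligand–receptor genes by their fold change in their target type/condition.
Marker and LR genes are pinned to a fixed baseline (0.25 expected counts)
so injected effects are governed by the stated fold changes rather than by
the luck of the baseline draw; at fold 8 this yields detection fractions of
roughly 0.7 in the target group versus 0.2 elsewhere, straddling the
0.5/0.3 selection boundaries from the correct sides.

The stock cohorts are `tiny` (6 samples × 300 cells, 3,000 genes over 6
chromosomes) and `standard` (12 samples × 1,500 cells, ≥3 per condition,
6,000 genes over 10 chromosomes). Panel sizes were chosen so that
arm-scale CNV segments (half a synthetic chromosome, the geometry of real
tumor CNVs) span several 100-gene smoothing windows, as they do on real
panels of 20–30k genes; with much smaller panels a segment touches only
2–3 windows and per-cell CNV profiles become physically inseparable from
noise regardless of the caller. Segment placement echoes known subtype
biology (strong single-arm gain for HER2+, two moderate gains for TNBC,
losses for HR+) with |log2 CNR| between 0.5 and 0.8. Each tumor condition
also receives 12 epithelial markers (fold 8) and one ligand–receptor pair
(fold 6), plus one pan-tumor-condition pair.

What the generator does not model: doublets, ambient RNA, cell-type-
specific baseline expression profiles, batch effects across datasets, and
subclonal CNV structure. Passing tests therefore demonstrate the
*procedural* correctness and statistical calibration of each stage under
the stated noise model, not robustness to those real-data artifacts — in
particular, real epithelial cells differ transcriptionally from the
reference types, which makes real CNV backgrounds noisier than ours.

## CNV estimation

The workflow's published form delegates CNV estimation to an external
package; here it is re-implemented as the standard expression-smoothing
method: depth-normalize to 10⁴ counts, log1p, subtract the per-gene mean
over reference cells (the unweighted mean over all non-epithelial cells —
per-type baselines would be better on real data but add nothing under our
generator), convert to log2, clip to ±1.5, running mean over 100 genes with
stride 50 per chromosome (a chromosome smaller than one window becomes a
single window), then subtract each cell's median window value. Window
means are computed directly per window (not by cumulative-sum differences)
so that a cell whose profile equals the reference mean yields an exactly
zero row. The CNV score is the mean squared window value: monotone in
aberration magnitude, zero exactly for a flat profile. Any monotone
aberration summary would serve the same role; this one is the simplest
that is differentiable in the signal and strictly positive off the null.

## Tumor calling

PCA uses the full SVD solver with a fixed sign convention (largest-
magnitude loading positive) for bit-level reproducibility. The kNN graph
(k = 15, Euclidean, binary, symmetrized by union) feeds igraph's Louvain
at resolution 2, seeded for determinism.

The aggregated cluster adjacency is size-normalized — edges/(|a|·|b|) —
because raw edge counts would make large clusters look universally
well-connected; raw counts remain available by configuration. A cluster's
"connectivity with the seed set" is its maximum over individual seed
members (a candidate tightly linked to any one normal cluster is normal);
"sum" is available by configuration.

The growth threshold τ is the minimum, over current seed members, of that
same connectivity-with-the-rest-of-the-set quantity. This parallel
definition — candidates and members scored identically — is deliberate:
defining τ as the minimum over all seed *pairs* degenerates as the seed
count grows, because two mutually distant normal clusters with zero direct
edges drive τ to 0, after which every cluster (including clear tumor
clusters) is absorbed. With a single seed τ = 0, so growth can start. The
absorb condition is ≥ τ, ties break to the lowest cluster id, and the loop
is order-independent; a brute-force restatement of the loop serves as the
test oracle.

The normal density model is a diagonal-covariance Gaussian mixture
(covariance floor 10⁻⁶) on the 15-D PCA embedding of initial-normal cells,
component count by BIC over 1–5. The embedding is used rather than raw
windows because it is the space in which the clusters were formed; the raw
window space is available by configuration. At least 50 initial-normal
cells are required. Weights are shifted negative log-likelihoods
(minimum at 0), so the "weight" is non-negative as a weight should be; the
raw value is available by configuration.

The final call fits a two-component 1-D Gaussian mixture to log1p of
weight × CNV score and thresholds at the smallest value where the
higher-mean component's posterior exceeds 0.5 (computed on a 4,001-point
grid spanning the observed range). If the fitted means are closer than
0.5 pooled SD, or the scores are constant, all cells are called normal.
Otsu thresholding is available as an alternative. One degenerate case is
handled above this operation: when the grown normal set covers every cell,
the refinement is skipped and the initial (all-normal) decision stands —
with no initial tumor cells the weighted scores are noise by construction,
and a mixture threshold on noise manufactures calls; the measured mixture
separation on a null cohort (≈1.7 pooled SD) is indistinguishable from a
true tumor case (≈1.9), so no separation-based guard can catch it.

Tumor calls are reported only for epithelial cells (`is_tumor`); a
non-epithelial cell above threshold is flagged, not called. Tumor calls in
normal-tissue samples are retained and flagged `tumor_normal`.

## Marker discovery

Balanced sampling keeps samples with *more than* the lower cutoff of
target cells (default 200; smaller cohorts need a smaller cutoff, exposed
in configuration), sets the upper cutoff to exactly twice the minimum kept
count, and subsamples larger samples uniformly without replacement,
deterministically per seed. Subsampling is not stratified by condition —
the balancing unit is the sample.

The DEG statistic is a tie-corrected Wilcoxon rank-sum z (normal
approximation, no continuity correction) per gene, group vs pooled rest,
on log-normalized expression; Welch's t is available by configuration.
p-values are two-sided; Benjamini–Hochberg adjusted values are reported
alongside, but the pre-ranking filter uses raw p (≤ 0.05) with
log2FC ≥ 0.25, both boundaries inclusive. log2 fold changes compare
group/rest means of normalized (de-logged) expression with a 10⁻⁹
pseudocount. A constant gene gets z = 0, p = 1. Detection fractions are
computed on raw counts. Marker selection applies pct_nz_group ≥ 0.5 and
pct_nz_reference < 0.3 exactly (the strict inequality matters at the 0.3
boundary), sorts by descending score with lexical gene-id tie-break, and
truncates at M = 12 per (cell type, condition).

## Ligand–receptor consensus

Eligibility requires ≥ 40 cells of *each* participating cell type in the
sample (the stricter of the two readings of a per-sample cell cutoff; the
sample-total reading is configurable). The permutation null shuffles the
sample's cell-type labels wholesale, which preserves type counts; with
identical sender and receiver types the permuted sender set doubles as the
receiver set. p = (1 + #{null ≥ observed})/(n_perm + 1), never 0 and never
below 1/(n_perm+1). The 10% detection-support rule (ligand in senders,
receptor in receivers, raw counts) forces p = 1 for unexpressed pairs.
Multi-subunit complexes are out of scope — pairs are simple gene–gene.

Consensus is evaluated per (pair, sender type, receiver type, condition)
with the denominator equal to that condition's *eligible* samples — the
only denominator under which the 75% rule is well defined per pair. The
per-sample significance filter (p ≤ 0.05, mean ≥ 0.1) and the reporting
filter (median mean ≥ 0.5, sort by median p then median mean, top 50)
apply at different stages: the former gates consensus, the latter gates
the final report.

## Cohort statistics

Immune fraction is the summed proportion of T, B and myeloid cells per
sample. Condition comparisons use Welch's t (pooled-variance optional)
with Bonferroni correction over the condition pairs actually tested; a
pair with fewer than two samples on either side is skipped with a warning,
and identical zero-variance groups get p = 1 by convention. The
CNV–immune screen averages log2(CNR) over each sample's tumor cells per
window, requires ≥ 3 contributing samples, skips zero-variance windows,
and reports Pearson r sorted by |r| with an optional report threshold
(default 0.6). No multiple-testing correction is applied across windows
and no significance is claimed — with a handful of samples per condition
the screen is descriptive.

## Pipeline and determinism

`run_all` executes input → CNV → tumor calling → markers → CCI → cohort
statistics, writing plain TSV/MTX artifacts and a JSON manifest (config
hash, seed, per-stage outputs and status). TSV floats are written with a
fixed format so reruns with the same config and seed are byte-identical.
Any stage can be driven from external files of the right shape through the
CLI.

## Problem sizes used in validation

The test suite and the acceptance script validate tumor calling and
marker/interaction recovery on the `standard` cohort (18,000 cells, 6,000
genes, three seeds), permutation calibration on 400 null pair-tests at
1,000 permutations, and the growth loop on 200 random cluster graphs
against brute force; boundary rules are checked on hand-built fixtures.
These sizes give stable estimates of every reported quantity (binomial
99% intervals for the calibration checks) while each stage remains a
single-CPU computation of a few minutes.
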