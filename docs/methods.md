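# Methods

## Synthetic data model

The generators are pure functions of (configuration, seed) and define the
study conditions every test and the acceptance script run under.

**Counts.** Gene counts are negative binomial around
`mu[g,c] = lib_c · rate_g · modifiers`, with variance `mu + α·mu²`
(`nb_dispersion` α = 0.1 by default, sampled as a gamma–Poisson mixture).
Per-cell library factors are log-normal with CV 0.25 around a mean library of
2,000 counts over 500 genes (so an average gene contributes ~4 counts/cell).
Per-gene relative rates are log-normal (σ = 0.4).

**Markers.** Each of the 5 cell types owns 3 exclusive markers: rate
8× the mean gene rate in the owning type and a small leak (5·10⁻⁴ of the mean
gene rate, ~0.002 counts/cell) elsewhere. Near-exclusivity is deliberate: the
strict specificity criterion (expressed in <3% of non-target cells) is a
property of truly exclusive genes, and the leak keeps the expected
out-of-type detection rate (~0.2%) far below that bound while also keeping
the lineage-doublet rule's false-removal rate of singlets under 2%.
A second, weaker class of exclusive genes ("auxiliary", 3× the mean rate,
default 0 per type) exists so that bulk couplings can drive genes that are
type-exclusive yet outside the type's top-N signature.

**Copy number.** CNV blocks multiply expected counts by `2^shift` in the
tumor type before sampling, so a +1 block doubles mean counts — the dosage
check is analytic. The default block spans one whole synthetic chromosome
(100 of 500 genes): expression-based CNV inference targets chromosome-arm
scale events, and at desk scale (2,000 counts/cell) a short sub-chromosomal
block is below the detection floor of a 51-gene smoothing window. The five
equal-sized chromosomes exercise per-chromosome smoothing boundaries.

**Doublets.** A configured fraction of cells is replaced by the sum of two
rate vectors from distinct types; they co-express both types' markers and are
the targets of the QC doublet rule.

**Bulk cohorts.** Sample abundances are symmetric-Dirichlet (concentration
100, i.e. modest compositional variation); log-expression is the log of the
abundance-weighted mixture of type mean-rate profiles plus Gaussian noise
(`noise_sd`, default 0.1). A coupling (A, B) adds
`shift · standardized(abundance_A)` to 20 of B's auxiliary exclusive genes.
The shift uses the standardized abundance because raw abundances vary little
around their compositional mean; the standardized form makes "driver genes
track A's abundance" hold at the stated shift scale while remaining
proportional to it. Two intrinsic properties of compositional mixtures are
worth keeping in mind when interpreting null cohorts: type-exclusive genes
always correlate positively with their own type's abundance, and negatively
(≈ −1/(k−1)) with every other type's — a planted coupling is therefore a
*positive* cross-type correlation, and null checks are one-sided.

**Program cohorts.** Cell rates are `w₁·(baseline + L_p1) [+ w₂·(baseline +
L_p2)]` with disjoint planted gene loadings (gamma-distributed weights); the
baseline rides on the program weight so a single-program cohort is exactly
rank one in expectation. Programs can be restricted to a condition to emulate
subtype-exclusive transcriptional states.

**Biomarker cohorts.** Two per-patient positivity rates are Beta-distributed
(concentration 12, baseline means 0.40/0.30); the recurrent group's means are
shifted up by `mean_shift`. The default evaluation cohort is 16 recurrent /
17 non-recurrent patients.

What the generators do *not* emulate: ambient RNA, batch effects, UMI
saturation, gene–gene co-expression beyond the planted structure, realistic
gene-length or GC effects, or overlapping marker programs. Passing tests
therefore certify the pipeline's logic and its statistical behavior under a
clean generative model, not performance on real tissue.

## Quality control and normalization

Cells are retained with feature counts strictly inside (200, 6000) and a
mitochondrial count fraction strictly below 0.10 (all bounds strict, read
from the "more than / less than" phrasing; the mito rule is a fraction of
counts, configurable). Lineage doublets are cells with nonzero counts for
both genes of any configured marker pair — no expression threshold, since
exclusive lineage markers should not co-occur at all. Rules apply in order
(low features, high features, mito, doublets) and each removal is counted
once. Normalization is `log1p(scale · count / total)` with natural log and
scale 10,000, the de facto default of the standard single-cell toolchain.

## CNV inference and scoring

Residuals are computed on log-normalized expression for query *and*
reference cells: subtract the per-gene reference mean, re-center each cell by
its own residual mean (removing depth-related offsets so the score reflects
chromosomal structure), clip to ±1.5, and smooth with a centered moving
average of 51 genes within each chromosome, windows shrinking symmetrically
at the edges. Genes without positions are dropped and reported; chromosomes
under 3 genes pass through unsmoothed with a warning.

The score normalizes the whole residual matrix by its single global maximum
absolute value — a per-cell maximum would destroy cross-cell comparability,
which cluster-level tumor calling needs — and sums squared normalized values
per cell. Calling is per cluster, not per cell: a query cluster is tumor when
its median score exceeds `median(ref) + z_cut · MAD(ref)` (z_cut = 3, raw
MAD). When the reference MAD degenerates to zero the call falls back to a
one-sided rank-sum test at α = 0.01, noted as ±inf in the reported margins.
Smoothing changes each cell's residual mean only through window shrinkage at
chromosome edges; the change is bounded by `2·(window//2)·max|r|` per
chromosome, which the tests assert.

## Marker statistics

pct values are raw nonzero fractions. log2FC is
`log2((mean(expm1 v₁)+1) / (mean(expm1 v₂)+1))` — de-logged means with
pseudocount 1, the avg_log2FC convention of the toolchain's v4 line.
Rank-sum p-values use the tie-corrected normal approximation with continuity
correction, switching to exact enumeration over group assignments when both
groups have ≤ 8 cells (exact even under ties). DEG discovery prefilters by
min.pct 0.1 and log2FC 0.5 (positive-only by default), tests the surviving
genes, BH-adjusts within each label and keeps adj. p < 0.05. The strict
specificity filter applies pct.1 > 0.50, pct.2 < 0.03, |log2FC| > 2, all
strict.

## Module scores

Genes are ranked by mean expression over all cells and cut into 24
equal-frequency bins (ties broken by gene order); each set gene draws 100
control genes from its bin (set genes excluded; with replacement only when
the bin is smaller than the draw), and the score is the mean set expression
minus the mean over the pooled controls, per cell. Draws come from a seeded
generator, so scores are exactly reproducible. Degenerate case: a set
covering the whole matrix leaves no eligible controls and scores 0 with a
warning.

## Correlative network

Signatures are the top-30 positive one-vs-rest DEGs by log2FC (ties by gene
identifier; types with fewer passing genes keep all). Self-expressed genes
per type: mean normalized expression > 1 and nonzero fraction > 20%, strict.
Abundance per bulk sample and type is the mean z-scored (across samples)
bulk expression of the signature genes, re-standardized per type so
abundance columns have mean 0/SD 1 by construction; constant bulk genes are
dropped with a warning and a type raises if under half its signature is
present. The adjusted correlation matrix is the gene × type PCC with each
type's self-expressed genes set to 0 — a type must not trivially explain its
own abundance. Per target, the top-30 positively correlated genes are
module-scored over all cells and the mean score of source-type cells weighs
the directed edge source → target (sources scoring high on a target's
abundance-correlated program are read as potential upstream regulators).
Gene symbols are matched upper-cased at the single-cell/bulk boundary — the
one deliberate exception to opaque identifiers, since symbol drift between
platforms is the dominant failure mode.

## Consensus NMF and meta-programs

Factorization runs on de-logged normalized values (nonnegativity).
Multiplicative updates minimize the Frobenius error; the objective is
monotone non-increasing, which the tests assert per iteration. Per K,
restarts (default 20; the analysis drivers use 5 at desk scale, where
consensus quality saturates) are matched to the best restart's components by
greedy maximum correlation; consensus spectra are component-wise medians and
usage is re-fitted against them and row-normalized. Stability is the mean
silhouette of the pooled restart components under that matching (correlation
distance); error is the best relative Frobenius error. K maximizes
`stability − λ·error` (λ = 1). The error enters directly — it is already a
scale-free quantity in [0, 1]; min–max rescaling across candidates would
amplify a few-percent error range to the size of the stability term and
select the largest K unconditionally. Candidates within 1% of the best
criterion tie and the smallest K wins; full diagnostics are emitted for
manual override.

Meta-programs: each pooled program contributes its top-50 genes; on the union
gene space the spectra are z-scored per gene (so dominant programs do not
swamp the correlation), programs are compared by PCC, clustered with average
linkage on 1 − PCC and cut into 3 groups. MP labels are deterministic
(clusters ordered by their lexicographically smallest program), consensus
genes are those in the top list of ≥ half the member programs, and cells are
assigned to the MP of their argmax-usage program. MP DEGs re-use the DEG
machinery at log2FC threshold 1.

## Two-marker ROC and Youden cutoffs

Candidate cutoffs per marker are the observed values plus −inf; a patient is
predicted positive when both rates strictly exceed their cutoffs (AND — the
combination rule the final decision threshold uses; OR and mean-score are
available for sensitivity analysis). A 2-D cutoff grid does not define a
unique ROC curve, so the single curve is the Pareto-dominant (FPR, TPR)
staircase closed at (0,0) and (1,1), and the AUC is its staircase area —
this construction can only gain from the second marker, so the two-marker
AUC never falls below either single-marker AUC. The Youden optimum maximizes
J = sensitivity + specificity − 1, ties broken by higher specificity, then
lower cutoffs. Sensitivity and specificity are computed as integer-count
ratios so they match an exhaustive confusion-matrix oracle exactly.

## Problem sizes and numerical choices

Defaults throughout are desk-scale: 5 types × 300 cells × 500 genes for the
CNV/marker stages; 5 types × 200 cells × 700 genes with 50 bulk samples for
the network; 5 samples × 120 cells × 200 genes, K = 3..10, 5 restarts ×
120 iterations for the NMF stage; 33 patients for the ROC stage. All
stochastic steps take explicit seeds; identical seeds give byte-identical
outputs. Oracle comparisons in the tests are at 1e-12 where arithmetic is
deterministic; distributional claims (AUROC, recovery rates, ARI) are
evaluated over 10–20 seeds.

## Known limitations

- Cluster-level tumor calling assumes clusters are homogeneous; a mixed
  cluster of tumor and normal fibroblasts would be called as a block.
- The global [−1, 1] normalization makes CNV scores comparable across cells
  but sensitive to a single extreme residual; clipping bounds that risk.
- Abundance estimation by signature z-score means is not a deconvolution; it
  recovers relative, not absolute, proportions, and degrades when signatures
  overlap between types.
- The ROC envelope is an optimistic summary of a 2-D cutoff family at small
  n; the null-cohort tests quantify that optimism (median best J ≈ 0.28 at
  33 patients with no effect).
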