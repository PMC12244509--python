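# tgctsc

Analysis pipeline for single-cell studies of tenosynovial giant cell tumor
(TGCT) — a locally aggressive synovial neoplasm in which the malignant cells
are a fibroblast-like minority hiding among reactive stroma and immune cells.
The package implements, as a tested and reusable library, the bespoke
computations such a study needs:

1. **CNV-score tumor identification.** Expression of fibroblast-like query
   populations is compared with copy-number-normal references (endothelial
   cells, T and B lymphocytes): per-gene reference-mean subtraction, per-cell
   re-centering, clipping, and moving-average smoothing along the genomic
   gene order give a residual copy-number profile. The profile is normalized
   to [−1, 1] by its global maximum absolute value and each cell's CNV score
   is the sum of its squared normalized values; clusters whose score
   distribution sits above `median(ref) + 3·MAD(ref)` are annotated tumor.
2. **Strict marker specificity.** One-vs-rest statistics (pct.1, pct.2,
   log2FC of de-logged means with pseudocount, Wilcoxon rank-sum, BH) and the
   strict filter pct.1 > 0.50, pct.2 < 0.03, |log2FC| > 2 that isolates
   tumor-exclusive surface markers.
3. **Correlative cell–cell interaction networks.** Top-30 DEG signatures per
   type → per-sample type abundance in a bulk cohort (mean z-scored signature
   expression) → gene × type Pearson correlations with each type's broadly
   "self-expressed" genes masked to 0 → per target the top-30 correlated
   genes are module-scored over all cells, and the mean score of source-type
   cells weighs the directed edge source → target.
4. **Consensus NMF meta-programs.** Per-sample multiplicative-update NMF over
   K = 3..10 with restart-consensus spectra, stability/error K selection, and
   clustering of pooled programs into meta-programs by the Pearson
   correlation of their top-50 gene spectra.
5. **Two-marker recurrence ROC.** For two immunohistochemistry positivity
   rates per patient, every cutoff pair is evaluated under an AND rule; the
   Pareto-dominant (FPR, TPR) staircase defines the ROC envelope and its AUC,
   and the Youden index J = sensitivity + specificity − 1 picks the optimal
   cutoff pair.

Because studies of this kind rarely deposit patient-level data, the package
ships a first-class synthetic-data module that plants ground truth for every
stage: exclusive markers, whole-chromosome copy-number gains, lineage
doublets, abundance-driver gene couplings in bulk mixtures, per-sample gene
programs, and biomarker/outcome cohorts with known effect sizes.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(later drivers are self-contained; 01–04 chain through `results/`):

```sh
python analysis/01_simulate_atlas.py --seed 1
python analysis/02_qc_normalize.py
python analysis/03_cnv_tumor_calling.py
python analysis/04_tumor_markers.py
python analysis/05_correlative_network.py --seed 1
python analysis/06_metaprograms.py --seed 1
python analysis/07_recurrence_roc.py --seed 1
```

which prints (seed 1):

```
simulated 1500 cells x 500 genes (75 planted doublets, tumor type = type0); wrote results/atlas/
retained 1413/1500 cells (doublet rule removed 87; 75/75 planted doublets caught); wrote results/qc/
tumor clusters: ['type0'] (planted: type0); CNV-score AUROC tumor vs reference = 0.9995; wrote results/cnv/
strict markers of type0: ['G00139', 'G00145', 'G00479'] (planted exclusives: ['G00139', 'G00145', 'G00479']); wrote results/markers/
abundance recovery PCC per type: {'type0': 0.989, 'type1': 0.988, 'type2': 0.991, 'type3': 0.988, 'type4': 0.989}; top incoming edge of type2: type1 (planted source: type1); wrote results/network/
chosen K per sample: {'S1': 3, 'S2': 3, 'S3': 3, 'S4': 3, 'S5': 3} (planted: 3); meta-program ARI vs planted families: 1.000; wrote results/metaprograms/
envelope AUC = 0.9743; Youden-optimal cutoffs: marker1 > 0.3623 AND marker2 > 0.3403 (J = 0.8787); wrote results/roc/
```

Reading the output: QC caught every planted lineage doublet while removing
under 1% of genuine cells; the CNV score separates planted tumor cells from
references almost perfectly and flags exactly the planted tumor cluster; the
strict specificity filter returns exactly the three planted tumor-exclusive
genes; the bulk abundance estimates track the true mixing proportions
(PCC ≈ 0.99) and the planted abundance coupling surfaces as the strongest
incoming network edge; K selection recovers the planted three programs in
every sample and the meta-program clustering matches the planted families;
and on a shifted biomarker cohort the two-marker AND rule reaches AUC ≈ 0.97
with its Youden-optimal cutoff pair.

The same stages are scriptable through one CLI
(`tgctsc simulate|qc|cnv|markers|score|network|metaprograms|roc|run`).

## Layout

- `src/tgctsc/` — the library: `synthetic`, `qc`, `cnv`, `markers`,
  `scoring`, `network`, `metaprograms`, `roc`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, parameter choices, and limitations.
- `tests/` — pytest suite with independent brute-force oracles.
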