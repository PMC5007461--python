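# protstrat

Proteomic stratification of cancer cell-line panels: a tested, reusable
implementation of the analysis chain that takes a label-free
protein-quantification matrix (or a peptide-level intensity table) to a
discriminating protein signature, external-cohort stratification and a
survival contrast.

The package is aimed at computational proteomics practitioners who work with
MaxQuant-style protein-groups tables from cell-line or tumour panels — for
example an ovarian-cancer panel in which cell lines fall into an
epithelial-like group, a clear-cell-like group and a mesenchymal-like group,
and where a compact protein signature is wanted to classify external tumour
proteomes into an epithelial and a mesenchymal cluster with different
overall survival.

## What it implements

* **Label-free quantification** (`protstrat.quantify`): per protein, the
  pairwise sample ratio is the median of log ratios over peptides observed
  in both samples, `r_AB = median_i log2(I_iA / I_iB)`; the relative
  abundance profile `x` minimises `Σ_(A,B) (x_A − x_B − r_AB)²` over the
  ratio graph per connected component, and is rescaled so that
  `Σ_s 2^{x_s}` equals the protein's total observed intensity. iBAQ =
  total intensity / number of theoretically observable peptides.
* **Preprocessing** (`protstrat.preprocess`): decoy/site/contaminant flag
  removal, the 2-of-3 replicate filter, replicate averaging, minimum-valid
  filtering, removal of ~200 abundant plasma proteins, row/column and
  cohort-wise z-scoring, reporter-channel (iTRAQ-style) normalization, and
  left-censored imputation from `Normal(μ_j − 1.8·σ_j, (0.15·σ_j)²)` per
  sample column.
* **Variability profiling** (`protstrat.variability`): per-protein SD of
  log10 intensity vs log10 summed iBAQ, with the high-variability subset at
  SD > 0.5.
* **Clustering and PCA** (`protstrat.multivariate`): hierarchical clustering
  with `d(i,j) = 1 − ρ_Spearman(i,j)`, dendrogram cuts, Newick export, and
  SVD-based PCA with explained-variance fractions.
* **Statistics** (`protstrat.stats`): the s0-moderated two-sample statistic
  `t = (x̄_a − x̄_b) / (se + s0)`, SAM-style permutation FDR,
  Benjamini–Hochberg adjustment, two-sided Fisher's exact enrichment,
  rank-based 1D annotation enrichment with position score
  `2·(R̄_in − R̄_out)/n ∈ [−1, 1]`, Kaplan–Meier estimation and the
  Mantel–Cox log-rank test.
* **Signature selection** (`protstrat.signature`): one-vs-all ranking by
  moderated-t p-value (s0 = 4), feature selection embedded in 250
  cross-validation repeats (stratified 85/15 splits, linear SVM error
  curves), per-group list sizes by the one-standard-error rule, the union
  signature, and its application to stratify any z-scored matrix into two
  clusters.
* **Synthetic panels** (`protstrat.simulate`): generator with planted
  groups, marker effects, a shared mesenchymal-like axis program,
  left-censored missingness, marker-concentrated annotation categories and
  group-dependent exponential survival — plus the ground truth needed for
  recovery tests.
* **Pipeline** (`protstrat.pipeline` and the `protstrat` CLI): a
  configuration-driven driver chaining all stages with a machine-readable
  manifest; `analysis/01…08` are narrative drivers for the same steps.

## Worked example

```sh
python analysis/01_simulate_panel.py
python analysis/03_preprocess_panel.py
python analysis/05_cluster_pca.py
python analysis/06_signature_selection.py
python analysis/08_survival.py
```

prints (abridged):

```
panel: 1000 proteins x 90 samples (3 groups x 10 lines x 3 replicates)
after replicate filter (2 of 3): 993 proteins
line-averaged, >= 10 valid values: 960 proteins x 30 lines
three clusters of sizes {1: 10, 2: 10, 3: 10}; adjusted Rand index vs planted groups = 1.000
per-group list sizes {1: 25, 2: 5, 3: 5} -> signature of 35 proteins (0 overlapping), 100% planted markers
2-cluster application separates group I from groups II+III with ARI = 1.000
cluster 1 (groups I): median survival 77.1 time units
cluster 2 (groups II+III): median survival 42.0 time units
Mantel-Cox log-rank: chi-square = 2.951, p = 0.0858
```

Reading the numbers: the unsupervised Spearman clustering recovers the three
planted cell-line groups exactly (adjusted Rand index 1.0); the
cross-validated one-vs-all selection needs a long list for the heterogeneous
epithelial-like group and short lists for the others, and every signature
protein is a planted marker; cutting the signature-restricted dendrogram at
two clusters isolates the epithelial-like group; the patient cohort tied to
those clusters shows the planted survival disadvantage of the
mesenchymal-like arm (medians are noisy at 84 patients, hence the moderate
log-rank p).

The same run is available as one command with a manifest:

```sh
protstrat run-all --seed 1 --outdir results/run1
```

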