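# Methods

This note documents the models, parameter choices and numerical conventions
behind `protstrat`, and what the synthetic panels do and do not establish
about real data.

## Label-free quantification

A peptide table holds raw (linear) intensities per peptide and sample; zero
is treated as the missing sentinel, and every peptide belongs to exactly one
protein id (shared peptides across protein groups are out of scope). For a
protein and an ordered sample pair (A, B), the pairwise protein ratio is the
median of `log2(I_A / I_B)` over peptides observed in **both** samples; at
least `min_ratio_count` (default 1) shared peptides are required for an
edge. Per protein, the log2 profile `x` minimises the sum of squared edge
residuals `(x_A − x_B − r_AB)²`. The system is solved per connected
component with `numpy.linalg.lstsq` after appending a gauge row that pins
the component mean (the profile is otherwise defined only up to an additive
constant); the resulting linear profile is rescaled so its sum equals the
component's total observed intensity. Consequences worth knowing:

* a sample disconnected from every other stays missing;
* a single-sample component keeps its observed intensity (total
  preservation forces this);
* total preservation makes per-sample rescaling equivariance *exact* only
  for consistent ratio sets — under noise, multiplying one sample's
  intensities by c reproduces that sample's abundance times c up to the
  (small) inconsistency absorbed by the component-level rescaling;
* for ≤ 6 samples the solution matches a dense Laplacian normal-equations
  solve to 1e-9 relative error (tested).

iBAQ is total intensity divided by the count of theoretically observable
peptides; the count must be ≥ 1.

## Preprocessing conventions

All matrices are log2 with NaN missingness. Standard deviations use the
sample (n−1) denominator everywhere, so the documented z-score example
(1,2,3) → (−1,0,1) is bit-reproducible. The filter chain used by the
pipeline is: flag removal (decoy-reverse and only-by-site always;
contaminants by default, separable) → per-line replicate filter (values kept
only where ≥ 2 of 3 replicates are observed; a line with fewer available
replicates is held to the available count) → replicate averaging (mean over
observed replicates) → minimum-valid filter (default 10 observed line
values) → imputation. Plasma-protein removal (a packaged, curated stand-in
list of ~219 classical high-abundance plasma gene symbols) is applied before
PCA when tumour-derived material is mixed in. Filters are idempotent and
individually correct; the pipeline enforces the order.

Imputation draws each missing entry of sample column j from
`Normal(μ_j − down_shift·σ_j, (width·σ_j)²)` with defaults width 0.15 and
down-shift 1.8 — the usual left-censored ("missing not at random")
assumption for label-free data, where values are absent mostly because they
fall below detection. Imputation is per sample column by default (a
whole-matrix mode exists behind `per_sample=False`); observed entries are
never altered; columns with fewer than two observed values are skipped with
a warning; a seed makes it deterministic.

Reporter-ion (iTRAQ-style) matrices are normalized by subtracting the
same-run control channel on log2 scale, dropping the control column and
median-centring each sample. Mixed-technology matrices are z-scored
cohort-wise (per quantification technology) so that cohort offsets cannot
masquerade as biology.

## Variability

Per protein, the SD of log10 intensity across line-averaged values (≥ 10
required) against log10 summed iBAQ; the high-variability subset uses a
strict `sd > 0.5` cutoff. Log base 10 is the default to match the axis
conventions of the usual variability plots; log2 is available. The SD is
computed on the line-averaged matrix (a flag switches to the raw matrix) —
replicate averaging first removes technical scatter, which is what a
between-line variability measure should ignore.

## Clustering and PCA

Distances are `1 − ρ_Spearman` with average ranks for ties, computed on
complete (imputed) matrices only; constant columns raise an error naming the
column. Linkage is scipy's agglomerative machinery; **average linkage** is
the default (the common default of the analysis platforms this mirrors; the
choice is configurable among average/complete/single/ward). Cluster labels
come from cutting at the height that yields exactly k clusters. PCA centres
each protein across samples and uses SVD; explained fractions are
eigenvalues over total variance, and the sign convention (largest-absolute
loading positive) makes outputs reproducible.

## Moderated statistics and permutation FDR

The two-sample statistic is `t = (x̄_a − x̄_b) / (se + s0)` with a pooled
standard error by default (Welch behind a flag; the SAM-style statistic this
follows pools). `s0 ≥ 0` damps low-variance, small-effect features; `s0 = 0`
recovers Student's t, and statistic magnitude is non-increasing in s0
(property-tested). P-values evaluate the moderated statistic against the
Student reference distribution with the unmoderated degrees of freedom; the
exact p-value recipe is not uniquely determined by the statistic, so where
calibration matters the permutation route is the one to use and the pipeline
uses it for the pairwise cluster comparison (s0 = 2, FDR 5%, 250 label
permutations; exact enumeration when the number of distinct arrangements is
smaller). The estimated FDR at cutoff c is
`(mean permuted count ≥ c) / (observed count ≥ c)`; per-protein q is the
minimum estimated FDR over cutoffs at or below the protein's own |t|, which
makes the significant set the largest one within the threshold.

BH adjustment delegates to `statsmodels.multipletests` and is tested against
the literal step-up definition. Fisher enrichment uses scipy's two-sided
exact test (probability-mass definition: sum of table probabilities ≤ the
observed one), minimum category size 4, BH threshold 0.02 — all tested
against exhaustive hypergeometric enumeration for margins ≤ 12. The 1D
enrichment ranks all n proteins by a numeric score (average ranks for ties)
and reports per category `score = 2·(R̄_members − R̄_others)/n`, which is +1
when members occupy the top ranks and −1 at the bottom; p-values come from
the two-sided Mann–Whitney U test; categories below the minimum size or
covering the whole universe are skipped.

Survival uses lifelines: the product-limit estimator (median = earliest time
with S(t) ≤ 0.5, infinite when never reached) and the Mantel–Cox log-rank
test on exactly two clusters, with a warning (not an error) when one arm has
no events.

## Signature selection

One-vs-all ranking orders proteins by ascending moderated-t p (s0 = 4,
target group vs pooled rest), tie-broken by |statistic| then id. Feature
selection is embedded in cross-validation: 250 repeats of a stratified
random 85/15 split (stratified rather than fully random so small groups
cannot vanish from training); per repeat the ranking is computed on the
training split only — a leakage-guard test plants a protein informative only
through held-out samples and asserts its aggregate rank is unaffected. For
each candidate list size k, a linear SVM (cost 1; the standard choice for
high-dimensional low-n omics) per group is trained on the top-k training
features and scored on the held-out split. Aggregate protein rank is the
median rank across repeats (a selection-frequency aggregation would also be
defensible; median rank is simpler and stable).

"Good tradeoff between minimal sets and smallest error rates" is
operationalized as the **one-standard-error rule**: the smallest k whose
mean held-out error is within one standard error of the minimum. Chosen ks
are always overridable in the pipeline config. The final signature is the
union of the per-group top-k lists; the overlap count is the number of
membership duplications absorbed by the union (e.g. 53/10/10 with six
overlaps → 67).

Applying a signature restricts a z-scored matrix to the signature rows
(≥ half must be present, else a coverage error), clusters samples by
Spearman distance and cuts at k = 2. Cluster identities are arbitrary
labels; naming (epithelial-like vs mesenchymal-like) is a downstream
convention by marker direction.

## Synthetic panels: what they emulate

`PanelConfig` defaults describe a 30-cell-line panel: 3 groups × 10 lines ×
3 replicates, 1,000 proteins (a deliberate scale-down from the ~10,000 of a
deep single-run experiment; it keeps the whole suite fast while leaving the
statistics comfortably powered), log2 intensities `N(25, 2²)` per protein
with replicate noise SD 0.5, 50 markers per group shifted +4 log2 units in
their own group, and 10% left-censored missingness (probit-shaped
missingness probability in log intensity, threshold calibrated numerically
per sample so the expected missing fraction matches the config).

Two structural features mirror the two-level biology of
epithelial/mesenchymal panels and are essential for the 2-cluster
behaviour:

* a **shared axis program** (50 proteins, effect 1.5 × the marker effect,
  i.e. 6 log2 units at defaults) elevated in every group except group I —
  the analogue of a mesenchymal program common to the non-epithelial
  groups;
* **partial penetrance (0.75)** of the axis programs (group-I markers and
  the shared program) at the line level: each axis protein is expressed in
  only ~75% of the relevant lines. This emulates the heterogeneity of the
  epithelial-like group, and it is what forces the cross-validated
  selection to pick a *long* list for group I and short lists for the
  others. That asymmetry is not cosmetic: for a perfectly symmetric
  3-group generator one can show the three possible 2-cluster cuts of the
  signature-restricted Spearman dendrogram are exchangeable (every
  signature dimension separates exactly one group from the other two, and
  rank correlations depend only on the per-group list sizes), so the
  epithelial-vs-rest cut could never be recovered reliably. Real panels
  avoid the tie the same way — the epithelial group contributes far more
  discriminating proteins than the others.

All planted effects scale with `effect_size`, so `effect_size = 0` is an
exact null. Annotation categories: one category per group concentrated in
that group's markers (fraction 0.8) plus random filler categories. Survival
times are exponential per group around planted medians (defaults 58 for
group I and 43.5 for groups II/III time units, 28 patients per group) with
independent exponential censoring calibrated to a 20% censored fraction —
independence keeps the Kaplan–Meier estimator unbiased.

What passing tests show — and what they do not: the generator produces
Gaussian log-intensities with a single shared missingness mechanism, fully
independent proteins apart from the planted programs, and exponential
survival. Real panels have correlated complexes and pathways, batch
structure, peptide-level artefacts and non-proportional hazards; recovery
of planted structure here validates the *implementation* of the chain, not
its power on any particular real data set. Quantities that depend on the
real data (exact dendrogram topologies, explained-variance percentages,
"13% of proteins above the cutoff", specific marker identities) are
deliberately not asserted.

## Problem sizes and runtime

The default test suite and the acceptance script run panels of 200–1,000
proteins and 12–90 samples, 250 CV repeats and 250 permutations; the full
suite completes in a few minutes on one CPU and the acceptance script in
well under one minute. These sizes are the package's study conditions, and
all thresholds in the tests (ARI = 1, ≥ 80% signature purity, FDR ≤ 2×
nominal, calibration tolerances) were fixed together with them.

## Known limitations

* Peptide-to-protein assignment is taken as given; protein inference,
  identification FDR and match-between-runs are out of scope.
* The moderated p-value's Student reference is a convention, not a
  calibrated null — use the permutation mode when error control matters.
* `apply_signature` performs cohort-level stratification; it is not a
  classifier for single new samples.
* The packaged plasma-protein list is a curated stand-in (any ~200-symbol
  list of abundant plasma proteins serves the same purpose).
* With fewer than ~3 lines per group the stratified 85/15 split degenerates
  (a group would lose its single test or training sample); the generator
  and pipeline assume ≥ 3 lines per group.
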