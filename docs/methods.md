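# Methods

`patchlink` implements an integrated analysis of patch-seq data from
pancreatic islet cells: each cell contributes a transcriptome (raw gene
counts from single-cell RNA-seq) and eight whole-cell electrophysiology
features measured on the same cell before harvesting. The pipeline links
the two modalities in five stages — marker-based cell typing,
electrophysiological fingerprinting, differential expression, detection-
filtered zero-excluded bootstrapped Spearman correlation, and gene-set /
genetic-risk enrichment — and ships a synthetic cohort generator with
planted, recoverable structure so that every stage can be validated
against a known truth.

## The synthetic cohort generator

### What it emulates

The generator draws a multi-donor case/control cohort comparing
nondiabetic (ND) and type 1 diabetic (T1D) donors. Its defaults mirror
the shape of a realistic islet patch-seq study:

| parameter | default | rationale |
|---|---|---|
| donors | 17 ND, 9 T1D | T1D donor tissue is rare; control banks are larger |
| cells/donor | ND 22, T1D 77 | deeper sampling of the rare T1D donors |
| cell-type mix (ND) | α .65, β .28, δ .04, γ .02, acinar .01 | dissociated-islet composition |
| cell-type mix (T1D) | α .86, β .025, δ .06, γ .035, acinar .02 | autoimmune β-cell loss: surviving β cells number in the tens |
| genes | 2,000 | desk-scale transcriptome |

Counts are negative binomial: gene baseline means are log-normal
(`exp(N(0, 1))` counts), dispersion θ = 1 (variance μ + μ²/θ), with an
optional donor random intercept on the log-mean (sd 0.1) so the pipeline
is exercised against donor clustering. Dropout is carried entirely by the
NB mass at zero (an optional `dropout_rate` adds independent zeroing);
this keeps the behavior of downstream detection filters realistic with
one fewer free parameter.

Hormone marker genes (GCG; INS and IAPP; SST; PPY; PRSS1/2; GHRL) have
baseline mean 5 and are boosted 100-fold in their own cell type, with a
tighter dispersion (θ = 10). Both choices reflect real islet data:
hormone transcripts make up several percent of an islet cell's library,
and high-mean transcripts sit well below the genome-wide dispersion
baseline (the standard mean–dispersion trend). Under the default NB
baseline (θ = 1, i.e. geometric-tailed), a mean-500 marker would still
produce a fat low tail and frequent marker dropout, which real data do
not show.

Two effect classes are planted, both restricted to α cells and recorded
in a `GroundTruth` object:

* **Differential expression** — `n_de_genes` = 40 genes shifted by
  `de_log2fc` = 2 log2 units in T1D α cells only.
* **Gene–electrophysiology couplings** — `n_linked_genes` = 20 genes
  tied to one electrophysiology property (default: normalized total
  exocytosis) through a Gaussian copula with latent correlation
  `rho_true` = 0.5. Per α cell, the gene's latent normal is
  `ρ·z_prop + √(1-ρ²)·ε`, where `z_prop` is the property's standardized
  value under its generating distribution; the latent is mapped through
  the gene's NB quantile function. This preserves both marginals exactly
  while fixing the latent rank correlation at (6/π)·asin(ρ/2) ≈ 0.483
  for ρ = 0.5.

Planted genes draw baseline means log-uniformly on [5, 50] rather than
from the global log-normal: the population-relevance filter downstream
(detection in ≥ 50% of cells) must be able to retain them, otherwise
"recovery" would be undefined for a random subset of the truth.

Electrophysiology is multivariate normal per (condition, cell type) over
the eight features, in raw patch-clamp units: cell size (pF); total,
first and late depolarization-evoked capacitance increase normalized to
cell size (fF/pF); early and late peak Ca²⁺ current density (pA/pF);
cumulative Ca²⁺ charge entry (pC/pF); peak Na⁺ current density (pA/pF).
Inward currents are negative. T1D α cells are larger and
hyperresponsive (≈1.5× exocytosis, larger Ca²⁺/Na⁺ currents); T1D β
cells show elevated exocytosis and Ca²⁺ currents. The default covariance
is diagonal with sd = 45% of the feature mean (floored at 0.5 in the
feature's units), a deliberate compromise: tight enough that α and β
populations are separable well above the 75% classifier gate, wide
enough that no single feature dominates the fit.

### What it does not emulate

No sequencing reads, no raw capacitance/current traces, no ambient RNA
or doublets, no batch or plate effects, no cell-cycle structure, no
glucose-level variation within a cohort (all cells carry the configured
glucose, default 5 mM). Gene–gene correlation beyond the shared donor
intercept is absent, so gene-set enrichment nulls here are friendlier
than in real data. Passing tests therefore demonstrate correctness of
the statistics and recoverability of planted effects under the stated
model — not robustness to every failure mode of real patch-seq data.

One property of the generator is worth knowing when reading outputs:
because the planted DE program is large (40 genes × 4-fold at moderate
expression), per-cell normalization makes the *unchanged* genes appear
systematically down-shifted in T1D α cells (a compositional effect, just
as in real CPM-based differential expression). Discovery counts in the
DE table therefore exceed the 40 planted genes; the planted set still
ranks first in the enrichment stage.

## Cell typing

Expression is normalized to 10,000 counts per cell and transformed with
ln(1+x) (CP10K-log). Each cell is labeled with the type whose mean
normalized marker expression is maximal; cells whose best marker score
is zero are `unassigned`. Ties between nonzero scores break by scheme
order (deterministic). The log base is immaterial: every statistic
downstream of typing is rank-based within cells.

This is a deliberate simplification of the embedding/clustering route
(graph clustering on a reduced space, then labeling clusters by the same
markers): the marker-to-type map is identical, the embedding is
presentation-layer, and direct marker scoring recovers ≥ 99% of planted
types on the default cohort. Outlier exclusion (below) and all
downstream stages consume these labels.

## Electrophysiology outlier exclusion

Within each (cell type × condition × glucose) stratum and each feature
independently, values with |z| > 3 (sample mean/sd, ddof 1) are masked.
Removal is per-feature, not per-cell: a cell with one aberrant current
keeps its other features. Strata with fewer than two observed values, or
zero standard deviation, pass through unchanged. Exclusion is applied
once, before classifier training and all downstream statistics, so every
stage sees the same data.

## Electrophysiological fingerprinting

A gradient-boosted decision-tree ensemble (XGBoost, `binary:logistic`)
is trained on the eight features to classify α vs β cells, using ND
cells only (typed α and β cells with complete electrophysiology). The
predicted probability is the **α score**: 1.0 = canonically α-like
electrical behavior, 0.0 = β-like; the β score is its complement.

Training protocol: stratified 80/20 train/test split; a further 20%
validation carve-out of the training split drives early stopping
(patience 100 boosting rounds, AUCPR as the evaluation metric, up to 500
rounds). A small grid — max depth {2, 3, 4}, learning rate {0.05, 0.1},
subsample {0.8, 1.0} — is scanned in fixed order and the first
configuration whose validation accuracy reaches 0.75 wins; if none does,
the best (accuracy, fewer rounds) configuration wins. No class
reweighting is applied (training classes are roughly balanced); balanced
accuracy is always reported to expose majority-class collapse.

Predictions use the full trained ensemble, not a truncation at the
AUCPR optimum. AUCPR is a pure ranking metric: on well-separated data it
saturates in the first rounds, and truncating there leaves shrunken
probabilities (≈0.9 for unambiguous α cells) that undermine the α score
as a graded phenotype. The rounds past the plateau, bounded by the
patience window, only sharpen calibration.

The audit reports the confusion matrix, accuracy, balanced accuracy,
AUCPR, and gain-based feature-importance shares normalized to sum 1; a
flag is raised when any single feature's share exceeds 0.5 (the
qualitative "no overreliance" property made testable). Associations of
the α score with donor covariates (age, sex, BMI, cold-ischemia time,
condition) use ordinary least squares with an intercept; rank-deficient
designs are rejected with the collinear columns named (pivoted QR).

## Differential expression

Per-gene two-group comparison (T1D vs ND within one cell type) by the
Wilcoxon rank-sum test on CPM (counts per million) values, using the
normal approximation with tie correction and a 0.5 continuity
correction; z > 0 means higher in T1D. Ranks are invariant to the log,
so computing the statistic on CPM or log-CPM is identical. Genes
detected in fewer than 3 cells overall are dropped before testing (their
null is dominated by ties at zero and the normal approximation is
meaningless there) and reported as untested. Fold changes are
`log2((mean CPM_T1D + 1) / (mean CPM_ND + 1))`; the pseudocount of 1 CPM
is recorded in the table metadata. FDR is Benjamini–Hochberg across all
tested genes; the significance gate downstream is q < 0.1.

The normal approximation is accurate at the group sizes this pipeline
targets (tens to hundreds of cells); the test suite checks it against
exhaustive enumeration at 4 vs 4, where it still tracks the exact p
within 0.05.

## Transcript–electrophysiology correlation

The linkage statistic, per (gene, property):

1. **Detection filter** — only transcripts detected (count > 0) in
   ≥ 50% of the cell group are considered (populational relevance).
2. **Zero exclusion** — for each gene, cells with zero counts are
   removed from that gene's correlation (pairwise), limiting the
   influence of tied ranks and zero inflation.
3. **Spearman's ρ** on average ranks of the remaining pairs; two-sided p
   from the t approximation with n−2 degrees of freedom. ρ is reported
   missing when fewer than 3 cells remain or either margin is constant.
4. **Bootstrap** — B = 1,000 resamples of cells with replacement; one
   resample per iteration, shared across genes (preserving cross-gene
   dependence and keeping cost linear in B). The bootstrap supplies the
   mean coefficient used to rank genes for enrichment; significance is
   gated on the plug-in estimate's p (the bootstrap is a ranking device,
   not a test).

Ranks are computed on **raw counts**, not CPM. Spearman's ρ is invariant
to any monotone per-gene transform, so for untied data the choice is
cosmetic — but counts are heavily tied, and dividing by per-cell totals
re-breaks those ties by 1/library-size. Whenever library size co-varies
with the property (which the planted couplings guarantee here, and
biology can produce in real data), that tie-breaking manufactures
spurious correlations: under CPM ranking the measured decoy
false-positive rate at p < 0.05 was 0.09–0.15 instead of 0.05. Raw-count
ranking restores nominal calibration (≈0.05).

The default property set is the eight model features, the α score, and
the exocytosis/Ca²⁺ ratio (total exocytosis per unit Ca²⁺ charge entry,
a measure of the secretory efficacy of Ca²⁺ influx).

**Multi-property consistency**: a gene is reported as a consistent
correlate when it is significant (p < 0.05) for at least 3 properties
*and* all its significant coefficients share one sign; genes meeting the
count with mixed signs are logged separately. Note that the properties
are themselves correlated (the ratio shares a numerator with total
exocytosis; the α score is a function of all eight features), so the
consistency count is evidence of breadth, not of independent
replication.

Zero-exclusion has one quantitative consequence worth flagging: it
conditions on detection, truncating the low tail of the latent
expression scale, and together with NB discretization it attenuates the
observable rank correlation below the copula-implied value. At planted
ρ = 0.5 (implied Spearman 0.483) the measured per-gene values run
≈ 0.40–0.47 depending on expression level. Tests therefore check the
mean over linked genes within ±0.1 of the implied value, and recovery is
assessed by significance with correct sign, which is insensitive to the
attenuation.

## Enrichment

**Preranked GSEA.** Genes are ordered by decreasing score (DE z, or
bootstrap-mean ρ). The enrichment score is the maximum deviation of the
classic weighted running sum: hits increment by |score|^w / Σ|score|^w
(w = 1 by default; w = 0 gives the unweighted statistic), misses
decrement by 1/(N − N_hit). Sets are intersected with the ranked
universe; sets outside [5, 500] after intersection, or equal to the
whole universe (miss denominator zero), are skipped with a warning. The
null permutes set membership over genes (the only permutation scheme
available for preranked input), with nulls shared across sets of equal
size; nominal p and NES are sign-matched (ES divided by the mean of
same-sign null ES), and FDR follows the standard pooled-NES procedure.
The leading edge is the set members at or before (after, for negative
ES) the running-sum extremum.

**Weighted set cover.** Significant sets (q < 0.1) are reduced by greedy
selection maximizing (newly covered genes × weight) per step, weight =
−log10(q) clipped at 16; every selected set must contribute at least one
new gene; ties break by set name. This is a redundancy-reduction
heuristic, not an optimal cover.

**Over-representation (ORA).** One-sided hypergeometric upper tail for
the overlap between a hit list (e.g. the consistent correlates) and each
set, against the detected-gene background, with BH FDR across sets.

**Genetic-risk enrichment.** A 2×2 Fisher exact test (two-sided, point-
probability rule) of a query gene list (e.g. upregulated DE genes, or
positive/negative α-score correlates) against a risk-gene list, with the
background of all tested genes. Risk lists are plain-text inputs built
by the user (e.g. human-genetic-evidence score ≥ 3, or islet eQTL
significance at 2×10⁻⁶ strict / 5×10⁻³ permissive); the pipeline records
which list was used but does not bundle any database. The odds ratio
uses the Haldane–Anscombe 0.5 correction when any cell is zero; the 95%
CI is the Woolf log-OR interval on the (corrected) table. The Woolf
interval is asymptotic: its coverage is nominal when expected cell
counts are large (the calibration test uses expected overlap 160 and
measures ≈94–95% coverage) and degrades for very sparse tables.

## Pipeline and reproducibility

`run_pipeline` executes typing → outlier exclusion → fingerprinting →
DE → GSEA → correlations → consistency → ORA → risk enrichment on a
configured stratum (default: α cells), reading a dataset directory or
generating a synthetic cohort from an embedded generator block. One
config seed fans out to per-stage seeds through `SeedSequence` spawning,
so stages are individually re-runnable. Identical config + seed gives
byte-identical TSV/JSON outputs; wall-clock timings go to `run.log`,
which is the one file outside that contract. Every threshold actually
applied (detection 0.5, |z| > 3, p < 0.05, FDR < 0.1, ≥ 3 properties) is
echoed in `report.json`. If the electrophysiology table is absent, the
fingerprinting and correlation stages are skipped with explicit notice
and the transcriptome-only stages still run.

## Problem sizes used in validation

The test suite validates at sizes chosen for statistical adequacy:
the default cohort (~1,067 cells, 2,000 genes) for typing, the
classifier gate and null calibration; 20 replicates of ~100 vs 100 α
cells for DE recovery; a single-condition 400-α-cell cohort with 4,800
genes for correlation recovery (≥ 2,000 calibrated decoys); 1,000
replicates for CI coverage; 1,000 small random instances against the
exact Spearman oracle, 500 tables against Fisher enumeration, and 200
instances against the brute-force running-sum oracle. Pipeline-level
tests use smaller cohorts (≈400 cells, 400–600 genes) with B = 50 and
100–200 permutations.

## Known limitations

* The Wilcoxon DE is per-cell, as specified: donor pseudobulk or
  covariate-adjusted models are out of scope, so donor effects inflate
  effective significance in real multi-donor data.
* Spearman correlation detects monotone association only; nonmonotonic
  (e.g. parabolic) gene–function relationships are invisible to it.
* The t-approximation p for Spearman and the normal-approximation
  rank-sum p are asymptotic; both are validated against exact references
  at small n but are not exact tests.
* The consistency rule counts correlated properties (see above).
* GSEA's gene-permutation null ignores inter-gene correlation, as all
  preranked GSEA implementations do; FDRs on real (correlated) data are
  approximate.
* The generator's electrophysiology is Gaussian per stratum; real
  patch-clamp features are skewed and heavy-tailed, which is precisely
  why the |z| > 3 exclusion stage exists — but the exclusion rate
  measured on Gaussian groups (≲1%) understates what real data would
  show.
* The generator's T1D α-cell shift (hyperresponsive: more exocytosis,
  larger currents) moves those cells *further* from β cells in feature
  space, so a classifier trained on ND cells scores synthetic T1D α
  cells as slightly more α-like. In real disease data the same
  hyperresponsiveness coexists with a *loss* of canonical identity and
  lower α scores — a phenotype the generator's per-stratum Gaussians do
  not attempt to reproduce. Score-direction effects between conditions
  should therefore not be read off synthetic cohorts.
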