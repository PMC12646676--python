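# patchlink

Linking islet-cell electrophysiology to transcriptomes in patch-seq
studies of type 1 diabetes.

## The problem

Patch-seq records whole-cell electrophysiology and a single-cell
transcriptome from the *same* pancreatic islet cell. In type 1 diabetes
(T1D), the surviving β cells and the glucagon-secreting α cells both
show disturbed electrical behavior; the scientific question is which
transcripts and pathways travel with that dysfunction. Answering it
requires an integrated analysis that (i) types cells from markers,
(ii) compresses eight electrophysiology features into an interpretable
cell-identity score, (iii) finds condition-dependent expression changes,
(iv) correlates transcripts with electrical function gene-by-gene
without being swamped by dropout zeros, and (v) asks whether the hits
concentrate in pathways and in genetic risk loci.

`patchlink` implements that pipeline for analysts working with
patch-seq exports (MatrixMarket counts + TSV metadata/electrophysiology
+ GMT gene sets), together with a synthetic multi-donor cohort generator
with planted ground truth, so every stage is testable at desk scale.

## The statistics at the core

* **α score** — an XGBoost ensemble over the 8 features
  (cell size pF; total/first/late exocytosis fF/pF; early/late Ca²⁺
  peaks pA/pF; Ca²⁺ integral pC/pF; Na⁺ peak pA/pF), trained on
  nondiabetic α vs β cells with early stopping (patience 100 rounds,
  AUCPR metric) and a ≥75% held-out accuracy gate. P(α) = 1 means
  canonically α-like electrical behavior, 0 means β-like.
* **Differential expression** — per-gene Wilcoxon rank-sum on CPM
  (tie + continuity corrected normal approximation),
  log2FC = log2((CPM̄_T1D+1)/(CPM̄_ND+1)), Benjamini–Hochberg FDR,
  gate q < 0.1.
* **Zero-excluded bootstrapped Spearman** — for each transcript detected
  in ≥50% of cells, cells with zero counts are dropped *for that
  transcript*, Spearman's ρ is computed against each electrophysiology
  property (p from the t approximation, df = n−2), and B = 1,000 cell
  bootstraps (resample shared across genes) give the mean coefficient
  used to rank genes for enrichment. Genes significant with one sign
  across ≥3 properties are reported as consistent correlates.
* **Enrichment** — preranked GSEA (weighted running-sum ES,
  gene-permutation null, pooled-NES FDR, weighted-set-cover redundancy
  reduction), hypergeometric ORA, and two-sided Fisher exact
  genetic-risk enrichment with Haldane-corrected odds ratios and Woolf
  95% CIs.

Model details, defaults and numerical conventions: `docs/methods.md`.

## Worked example

```python
import patchlink as pl
from sklearn.model_selection import train_test_split

# a default synthetic cohort: 17 ND donors, 9 T1D donors, 2,000 genes
dataset, truth = pl.generate_dataset(pl.GeneratorConfig(seed=1))

# 1. cell typing from hormone markers
types = pl.annotate_cell_types(pl.normalize_cp10k_log(dataset),
                               dataset.gene_ids, dataset.cell_ids)

# 2. electrophysiological fingerprinting on ND alpha/beta cells
nd_ab = types.isin(["alpha", "beta"]) & (dataset.cell_meta["condition"] == "ND")
X, y = dataset.ephys.loc[nd_ab[nd_ab].index], types[nd_ab].to_numpy()
X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.2,
                                          stratify=y, random_state=1)
model = pl.train_classifier(X_tr, y_tr, pl.TrainConfig(seed=1))
audit = pl.audit_classifier(model, X_te, y_te)

# 3. differential expression, T1D vs ND alpha cells
cpm = pl.normalize_cpm(dataset)
alpha = (types == "alpha").to_numpy()
t1d = (dataset.cell_meta["condition"] == "T1D").to_numpy()
de = pl.wilcoxon_de(cpm[:, alpha], dataset.gene_ids, t1d[alpha])
```

On this cohort the run prints:

```
cohort: 1,067 cells, 26 donors (374 ND / 693 T1D), 2,000 genes
typing agreement with planted truth: 1.000
held-out accuracy 0.986, balanced 0.990, AUCPR 0.999, max importance share 0.27
DE: 1068 genes at q<0.1; planted-DE recovery 1.00
correlation (T1D alpha cells): 1023 genes pass detection; 78 significant;
  linked-gene mean rho 0.425 (20/20 significant)
```

Reading the numbers: typing recovers every planted cell type; the
classifier clears the 75% accuracy gate with a large margin and no
feature contributes more than 27% of the importance; all 40 planted DE
genes are recovered at q < 0.1 (the additional discoveries are the
compositional echo of a large planted program under per-cell
normalization — see `docs/methods.md`); and the 20 planted
gene–exocytosis couplings (latent ρ = 0.5, implied Spearman ≈ 0.48,
attenuated by zero-exclusion on discrete counts) are all detected with
the correct sign.

The same analysis runs end-to-end from a config file:

```bash
patchlink simulate --seed 1 --out cohort/          # fixture + truth + GMT
patchlink validate cohort/                         # invariant check + summary
patchlink run --config analysis.yaml               # full pipeline -> TSVs + report.json
```

where `analysis.yaml` names either `input_dir: cohort/` or an embedded
`synthetic:` block, plus thresholds (defaults: detection 0.5, |z| > 3,
p < 0.05, FDR < 0.1, ≥ 3 properties), B, n_perm and a seed. Identical
config + seed reproduces every output byte-for-byte.

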