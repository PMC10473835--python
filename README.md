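# npxcc — cross-cohort comparison of NPX inflammatory proteomes

`npxcc` is a tested, reusable pipeline for comparing targeted affinity
proteomics panels (Olink-style proximity-extension assays, reported as
normalized protein expression, NPX, on a log2 scale) between two cohorts
measured on separate plate sets — for example an East African and a Western
European population profiled on the same 92-protein inflammation panel. It
is aimed at systems-immunology and molecular-epidemiology analysts who need
the whole chain from raw long-format NPX exports to differential-expression
tables, host-factor scans and metabolome–proteome association matrices,
with every pre-analytical decision recorded.

## What it computes

**Bridging normalization.** Pooled plasma controls ("bridge" samples, two
per plate, four plates per cohort) are measured in both cohorts. For each
protein *p* the between-cohort technical offset is

    X_p = median(bridge NPX in cohort A) − median(bridge NPX in cohort B)

and X_p is subtracted from every cohort-A value (and from cohort A's limit
of detection, so below-LOD status is invariant under bridging).

**Quality control.** Values below the limit of detection (LOD) are kept as
measured, never imputed; a protein is excluded when more than 25% of study
samples fall strictly below its LOD (per cohort, in both cohorts, or in
either — configurable). Samples are screened once with PCA: any sample
whose PC1 or PC2 score lies more than 3 SD from the component mean is
removed.

**Differential expression.** Per protein, OLS of NPX on a cohort indicator
plus covariates (age, sex, BMI by default); the cohort coefficient is the
log2 fold change. Residual variances s²_g are shrunk toward a panel-wide
prior with the empirical-Bayes posterior

    s²_post = (d0·s0² + df·s²_g) / (d0 + df),   t_mod = β / (u·s_post)

where (d0, s0²) are moment-matched on the log residual variances and u is
the unscaled coefficient SD; t_mod has d0 + df degrees of freedom.
Benjamini–Hochberg FDR < 0.05 declares a protein differentially expressed.

**Scans and clustering.** Factor-by-protein regression scans (age, sex,
BMI, season, residency, exposures) with FDR stars (\*\*\* < 0.0001,
\*\* < 0.005, \* < 0.05); a matrix pQTL scan of additive SNP dosages with
unadjusted p-values flagged at 5×10⁻⁸ / 5×10⁻⁶; two-layer unsupervised
clustering (Ward hierarchical clustering of food-derived metabolites, then
k-means with 100 restarts on the proteome) with chi-square / Mann–Whitney
annotation enrichment; and a metabolite × protein multiple-regression
matrix (protein ~ metabolite + age + sex, standardized betas, matrix-wide
FDR) with chemical-class summaries.

**Synthetic cohorts.** A fully seeded generator produces two cohorts with
known injected cohort effects, covariate effects, technical and plate
offsets, LOD censoring, multivariate outliers, a two-cluster food
metabolome coupled to the proteome, and Hardy–Weinberg genotypes — so
every stage is testable end-to-end against ground truth.

## Worked example

```python
import npxcc
from npxcc.simulate import SimConfig, simulate_study

cfg = SimConfig(seed=42)                 # 318 + 416 samples, 92 proteins
a, b, meta, metab, geno, truth = simulate_study(cfg)

clean_a, clean_b, qc = npxcc.preprocess_pipeline(a, b)
de = npxcc.run_de(clean_a, clean_b, meta)
print("retained proteins:", clean_a.n_proteins, "/", clean_b.n_proteins)
print("DE counts:", de.counts)
print(de.summary().head(5).round(3))
```

prints

```
retained proteins: 72 / 74
DE counts: {'up': 36, 'down': 21, 'ns': 15}
         log2_fc   t_mod    p  fdr direction
protein
prot061    1.723  50.316  0.0  0.0        up
prot065    1.937  49.007  0.0  0.0        up
prot063    1.904  47.932  0.0  0.0        up
prot051    1.428  45.966  0.0  0.0        up
prot054    1.677  41.870  0.0  0.0        up
```

Twenty proteins censored above the 25% below-LOD rule were excluded (20 in
cohort A, 18 in cohort B, leaving 72 and 74), 12 planted outlier samples
were removed, and the strongest injected effect (1.9 log2 units) is
recovered at 1.937 with an essentially zero FDR. `de.plot_volcano()` draws
the volcano plot with the FDR gate and the ±0.5 log2 display cut-offs.

The same analysis runs from the shell:

```bash
npxcc simulate --seed 42 --out sim/
npxcc run --config run.yaml            # paths + thresholds in YAML
```

producing per-stage TSVs, a QC report (JSON + TSV) and a run report
(JSON + markdown) whose content hash is reproducible from config + inputs.

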