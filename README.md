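# proteodx

Integrated proteome + targeted-RNA analysis for cohort-based single-case
diagnostics: missing-value-aware preprocessing of a PBMC protein intensity
matrix and a targeted RNA count matrix, disease-gene calling by cohort
z-scores and healthy-control fold changes, per-gene protein–mRNA correlation
profiling, marker-based classification of B-/T-cell-deficient samples, and
moderated differential expression with gene-set enrichment. A synthetic
cohort generator with full ground truth stands in for raw study data and
drives all recovery tests.

## Modules

| module | what it does |
| --- | --- |
| `proteodx.matrix_io` | data model (`ExpressionMatrix` with explicit missingness mask, `CohortMeta`, `GeneAnnotation`, `GeneSetCollection`), TSV/GMT/JSON I/O |
| `proteodx.synthetic_cohort` | log-normal protein intensities with batch shifts and abundance-dependent left-censored dropout; negative-binomial targeted RNA counts; planted disease cases, cell deficiencies and dropout outliers; ground-truth records |
| `proteodx.qc_missingness` | sample PCA + robust outlier exclusion, MV-proportion~abundance regression, MV density contrast, protein/RNA gene filters, panel-overlap report |
| `proteodx.normalize_impute` | zero-floor and MinDet (per-sample low quantile) imputation, quantile and robust-linear-regression normalization, size-factor log transform for counts, normalization-assessment metrics |
| `proteodx.diagnose_case` | cohort z-scores (both layers), archetype classification (concordant vs protein-only loss), case-vs-HC log fold changes (MA table), candidate ranking |
| `proteodx.correlate_layers` | per-gene Spearman rho with strength bins (strong/moderate/weak/none) and marker-group summaries |
| `proteodx.cluster_celldef` | marker selection (fewest MVs, then specificity), z-normalized k-means (k=2), elbow validation, cross-layer agreement (Jaccard/containment) |
| `proteodx.dea_enrich` | empirical-Bayes moderated t-test, strict significance thresholds, hypergeometric enrichment with BH adjustment |

## CLI

All stages are exposed through one entry point (`proteodx --help`):

```sh
# generate a synthetic cohort (TSV matrices + metadata + truth.json)
proteodx simulate --config sim.yaml --out cohort/

# QC funnel: PCA exclusion, MV diagnostics, gene filters, overlap report
proteodx qc --in cohort/ --out qc/

# imputation + normalization of both layers
proteodx preprocess --in cohort/ --out pre/ --impute min_det --norm quantile

# single-case diagnostics (zero-imputed arm): calls, candidates, MA table
proteodx diagnose --in cohort/ --out dx/ --case P005

# per-gene protein-mRNA Spearman correlation (MinDet arm)
proteodx correlate --in cohort/ --out corr/

# B-/T-cell-deficiency clustering, protein or RNA layer
proteodx cluster --in cohort/ --out clu/ --cell-type b --layer protein --seed 0

# moderated DEA + gene-set enrichment for a sample grouping
proteodx dea --in cohort/ --out dea/ --groups groups.tsv --gmt sets.gmt
```

A `sim.yaml` holds `SimConfig` fields plus an optional `plants:` list, e.g.

```yaml
n_patients: 63
n_controls: 6
n_genes_protein: 2000
n_genes_targeted: 500
seed: 7
plants:
  - {kind: concordant_down, sample_id: P005, effect_log2: 8.0, gene: G0100}
  - {kind: b_cell_deficient, sample_id: P010, effect_log2: 4.0}
```

## File formats

- expression matrices: TSV, genes as rows, header of sample ids, empty cell
  (or `NA`) = missing; a literal `0` is an observed zero
- metadata: TSV with `sample, role, batch, excluded, exclusion_reason`
- annotation: TSV with `gene, targeted_panel, nontarget_category,
  cell_marker, coding`
- gene sets: standard GMT (`set id <TAB> description <TAB> genes...`)
- results: TSV tables plus JSON summaries
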