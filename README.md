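# pdxfidelity

Patient-derived xenografts (PDX) — human tumour tissue engrafted into
immunodeficient mice and serially passaged (F0 = patient biopsy, F1, F2,
… = passages) — are a workhorse preclinical model for evaluating
anticancer drugs. The central question for anyone using them is
*fidelity*: how much of the patient tumour's expression program does the
xenograft preserve, where in the PDX lifecycle does expression change
concentrate, and how much does that change perturb expression-based
drug-sensitivity predictions?

`pdxfidelity` is a library (plus a thin CLI) for answering those
questions on gene × sample expression matrices. It is aimed at
computational-biology practitioners running PDX quality control or
meta-analyses across cohorts. Everything runs at desk scale: a
synthetic-data module generates annotated patient/PDX cohorts and
cell-line drug-response panels with planted ground truth, standing in
for repository downloads.

## What it computes

- **Fidelity** — comparison pairs from passage labels (biopsy vs
  xenograft; consecutive xenograft passages), Spearman's rank
  correlation (SRCC) per pair, a low-quality flag at
  `mean − 1.5·sd` of the SRCC distribution, and a Wilcoxon rank-sum
  comparison of the two pair groups (exact enumeration at small *n*,
  ties handled; tie-corrected normal approximation otherwise).
- **Consensus differential expression** — per-pair fold-change screen
  (gene differential when |Δlog2| ≥ log2 1.5, boundary inclusive);
  selection of genes differential in ≥ 3 datasets *and* more than half
  of the patients; leave-one-dataset-out stability; local hypergeometric
  enrichment with Benjamini–Hochberg adjustment and a *robustness
  score* (the fraction of per-pair differential sets in which a term is
  enriched at adjusted p < 0.01); a gene → drug interaction join.
- **Model comparison** — each biopsy against three reference panels
  (own xenografts, cell lines, other same-cancer patients) by maximum
  SRCC, after joint empirical-Bayes batch adjustment (parametric ComBat
  without covariates, re-implemented and oracle-checked against
  Bioconductor `sva::ComBat`).
- **Drug-response simulation** — ridge regression of log-IC50 on
  expression (closed form via SVD; penalty by generalized
  cross-validation), then a sweep multiplying every matrix element by
  Normal(1, sd) fold-change factors over sd ∈ {0, 0.01, …, 0.20} with
  *R* replicates per sd (21 × 500 = 10500 cells by default). Each cell
  reports the median per-line SRCC to the real data ("expression
  change") and the predicted-vs-observed IC50 SRCC divided by its
  unperturbed baseline ("relative SRCC_IC50").
- **Preprocessing** — quantile normalization (reference = row-wise means
  of the column-sorted matrix; ties get the mean of the spanned
  reference values), log2 transform, probe → gene median collapse.

## Worked example

`examples/drug_response_simulation.py` trains the ridge predictor on a
synthetic 200-line × 500-gene panel and runs a 50-replicate sweep:

```
ridge penalty (GCV): λ = 218.3; baseline SRCC_IC50 = 0.9744
1050 simulation cells (21 sd values × 50 reps)
  sd  median_expression_change  mean_relative_srcc_ic50
0.00                    1.0000                   1.0000
0.05                    0.9836                   0.9678
0.10                    0.9394                   0.8865
0.15                    0.8773                   0.7909
0.20                    0.8062                   0.6959
```

Reading: at perturbation sd 0.10 the simulated expression profiles still
rank-correlate 0.94 with the real panel (about the similarity level of a
biopsy and its xenograft), and the predicted drug-sensitivity ranking
retains 89% of its unperturbed agreement with the observed IC50s. At
sd = 0 both quantities are exactly 1 by construction, and both decay
monotonically as the perturbation grows.

The other example scripts each exercise one capability
(`simulate_cohort.py`, `fidelity_screen.py`, `consensus_genes.py`,
`model_comparison.py`) and print a short interpretation with their
numbers. The same operations are reachable from the shell, e.g.:

```bash
pdxfidelity simulate cohort --out cohort/ --seed 2015
pdxfidelity fidelity --matrix cohort/expression.tsv --samples cohort/samples.tsv --out fid/
pdxfidelity de --matrix cohort/expression.tsv --samples cohort/samples.tsv \
    --gmt cohort/gene_sets.gmt --out de/
```

## File formats

Tab-separated UTF-8 throughout: expression matrices (first column
`gene_id`, header = sample ids), sample sheets (`sample_id`,
`patient_id`, `dataset_id`, `passage_label` `F<k>`/`F?`, optional
`cancer_type`), GMT gene sets, two-column gene/drug maps, and
`cell_line`/`log_ic50` response tables. GEO series matrices should be
exported to plain TSV before use — repository retrieval is out of scope.

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
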