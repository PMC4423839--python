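"""Generate a synthetic patient/PDX cohort and inspect its structure.

Builds the default desk-scale cohort (20 patients × {F0, F1, F2} over 5
datasets, 1000 genes with a planted engraftment program) and prints the
bookkeeping counts plus the planted truth a recovery analysis would aim
to find.
"""

from pdxfidelity import CohortConfig, cohort_summary, derive_pairs, generate_cohort

config = CohortConfig(seed=2015)
matrix, annotation, truth = generate_cohort(config)
pairs = derive_pairs(annotation)
summary = cohort_summary(annotation, pairs)

print(f"expression matrix: {matrix.n_genes} genes × {matrix.n_samples} samples (log2)")
for key, value in summary.items():
    print(f"  {key}: {value}")
print(f"planted engraftment genes: {len(truth.engraftment_genes)}")
down = sum(truth.per_gene_shift[g] < 0 for g in truth.engraftment_genes)
print(f"  of which down-shifted in xenografts: {down}")
print(f"outlier samples: {sorted(truth.outlier_samples)}")
print()
print("Counts are the cohort bookkeeping: human-vs-xeno pairs compare the")
print("biopsy with each xenograft; xeno-vs-xeno pairs compare consecutive")
print("passages. The planted gene list is the ground truth that the")
print("consensus differential-expression screen should recover.")
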