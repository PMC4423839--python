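"""Score patient↔xenograft expression fidelity on a synthetic cohort.

Computes the Spearman correlation (SRCC) of every comparison pair, flags
low-quality pairs with the mean − 1.5·sd rule, and tests whether
biopsy-vs-xenograft correlations sit below xenograft-vs-xenograft ones.
"""

from pdxfidelity import (
    HUMAN_VS_XENO,
    XENO_VS_XENO,
    CohortConfig,
    compare_pair_groups,
    derive_pairs,
    flag_outliers,
    generate_cohort,
    outlier_threshold,
    pair_correlations,
)

matrix, annotation, _ = generate_cohort(CohortConfig(seed=2015))
pairs = derive_pairs(annotation)
table = pair_correlations(matrix, pairs)
threshold = outlier_threshold(table["srcc"], k=1.5)
table = flag_outliers(table, threshold)
kept = table.loc[~table["is_outlier"]]

print(f"{len(table)} pairs; outlier threshold = mean − 1.5·sd = {threshold:.4f}")
print(f"flagged outliers: {int(table['is_outlier'].sum())} (excluded below)")
hx = kept.loc[kept["kind"] == HUMAN_VS_XENO, "srcc"]
xx = kept.loc[kept["kind"] == XENO_VS_XENO, "srcc"]
print(f"human-vs-xeno SRCC: median {hx.median():.4f} over {len(hx)} pairs")
print(f"xeno-vs-xeno SRCC:  median {xx.median():.4f} over {len(xx)} pairs")
result = compare_pair_groups(hx, xx)
print(f"rank-sum test ({result.method}): p = {result.p_value:.2e}")
print()
print("The biopsy→xenograft step carries the engraftment expression shift,")
print("so its correlations sit significantly below the passage-to-passage")
print("ones — expression change concentrates at engraftment, not passaging.")
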