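# Methods

This note records the statistical procedures, the synthetic-data model,
the parameter defaults and the deliberate design choices behind
`pdxfidelity`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline treats a PDX study as a set of *datasets* (studies), each
contributing *patients*, each patient contributing a biopsy (F0) and a
chain of xenograft passages (F1, F2, …; F? when the passage is
unrecorded). All analysis happens on log2-scale gene × sample matrices.

**Pairing.** Expression fidelity is a property of sample pairs:
`human_vs_xeno` (F0 against any xenograft of the same patient, F?
included) and `xeno_vs_xeno` (consecutive *available* numeric passages
of the same patient; F? never enters chains). Because real studies match
pairs by hand from sample descriptions, an explicit pair file overrides
derivation. Patients without an F0 contribute no biopsy pairs (warned)
but still contribute passage pairs — cohorts exist whose only patient
has xenografts alone.

**Fidelity.** Each pair is scored by Spearman's rank correlation
(Pearson correlation of average ranks; ties averaged). A constant vector
makes the coefficient undefined and raises an error — it is never
silently 0. Low-quality pairs are flagged when SRCC falls *strictly
below* `mean − k·sd` (k = 1.5; sample sd with n − 1). The threshold is
computed once over all pairs, flags applied, and flagged pairs excluded
from downstream summaries — no iteration. The two pair groups are
compared with a two-sided Wilcoxon rank-sum test: full enumeration of
rank assignments (average ranks, so ties are exact) when the combined
n ≤ 20 or either group has < 2 values, otherwise the tie-corrected
normal approximation. The exact two-sided p is
`min(1, 2·min(P(R ≤ r), P(R ≥ r)))`.

**Differential expression and consensus.** A gene is differential in a
pair when the log2 difference (second sample minus first: xenograft
relative to biopsy, later relative to earlier passage) satisfies
|Δ| ≥ log2(fc), fc = 1.5, boundary inclusive. Consensus selection uses
only biopsy-vs-xenograft pairs: a gene counts for a patient if
differential in ≥ 1 of that patient's pairs (direction ignored for
membership, tallied for reporting), and is selected when hit in
≥ `min_datasets` (default 3) datasets and in strictly more than
`min_patient_fraction` (default 0.5) of the patients contributing ≥ 1
such pair. Both thresholds are configurable; the "any pair per patient"
rule was chosen over "all pairs" because multi-pair patients would
otherwise be penalised for passage-specific noise. Stability is probed
by re-running the selection with each dataset dropped and intersecting
the per-drop lists.

**Enrichment.** Functional context comes from a local catalogue of gene
sets (GMT). Per term, the upper-tail hypergeometric probability
P(overlap ≥ observed) is computed on the analysis universe, with
Benjamini–Hochberg adjustment across the terms tested. This is a
deliberate, self-contained replacement for web-service enrichment tools
(whose EASE-style modified scores are not reproducible offline); the
hypergeometric test is oracle-checked against exhaustive enumeration on
small universes. The *robustness score* of a term is the fraction of
biopsy-vs-xenograft pairs whose own differential gene set yields
adjusted p < 0.01 for that term; pairs with empty differential sets are
excluded from the denominator. It measures whether an enrichment is
supported broadly or driven by one dominant dataset.

**Batch adjustment.** Between-study merging keeps the gene intersection
and applies parametric empirical-Bayes location/scale adjustment
(the ComBat model without covariates): genes standardized against the
batch-size-weighted grand mean and pooled within-batch variance;
per-batch per-gene location and scale estimates shrunk toward batch-wide
moments (normal prior on location, inverse-gamma on scale,
hyperparameters by method of moments) via the standard iterative
posterior solution (relative convergence 1e-4); data reconstructed. A
single batch label short-circuits to the merged matrix unchanged —
there is nothing to adjust, and degenerate hyperpriors are avoided.
Batches of size 1 are rejected (within-batch variance undefined). The
implementation follows the `sva` conventions (sample variance with
n − 1 within batches, pooled variance with 1/N) and one test compares
it against `sva::ComBat` through Rscript on a small fixture (agreement
to < 1e-6).

**Model comparison.** Each biopsy is compared against its own
xenografts, a cell-line panel, and F0 biopsies of *other* patients with
the same cancer type, using the maximum SRCC over each panel. Query and
panels are batch-adjusted jointly before comparison (merge first, then
adjust, matching the merging procedure above); ties in the argmax break
toward the earlier panel column and the winner is reported. Leakage
guards: the own-xenograft panel excludes the biopsy itself; the
other-patient panel excludes all samples of the query patient.

**Drug-response simulation.** A ridge regression predicts log-IC50 from
expression: genes standardized on the training panel (population sd;
constant genes get unit scale and a zero coefficient), closed-form
solution via SVD, intercept = mean response. The penalty λ defaults to
the minimizer of leave-one-out generalized cross-validation
`GCV(λ) = n·RSS / (n − df)²` with `df = Σ s²/(s² + λ) + 1` over a
logspace grid (1e-3 … 1e4, 60 points); a fixed λ is accepted. The
training baseline is the SRCC between fitted and observed IC50; a
constant fit (λ → ∞) makes it undefined and is flagged as NaN with a
warning rather than silently zero. A `standardize=False` mode exposes
the textbook unscaled closed form `β = Σxy/(Σx² + λ)`.

The perturbation multiplies every matrix element by an independent
factor ~ Normal(1, sd), clipped below at 1e-6. Mean 1 makes sd = 0 the
exact identity, anchoring the grid's zero endpoint; factors are drawn
per element (per gene × sample) because shared per-gene factors would
leave per-sample rank order — and hence the expression-change statistic
— degenerate. Multiplication is applied to the stored (log-scale)
values; this is biologically unconventional but matches the simulation
as described, and a linear-scale matrix can be supplied instead via the
scale flag. For each grid cell, seeded from the master seed through
deterministic spawned substreams: the *expression change* is the median
over samples of the per-sample SRCC(simulated, real), and the *relative
SRCC_IC50* is the predicted-vs-observed IC50 SRCC divided by the
unperturbed baseline — exactly 1 at sd = 0. The sweep perturbs and
scores all panel lines (no held-out split), since the unperturbed panel
itself is the reference condition.

## The synthetic-data generator

The generator emulates the structure the analysis assumes of public PDX
expression cohorts, with ground truth for recovery tests. Per gene a
log2 baseline μ_g ~ N(8, 2); per patient an offset ~ N(0, 0.5); the
latent F1 profile adds a signed engraftment shift on a planted gene
fraction; each later passage adds per-gene drift ~ N(0, drift_sd);
every observed sample adds measurement noise ~ N(0, noise_sd); outlier
samples add N(0, outlier_sd) on top. All randomness flows from a single
master seed through named substreams (cohort / panel / gene_sets /
probe_map), so artifacts regenerate independently and byte-identically.

Defaults (the fixed study conditions of the tests and acceptance runs):

| parameter | default | rationale |
|---|---|---|
| patients / datasets | 20 / 5 | smallest cohort where a ≥ 3-dataset, > half-patients consensus rule is meaningfully stressed |
| passages per patient | 2 (F0–F2) | one engraftment step plus one passage step, the minimum to contrast the two |
| genes | 1000 | desk scale; large enough for stable rank correlations |
| engraftment fraction | 5% (50 genes) | a contained program, as stroma/immune signatures are |
| engraftment effect | ≥ 1 log2 unit, 80% down | exceeds the 1.5-fold cutoff so recovery is a property of the meta-analysis, not the screen; the down-skew mirrors xenografts losing human stromal/immune transcripts |
| passage drift sd | 0.1 log2 | an order below the engraftment effect — passages are stable by assumption, and the generator enforces drift < effect |
| sample noise sd | 0.2 log2 | keeps biopsy↔xenograft SRCC near the high-0.9s regime typical of matched arrays |
| outliers | 5% of samples, extra sd 2.0 | rare degraded hybridisations |

The cell-line panel draws expression N(μ_g, 1) and builds log-IC50 as a
sparse linear combination of `n_causal` genes (nonzero coefficients
~ N(0, 1)) plus N(0, noise_sd). Gene identifiers share the cohort's
scheme so the two artifact families can be harmonized when needed.

What the generator does *not* emulate — and hence what green tests do
not show about real data: probe-level intensities and scanner effects
(a separate probe-map fixture exists only to exercise the median
collapse), mouse-read contamination, correlated gene–gene structure
(genes are independent given patient and passage), platform differences
beyond additive/multiplicative batch effects, and real dose–response
biology. Recovery rates on this generator are upper bounds on what the
same procedures achieve on repository data.

## Numerical choices

- Quantile normalization reference = row-wise means of the
  column-sorted matrix; tied values receive the mean of the reference
  values their positions span. Idempotence and identical column
  multisets are exact (1e-12) for tie-free columns; ties replace spanned
  reference values by their mean, so the multiset property holds only up
  to that averaging.
- Outlier rule: strict `<`, so values sitting exactly on the threshold
  are kept. With the summary printed for the real meta-analysis
  (mean 0.91, sd 0.10, k = 1.5) the cutoff is 0.76.
- Fold-change cutoff boundary inclusive (≥ log2 1.5), per-pair.
- Hypergeometric p computed as a survival function — never exactly 0
  for nonempty terms.
- Ridge at λ = 0 with a rank-deficient design returns the minimum-norm
  solution (SVD pseudo-inverse limit).
- Exact rank-sum enumeration caps at combined n = 20
  (C(20,10) ≈ 1.8 × 10⁵ assignments); beyond that the tie-corrected
  normal approximation is used. Test agreement between the two branches
  is checked by full enumeration at 10 vs 10 — full enumeration at
  15 vs 15 (≈ 1.6 × 10⁸ assignments) is not practical, and the
  asymptotic branch is the one actually used there.

## Problem sizes

Tests and the acceptance script run the sweep at 21 sd × 50 replicates
on a 200-line × 500-gene panel and the cohort analyses at the defaults
above — sizes chosen as the package's desk-scale operating point. The
full 21 × 500 grid is the `SimulationGrid` default and runs unchanged;
only its replicate count distinguishes it from the desk runs.

## Known limitations

- The consensus rule treats direction-inconsistent hits as the same
  gene; per-gene up/down tallies are reported but not enforced.
- The drug simulation covers a single response vector (one drug) per
  run and no homogenization against clinical arrays.
- Non-parametric ComBat, covariate-adjusted ComBat, background
  correction, RMA/MAS5, missing-value imputation and repository
  retrieval are out of scope.
- On this generator the *relative* drug-response retention can decay
  faster than expression similarity: predictions depend on
  between-line expression variance (per-gene sd 1), which element-wise
  perturbation of log-scale values (absolute noise ≈ sd × value ≈ 8·sd)
  degrades more than within-profile rank order, whose spread is
  dominated by the μ_g baseline (sd 2). Whether a real panel shows the
  gentler decay depends on gene–gene correlation absorbing element-wise
  noise — structure this generator deliberately omits. The monotone
  decay and the exact sd = 0 anchor are the properties the package
  asserts.
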