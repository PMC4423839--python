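"""Map expression perturbation to drug-sensitivity prediction change.

Trains a ridge model (log-IC50 from expression) on a synthetic cell-line
panel, then perturbs the expression with element-wise Normal(1, sd)
fold-change factors over an sd grid. For each sd it reports the median
per-line SRCC to the real data (expression change) and the predicted-vs-
observed IC50 SRCC divided by its unperturbed baseline (drug-response
retention).
"""

from pdxfidelity import SimulationGrid, generate_cellline_panel, run_sweep, summarize_sweep, train_ridge

expr, ic50, _ = generate_cellline_panel(
    n_lines=200, n_genes=500, n_causal=20, noise_sd=0.5, seed=7
)
model, baseline = train_ridge(expr, ic50)
print(f"ridge penalty (GCV): λ = {model.lam:.1f}; baseline SRCC_IC50 = {baseline:.4f}")

grid = SimulationGrid(reps_per_sd=50, seed=2015)  # desk scale; default is 500 reps
table = run_sweep(model, expr, ic50, grid)
summary = summarize_sweep(table)
print(f"{len(table)} simulation cells ({len(grid.sd_values)} sd values × {grid.reps_per_sd} reps)")
print(
    summary[["sd", "median_expression_change", "mean_relative_srcc_ic50"]]
    .iloc[::5]
    .round(4)
    .to_string(index=False)
)
print()
print("As the perturbation sd grows, expression drifts from the real panel")
print("(median SRCC falls) and the predicted drug-sensitivity ranking decays")
print("with it; at sd = 0 both are exactly 1 by construction.")
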