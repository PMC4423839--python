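"""Shared fixtures: frozen-seed synthetic cohort and cell-line panel.

The cohort seed (2015) and the panel parameters (200 lines × 500 genes,
20 causal genes, noise sd 0.5, seed 7) are fixed study conditions, not
tunables; expensive artifacts are session-scoped so fidelity, consensus
and simulation tests share them.
"""

from __future__ import annotations

import warnings

import pytest

from pdxfidelity import de_meta, drug_sim, fidelity
from pdxfidelity.synthetic_data import (
    CohortConfig,
    generate_cellline_panel,
    generate_cohort,
    generate_gene_sets,
)

COHORT_SEED = 2015
PANEL_ARGS = dict(n_lines=200, n_genes=500, n_causal=20, noise_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def cohort():
    """(matrix, annotation, truth) for the default frozen-seed cohort."""
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_pairs(cohort):
    matrix, ann, _ = cohort
    return fidelity.derive_pairs(ann)


@pytest.fixture(scope="session")
def cohort_correlations(cohort, cohort_pairs):
    matrix, _, _ = cohort
    return fidelity.pair_correlations(matrix, cohort_pairs)

@pytest.fixture(scope="session")
def cohort_de(cohort, cohort_pairs):
    matrix, _, _ = cohort
    return [de_meta.differential_genes(matrix, p) for p in cohort_pairs]


@pytest.fixture(scope="session")
def cohort_gene_sets(cohort):
    _, _, truth = cohort
    return generate_gene_sets(
        truth,
        n_decoy_terms=20,
        term_size=len(truth.engraftment_genes),
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def panel():
    """(expression, ic50, truth) for the frozen cell-line panel."""
    return generate_cellline_panel(**PANEL_ARGS)


@pytest.fixture(scope="session")
def ridge_fit(panel):
    expr, ic50, _ = panel
    return drug_sim.train_ridge(expr, ic50)


@pytest.fixture(scope="session")
def desk_sweep(panel, ridge_fit):
    """21 sd values × 50 replicates on the frozen panel (desk scale)."""
    expr, ic50, _ = panel
    model, _ = ridge_fit
    grid = drug_sim.SimulationGrid(reps_per_sd=50, seed=COHORT_SEED)
    return grid, drug_sim.run_sweep(model, expr, ic50, grid)
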