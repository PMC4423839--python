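"""Fold-change perturbation simulation of drug-response prediction.

A ridge regression trained on a cell-line panel (expression → log IC50)
defines a drug-sensitivity predictor. Expression is then perturbed by
element-wise multiplicative fold changes drawn from Normal(1, sd) over a
grid of sd values; for each perturbed dataset the median per-cell-line
Spearman correlation with the real expression measures the expression
change, and the Spearman correlation between predicted and observed IC50
("SRCC_IC50"), divided by its training-data baseline, measures how much
of the drug-response ranking survives the perturbation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConstantInputError, ValidationError
from .expression_io import ExpressionMatrix
from .fidelity import spearman_rcc

__all__ = [
    "RidgeModel",
    "SimulationGrid",
    "train_ridge",
    "perturb",
    "expression_change",
    "run_sweep",
    "summarize_sweep",
]


@dataclass
class RidgeModel:
    """Closed-form ridge predictor with its training standardization."""

    coef: pd.Series  # per gene, on the standardized scale
    intercept: float
    gene_mean: pd.Series
    gene_sd: pd.Series
    lam: float

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        missing = [g for g in self.coef.index if g not in expr.data.index]
        if missing:
            raise ValidationError(f"model genes missing from matrix: {missing[:5]}")
        X = expr.data.loc[self.coef.index].to_numpy(dtype=float).T  # samples × genes
        Z = (X - self.gene_mean.to_numpy()) / self.gene_sd.to_numpy()
        return pd.Series(
            self.intercept + Z @ self.coef.to_numpy(), index=expr.sample_ids
        )


@dataclass
class SimulationGrid:
    """Perturbation grid: sd values × replicates, seeded.

    The default grid (sd 0.00–0.20 in steps of 0.01, 500 replicates per
    sd) yields 21 × 500 = 10500 simulation cells.
    """

    sd_values: tuple = tuple(np.round(np.arange(0.0, 0.2001, 0.01), 10))
    reps_per_sd: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.sd_values):
            raise ValidationError("grid sd values must be ≥ 0")
        if self.reps_per_sd < 1:
            raise ValidationError("need ≥ 1 replicate per sd")

    @property
    def size(self) -> int:
        return len(self.sd_values) * self.reps_per_sd


def train_ridge(
    expr: ExpressionMatrix,
    ic50: pd.Series,
    lam: float | None = None,
    standardize: bool = True,
    lam_grid=None,
) -> tuple[RidgeModel, float]:
    """Fit ridge regression of log-IC50 on expression; return the model
    and the training baseline SRCC_IC50.

    Genes are standardized on the training panel (constant genes get unit
    scale and contribute nothing). With ``lam=None`` the penalty is
    chosen by generalized cross-validation over ``lam_grid``
    (default logspace 1e-3…1e4). The baseline is the Spearman correlation
    between fitted and observed IC50; if the fit is constant (λ → ∞) the
    baseline is returned as NaN with a warning.
    """
    samples = expr.sample_ids
    missing = [s for s in samples if s not in ic50.index]
    if missing:
        raise ValidationError(f"IC50 missing for samples: {missing[:5]}")
    y = ic50.loc[samples].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValidationError("need at least 3 training samples")
    if np.ptp(y) == 0:
        raise ConstantInputError("constant IC50 — rank correlation undefined")
    if lam is not None and lam < 0:
        raise ValidationError("ridge penalty must be ≥ 0")

    X = expr.data.to_numpy(dtype=float).T  # samples × genes
    mean = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    Z = (X - mean) / sd
    ybar = float(y.mean())
    yc = y - ybar

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uty = U.T @ yc

    def _coef(lam_value: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(s > 0, s / (s**2 + lam_value), 0.0)
        return Vt.T @ (shrink * uty)

    if lam is None:
        if lam_grid is None:
            lam_grid = np.logspace(-3, 4, 60)
        best = None
        n = len(y)
        for lv in lam_grid:
            filt = s**2 / (s**2 + lv)
            fitted_c = U @ (filt * uty)
            df = float(filt.sum()) + 1  # +1 for the intercept
            gcv = n * float(((yc - fitted_c) ** 2).sum()) / (n - df) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lv)
        lam = float(best[1])

    beta = _coef(lam)
    fitted = ybar + Z @ beta
    model = RidgeModel(
        coef=pd.Series(beta, index=expr.gene_ids),
        intercept=ybar,
        gene_mean=pd.Series(mean, index=expr.gene_ids),
        gene_sd=pd.Series(sd, index=expr.gene_ids),
        lam=float(lam),
    )
    try:
        baseline = spearman_rcc(fitted, y)
    except ConstantInputError:
        warnings.warn(
            "fitted values constant (penalty too large?) — baseline SRCC undefined",
            stacklevel=2,
        )
        baseline = float("nan")
    return model, baseline


def perturb(expr: ExpressionMatrix, sd: float, rng) -> ExpressionMatrix:
    """Multiply every matrix element by an independent Normal(1, sd) factor.

    Factors are clipped below at 1e-6 (a fold change cannot be ≤ 0).
    ``rng`` is a numpy Generator or an integer seed. sd = 0 reproduces
    the input exactly.
    """
    if sd < 0:
        raise ValidationError("perturbation sd must be ≥ 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    factors = rng.normal(loc=1.0, scale=sd, size=expr.data.shape)
    factors = np.clip(factors, 1e-6, None)
    return ExpressionMatrix(
        pd.DataFrame(
            expr.data.to_numpy() * factors, index=expr.data.index, columns=expr.data.columns
        ),
        scale=expr.scale,
    )


def _column_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman correlation of each column of A with the same column of B."""
    ra = rankdata(A, axis=0)
    rb = rankdata(B, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    if (denom == 0).any():
        raise ConstantInputError("constant column — Spearman undefined")
    return (ra * rb).sum(axis=0) / denom


def expression_change(real: ExpressionMatrix, sim: ExpressionMatrix) -> float:
    """Median over samples of the per-sample SRCC(simulated, real)."""
    if real.data.shape != sim.data.shape:
        raise ValidationError("real and simulated matrices differ in shape")
    srccs = _column_spearman(sim.data.to_numpy(), real.data.to_numpy())
    return float(np.median(srccs))


def run_sweep(
    model: RidgeModel,
    expr: ExpressionMatrix,
    ic50: pd.Series,
    grid: SimulationGrid,
) -> pd.DataFrame:
    """Full perturbation sweep over the grid.

    For each (sd, replicate): perturb the panel, measure the expression
    change, predict IC50 and correlate with the observed values, and
    normalise by the unperturbed baseline. Per-cell seeds are spawned
    deterministically from the grid's master seed. Returns one row per
    cell: sd, rep, expression_change, srcc_ic50, relative_srcc_ic50.
    """
    y = ic50.loc[expr.sample_ids].to_numpy(dtype=float)
    baseline = spearman_rcc(model.predict(expr).to_numpy(), y)
    if baseline == 0:
        raise ValidationError("baseline SRCC_IC50 is zero — relative scores undefined")
    children = np.random.SeedSequence(grid.seed).spawn(grid.size)
    rows = []
    cell = 0
    for sd in grid.sd_values:
        for rep in range(grid.reps_per_sd):
            rng = np.random.default_rng(children[cell])
            cell += 1
            sim = perturb(expr, sd, rng)
            change = expression_change(expr, sim)
            srcc_ic50 = spearman_rcc(model.predict(sim).to_numpy(), y)
            rows.append((sd, rep, change, srcc_ic50, srcc_ic50 / baseline))
    out = pd.DataFrame(
        rows,
        columns=["sd", "rep", "expression_change", "srcc_ic50", "relative_srcc_ic50"],
    )
    out.attrs["baseline_srcc_ic50"] = float(baseline)
    return out


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sd means/medians of expression change and relative SRCC_IC50."""
    grouped = table.groupby("sd", sort=True)
    out = grouped.agg(
        mean_expression_change=("expression_change", "mean"),
        median_expression_change=("expression_change", "median"),
        mean_relative_srcc_ic50=("relative_srcc_ic50", "mean"),
        median_relative_srcc_ic50=("relative_srcc_ic50", "median"),
        n=("rep", "size"),
    ).reset_index()
    return out
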