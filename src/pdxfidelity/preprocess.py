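"""Normalisation, transformation, probe collapse and batch adjustment.

The preprocessing contract for microarray-style matrices is: quantile
normalize on the linear scale, log2-transform, collapse probes to genes
by the per-sample median, and — when merging studies — restrict to the
shared gene universe and remove between-study batch effects with a
parametric empirical-Bayes location/scale adjustment (the ComBat model,
without covariates).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .expression_io import LINEAR, LOG2, ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "log_transform",
    "collapse_probes",
    "merge_and_batch_adjust",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    matrix; each column's values are replaced by the reference value at
    their within-column rank, so within-sample rank order (and hence any
    Spearman correlation) is untouched. Tied values receive the mean of
    the reference values their positions span — the convention of the
    dominant microarray implementations.
    """
    X = m.data.to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValidationError("quantile normalization needs ≥1 sample")
    if not np.isfinite(X).all():
        raise ValidationError("missing values are not supported (imputation out of scope)")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        col_sorted = col[order]
        assigned = reference.copy()
        # average the reference over each run of tied input values
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        sums = np.add.reduceat(reference, starts)
        lengths = np.diff(np.concatenate((starts, [len(col)])))
        means = sums / lengths
        assigned = np.repeat(means, lengths)
        out[order, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale=m.scale,
        probe_level=m.probe_level,
    )


def log_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(value + offset); refuses already-log data (double-log guard)."""
    if m.scale == LOG2:
        raise ValidationError("matrix is already log2 scale — refusing to log again")
    shifted = m.data.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        rows, cols = np.nonzero(shifted <= 0)
        cells = [
            (m.data.index[r], m.data.columns[c]) for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValidationError(
            f"nonpositive value + offset at {len(rows)} cells, e.g. {cells}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(shifted), index=m.data.index, columns=m.data.columns),
        scale=LOG2,
        probe_level=m.probe_level,
    )


def collapse_probes(m: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene via the per-sample median.

    Gene order in the result is first-appearance order of the probes.
    Every probe row must be present in the map.
    """
    unmapped = [p for p in m.data.index if p not in probe_map]
    if unmapped:
        raise ValidationError(f"probes missing from probe map: {unmapped[:10]}")
    genes = [probe_map[p] for p in m.data.index]
    collapsed = m.data.groupby(genes, sort=False).median()
    return ExpressionMatrix(collapsed, scale=m.scale, probe_level=False)


# ---------------------------------------------------------------------------
# between-study merge + empirical-Bayes batch adjustment


def merge_and_batch_adjust(
    matrices: Sequence[ExpressionMatrix], batches: Mapping[str, str]
) -> ExpressionMatrix:
    """Merge studies on their shared genes and remove batch effects.

    Rows are restricted to the gene intersection (order of the first
    matrix); columns are concatenated; then a parametric location/scale
    empirical-Bayes adjustment (ComBat without covariates) equalises
    per-batch gene means and variances up to shrinkage. A single batch
    label across all samples is a no-op beyond the gene intersection.
    """
    if len(matrices) < 1:
        raise ValidationError("need at least one matrix")
    scale = matrices[0].scale
    if any(m.scale != scale for m in matrices):
        raise ValidationError("matrices mix linear and log2 scales")
    shared = [g for g in matrices[0].gene_ids if all(g in m.data.index for m in matrices[1:])]
    if not shared:
        raise ValidationError("gene-id intersection across matrices is empty")
    merged = pd.concat([m.data.loc[shared] for m in matrices], axis=1)
    if merged.columns.has_duplicates:
        dups = merged.columns[merged.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids across matrices: {dups}")
    missing = [s for s in merged.columns if s not in batches]
    if missing:
        raise ValidationError(f"samples without batch labels: {missing[:10]}")
    labels = pd.Series([batches[s] for s in merged.columns], index=merged.columns)
    if labels.nunique() == 1:
        return ExpressionMatrix(merged, scale=scale)
    adjusted = _combat(merged.to_numpy(dtype=float), labels.to_numpy())
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=merged.index, columns=merged.columns), scale=scale
    )


def _combat(X: np.ndarray, labels: np.ndarray, conv: float = 1e-4) -> np.ndarray:
    """Parametric ComBat without covariates (genes × samples).

    Standardize genes against the batch-size-weighted grand mean and the
    pooled within-batch variance, estimate per-batch per-gene location
    and scale, shrink them toward batch-wide moments (normal prior on
    location, inverse-gamma on scale, hyperparameters by method of
    moments) with the usual iterative posterior solution, and
    reconstruct.
    """
    n_genes, n_samples = X.shape
    batch_ids = list(dict.fromkeys(labels))
    idx = {b: np.flatnonzero(labels == b) for b in batch_ids}
    sizes = {b: len(idx[b]) for b in batch_ids}
    for b, n in sizes.items():
        if n < 2:
            raise ValidationError(f"batch {b!r} has a single sample (variance undefined)")

    batch_means = {b: X[:, idx[b]].mean(axis=1) for b in batch_ids}
    grand_mean = np.zeros(n_genes)
    for b in batch_ids:
        grand_mean += sizes[b] / n_samples * batch_means[b]
    resid = X - np.column_stack([batch_means[labels[j]] for j in range(n_samples)])
    pooled_var = (resid**2).sum(axis=1) / n_samples
    if (pooled_var <= 0).any():
        raise ValidationError("genes with zero pooled variance cannot be adjusted")
    pooled_sd = np.sqrt(pooled_var)

    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]

    out = np.empty_like(Z)
    for b in batch_ids:
        Zb = Z[:, idx[b]]
        n_b = sizes[b]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m_d = delta_hat.mean()
        s2_d = delta_hat.var(ddof=1)
        if s2_d < 1e-12:
            # degenerate scale prior (all scale estimates identical):
            # nothing to shrink
            gamma_star = (
                np.full(n_genes, gamma_bar)
                if tau2 < 1e-12
                else (n_b * tau2 * gamma_hat + delta_hat * gamma_bar)
                / (n_b * tau2 + delta_hat)
            )
            delta_star = delta_hat.copy()
        else:
            a_prior = (2 * s2_d + m_d**2) / s2_d
            b_prior = (m_d * s2_d + m_d**3) / s2_d
            gamma_star, delta_star = _iterative_eb(
                Zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior, conv
            )
        out[:, idx[b]] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    return out * pooled_sd[:, None] + grand_mean[:, None]


def _iterative_eb(Zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior, conv):
    """Iterative posterior-mode solution for the EB batch parameters."""
    n_b = Zb.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(500):
        g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2 + a_prior - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-30)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-30)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old
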