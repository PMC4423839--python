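"""Patient↔xenograft expression-fidelity statistics.

Given an annotated expression cohort, this module derives comparison
pairs (patient biopsy vs xenograft, and xenograft vs consecutive-passage
xenograft), scores each pair with Spearman's rank correlation (SRCC),
flags low-quality pairs with the mean − 1.5·sd rule, and tests whether
the biopsy-vs-xenograft correlations sit below the xenograft-vs-xenograft
ones with a Wilcoxon rank-sum test (exact at small n, ties included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, ValidationError
from .expression_io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "HUMAN_VS_XENO",
    "XENO_VS_XENO",
    "Pair",
    "derive_pairs",
    "read_pairs",
    "write_pairs",
    "spearman_rcc",
    "pair_correlations",
    "correlation_summary",
    "outlier_threshold",
    "flag_outliers",
    "RankSumResult",
    "compare_pair_groups",
    "cohort_summary",
]

HUMAN_VS_XENO = "human_vs_xeno"
XENO_VS_XENO = "xeno_vs_xeno"


@dataclass(frozen=True)
class Pair:
    """One comparison: ``sample_a`` is the human biopsy (or earlier
    passage), ``sample_b`` the xenograft (or later passage)."""

    sample_a: str
    sample_b: str
    kind: str
    patient_id: str
    dataset_id: str

    def __post_init__(self) -> None:
        if self.kind not in (HUMAN_VS_XENO, XENO_VS_XENO):
            raise ValidationError(f"unknown pair kind {self.kind!r}")
        if self.sample_a == self.sample_b:
            raise ValidationError(f"pair of a sample with itself: {self.sample_a!r}")


def derive_pairs(ann: SampleAnnotation, explicit_pairs: list[Pair] | None = None) -> list[Pair]:
    """Build comparison pairs from passage labels.

    Default policy: each patient's F0 biopsy is paired with every
    xenograft sample of that patient (including F? unknowns), and
    consecutive *available* numeric passages are paired with each other.
    Unknown-passage samples (F?) pair only with F0. An explicit pair
    list, when supplied, overrides derivation entirely (the faithful path
    when pairs were matched by hand) after validation against the
    annotation.

    Patients without an F0 biopsy contribute no biopsy-vs-xenograft pairs
    (a warning is emitted) but still contribute consecutive-passage
    xenograft pairs.
    """
    if explicit_pairs is not None:
        for p in explicit_pairs:
            for s in (p.sample_a, p.sample_b):
                if s not in ann.table.index:
                    raise ValidationError(f"pair sample {s!r} not in sample sheet")
            if (
                ann.table.loc[p.sample_a, "patient_id"]
                != ann.table.loc[p.sample_b, "patient_id"]
            ):
                raise ValidationError(
                    f"pair ({p.sample_a}, {p.sample_b}) spans two patients"
                )
        return list(explicit_pairs)

    pairs: list[Pair] = []
    for patient in ann.patients():
        samples = ann.samples_of_patient(patient)
        f0s = [s for s in samples if ann.is_biopsy(s)]
        xenos = [s for s in samples if not ann.is_biopsy(s)]
        numeric = [s for s in xenos if ann.passage_number(s) is not None]
        unknown = [s for s in xenos if ann.passage_number(s) is None]
        dataset = str(ann.table.loc[samples[0], "dataset_id"])
        if not f0s and xenos:
            warnings.warn(
                f"patient {patient!r} has no F0 biopsy; "
                "skipping human-vs-xenograft pairing",
                stacklevel=2,
            )
        for f0 in f0s:
            for x in numeric + unknown:
                pairs.append(Pair(f0, x, HUMAN_VS_XENO, patient, dataset))
        levels = sorted({ann.passage_number(s) for s in numeric})
        by_level = {
            lvl: [s for s in numeric if ann.passage_number(s) == lvl] for lvl in levels
        }
        for lo, hi in zip(levels, levels[1:]):
            for a in by_level[lo]:
                for b in by_level[hi]:
                    pairs.append(Pair(a, b, XENO_VS_XENO, patient, dataset))
    return pairs


def read_pairs(path) -> list[Pair]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = ["sample_a", "sample_b", "kind", "patient_id", "dataset_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"pair file missing columns {missing}")
    return [Pair(*row) for row in df[required].itertuples(index=False)]


def write_pairs(pairs: list[Pair], path) -> None:
    pd.DataFrame(
        [(p.sample_a, p.sample_b, p.kind, p.patient_id, p.dataset_id) for p in pairs],
        columns=["sample_a", "sample_b", "kind", "patient_id", "dataset_id"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman_rcc(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Raises :class:`ConstantInputError` when either vector is constant —
    the coefficient is undefined there and must never silently become 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def pair_correlations(m: ExpressionMatrix, pairs: list[Pair]) -> pd.DataFrame:
    """SRCC of the shared gene vector for every pair.

    Returns one row per pair with the pair metadata, the correlation and
    an (initially False) outlier flag; see :func:`flag_outliers`.
    """
    rows = []
    for p in pairs:
        for s in (p.sample_a, p.sample_b):
            if s not in m.data.columns:
                raise ValidationError(f"pair sample {s!r} missing from matrix")
        srcc = spearman_rcc(m.data[p.sample_a].to_numpy(), m.data[p.sample_b].to_numpy())
        rows.append((p.sample_a, p.sample_b, p.kind, p.patient_id, p.dataset_id, srcc))
    table = pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "kind", "patient_id", "dataset_id", "srcc"],
    )
    table["is_outlier"] = False
    return table


def correlation_summary(table: pd.DataFrame, exclude_outliers: bool = False) -> dict:
    """Mean/median/sd of SRCC overall and per pair kind."""
    data = table.loc[~table["is_outlier"]] if exclude_outliers else table
    def _stats(values: pd.Series) -> dict:
        if len(values) == 0:
            return {"n": 0, "mean": None, "median": None, "sd": None, "defined": False}
        return {
            "n": int(len(values)),
            "mean": float(values.mean()),
            "median": float(values.median()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else None,
            "defined": True,
        }
    out = {"all": _stats(data["srcc"])}
    for kind in (HUMAN_VS_XENO, XENO_VS_XENO):
        out[kind] = _stats(data.loc[data["kind"] == kind, "srcc"])
    return out


def outlier_threshold(srccs, k: float = 1.5) -> float:
    """Low-quality cutoff: mean − k·sd (sample sd, n−1 denominator)."""
    values = np.asarray(srccs, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 correlations for a threshold")
    return float(values.mean() - k * values.std(ddof=1))


def flag_outliers(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Flag pairs with SRCC strictly below the threshold."""
    out = table.copy()
    out["is_outlier"] = out["srcc"] < threshold
    return out


# ---------------------------------------------------------------------------
# group comparison (Wilcoxon rank-sum)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann–Whitney U for the first group
    p_value: float
    method: str  # "exact" or "normal"


def compare_pair_groups(srccs_a, srccs_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two SRCC groups.

    Exact null enumeration (ties handled via average ranks) when the
    combined sample size is ≤ 20 or either group has < 2 values; the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(srccs_a, dtype=float)
    b = np.asarray(srccs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if a.size < 2 or b.size < 2:
        warnings.warn(
            "group with < 2 values: normal approximation refused, using exact test",
            stacklevel=2,
        )
        return _exact_rank_sum(a, b)
    if a.size + b.size <= 20:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "normal")


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> RankSumResult:
    """Enumerate all rank assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(a)
    observed = ranks[:n1].sum()
    idx = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp
    ).reshape(comb(n, n1), n1)
    sums = ranks[idx].sum(axis=1)
    eps = 1e-9
    p_low = np.mean(sums <= observed + eps)
    p_high = np.mean(sums >= observed - eps)
    p = min(1.0, 2.0 * min(p_low, p_high))
    u = observed - n1 * (n1 + 1) / 2
    return RankSumResult(float(u), float(p), "exact")


# ---------------------------------------------------------------------------
# cohort bookkeeping


def cohort_summary(ann: SampleAnnotation, pairs: list[Pair]) -> dict:
    """Patient/sample/pair counts for a cohort (inventory bookkeeping)."""
    kinds = pd.Series([p.kind for p in pairs])
    n_hx = int((kinds == HUMAN_VS_XENO).sum()) if len(kinds) else 0
    n_xx = int((kinds == XENO_VS_XENO).sum()) if len(kinds) else 0
    return {
        "n_patients": int(ann.table["patient_id"].nunique()),
        "n_samples": int(len(ann.table)),
        "n_datasets": int(ann.table["dataset_id"].nunique()),
        "n_human_vs_xeno_pairs": n_hx,
        "n_xeno_vs_xeno_pairs": n_xx,
        "n_comparisons": n_hx + n_xx,
    }
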