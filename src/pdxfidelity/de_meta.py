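"""Cross-dataset differential-expression meta-analysis.

Per comparison pair, genes are called differential by a fold-change
cutoff (|Δlog2| ≥ log2 1.5 by default). Consensus genes are those
differential in at least ``min_datasets`` datasets AND in strictly more
than ``min_patient_fraction`` of the patients contributing
biopsy-vs-xenograft pairs; direction is ignored for membership but
tallied. Stability is probed by leave-one-dataset-out re-selection.
Functional context comes from a local hypergeometric test over supplied
gene sets with Benjamini–Hochberg adjustment, plus a robustness score:
the fraction of per-pair differential sets in which a term is enriched
at adjusted p < alpha. A simple gene→drug join surfaces interacting
drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression_io import LOG2, AnnotationSet, ExpressionMatrix
from .fidelity import HUMAN_VS_XENO, Pair

__all__ = [
    "DifferentialResult",
    "ConsensusGeneSet",
    "differential_genes",
    "consensus_genes",
    "leave_one_out",
    "enrich",
    "robustness_score",
    "count_interacting_drugs",
]


@dataclass(frozen=True)
class DifferentialResult:
    """Up/down gene calls for one pair.

    Direction is the second sample relative to the first: xenograft
    relative to human biopsy for human-vs-xeno pairs, later relative to
    earlier passage otherwise.
    """

    pair: Pair
    up_genes: frozenset
    down_genes: frozenset

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValidationError("a gene cannot be both up and down in one pair")

    @property
    def all_genes(self) -> frozenset:
        return self.up_genes | self.down_genes


@dataclass
class ConsensusGeneSet:
    """Consensus selection plus the thresholds it was made under."""

    genes: list[str]
    stats: pd.DataFrame  # per selected gene: dataset/patient tallies
    min_datasets: int
    min_patient_fraction: float
    n_patients_total: int
    n_datasets_total: int = 0
    extra: dict = field(default_factory=dict)


def differential_genes(
    m: ExpressionMatrix, pair: Pair, fc_cutoff: float = 1.5
) -> DifferentialResult:
    """Fold-change screen for one pair on a log2 matrix.

    up: log2(b) − log2(a) ≥ log2(fc_cutoff); down: ≤ −log2(fc_cutoff);
    the boundary is inclusive on both sides.
    """
    if m.scale != LOG2:
        raise ValidationError("matrix is linear scale — log-transform before screening")
    if fc_cutoff <= 1:
        raise ValidationError("fold-change cutoff must exceed 1")
    for s in (pair.sample_a, pair.sample_b):
        if s not in m.data.columns:
            raise ValidationError(f"pair sample {s!r} missing from matrix")
    delta = m.data[pair.sample_b] - m.data[pair.sample_a]
    cut = math.log2(fc_cutoff)
    up = frozenset(delta.index[delta >= cut])
    down = frozenset(delta.index[delta <= -cut])
    return DifferentialResult(pair, up, down)


def consensus_genes(
    results: list[DifferentialResult],
    min_datasets: int = 3,
    min_patient_fraction: float = 0.5,
) -> ConsensusGeneSet:
    """Select genes recurrently differential across datasets and patients.

    Only human-vs-xenograft pairs enter the tallies. A gene counts for a
    patient if it is differential (either direction) in ≥1 of that
    patient's pairs; the patient-fraction denominator is the number of
    patients contributing ≥1 human-vs-xenograft pair. Selection requires
    ≥ min_datasets datasets hit and patient_fraction strictly greater
    than min_patient_fraction.
    """
    hx = [r for r in results if r.pair.kind == HUMAN_VS_XENO]
    if not hx:
        raise ValidationError("no human-vs-xenograft pairs in results")
    datasets = sorted({r.pair.dataset_id for r in hx})
    if len(datasets) < min_datasets:
        raise ValidationError(
            f"results cover {len(datasets)} datasets; need ≥ {min_datasets}"
        )
    patients = sorted({r.pair.patient_id for r in hx})
    n_patients = len(patients)

    gene_datasets: dict[str, set] = {}
    gene_patients: dict[str, set] = {}
    gene_up_pairs: dict[str, int] = {}
    gene_down_pairs: dict[str, int] = {}
    for r in hx:
        for g in r.all_genes:
            gene_datasets.setdefault(g, set()).add(r.pair.dataset_id)
            gene_patients.setdefault(g, set()).add(r.pair.patient_id)
        for g in r.up_genes:
            gene_up_pairs[g] = gene_up_pairs.get(g, 0) + 1
        for g in r.down_genes:
            gene_down_pairs[g] = gene_down_pairs.get(g, 0) + 1

    rows = []
    for g in gene_datasets:
        n_ds = len(gene_datasets[g])
        n_pat = len(gene_patients[g])
        frac = n_pat / n_patients
        if n_ds >= min_datasets and frac > min_patient_fraction:
            rows.append(
                (
                    g,
                    n_ds,
                    n_pat,
                    frac,
                    gene_up_pairs.get(g, 0),
                    gene_down_pairs.get(g, 0),
                )
            )
    stats = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_datasets_hit",
            "n_patients_hit",
            "patient_fraction",
            "n_up_pairs",
            "n_down_pairs",
        ],
    )
    stats = stats.sort_values(
        ["n_datasets_hit", "patient_fraction", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ConsensusGeneSet(
        genes=list(stats["gene_id"]),
        stats=stats,
        min_datasets=min_datasets,
        min_patient_fraction=min_patient_fraction,
        n_patients_total=n_patients,
        n_datasets_total=len(datasets),
    )


def leave_one_out(
    results: list[DifferentialResult],
    min_datasets: int = 3,
    min_patient_fraction: float = 0.5,
) -> dict:
    """Re-select consensus genes with each dataset dropped in turn.

    Returns ``{"per_drop": {dataset: [genes]}, "intersection": [genes]}``
    where the intersection is over all drops — genes stable no matter
    which dataset is removed.
    """
    datasets = sorted(
        {r.pair.dataset_id for r in results if r.pair.kind == HUMAN_VS_XENO}
    )
    if len(datasets) < 3:
        raise ValidationError("leave-one-out needs ≥ 3 datasets")
    per_drop = {}
    for d in datasets:
        kept = [r for r in results if r.pair.dataset_id != d]
        per_drop[d] = consensus_genes(kept, min_datasets, min_patient_fraction).genes
    surviving = set(per_drop[datasets[0]])
    for d in datasets[1:]:
        surviving &= set(per_drop[d])
    return {"per_drop": per_drop, "intersection": sorted(surviving)}


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    query, universe, ann: AnnotationSet, alpha: float = 0.01
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH adjustment.

    For each term with ≥1 gene in the universe: p = P(overlap ≥ observed)
    drawing |query| genes from the universe. Benjamini–Hochberg adjusts
    across the terms tested. Returns one row per term tested.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query:
        raise ValidationError("empty query gene set")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for term in ann.terms.values():
        term_genes = term.genes & universe
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term.term_id, term.description, K, k, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "description", "n_term", "overlap", "p"]
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out


def robustness_score(
    term_id: str,
    results: list[DifferentialResult],
    universe,
    ann: AnnotationSet,
    alpha: float = 0.01,
) -> float:
    """Fraction of per-pair differential sets in which a term is enriched.

    Evaluates the human-vs-xenograft pairs with nonempty differential
    sets; each pair's set is enriched independently and the score is the
    fraction with BH-adjusted p < alpha for the requested term.
    """
    if term_id not in ann:
        raise ValidationError(f"term {term_id!r} absent from annotation")
    evaluated = 0
    hits = 0
    for r in results:
        if r.pair.kind != HUMAN_VS_XENO or not r.all_genes:
            continue
        evaluated += 1
        table = enrich(r.all_genes, universe, ann, alpha=alpha)
        row = table.loc[table["term_id"] == term_id]
        if len(row) and bool(row["significant"].iloc[0]):
            hits += 1
    if evaluated == 0:
        raise ValidationError("no human-vs-xenograft pair with a nonempty differential set")
    return hits / evaluated


def count_interacting_drugs(genes, drug_map: dict) -> tuple[dict, dict]:
    """Join a gene list against a gene→drug map.

    Returns (per_gene, per_drug): per query gene the number of
    interacting drugs (0 if none), and per drug the number of query
    genes it interacts with (drugs with no query gene are omitted).
    """
    genes = list(dict.fromkeys(genes))
    per_gene = {g: len(drug_map.get(g, ())) for g in genes}
    per_drug: dict[str, int] = {}
    for g in genes:
        for d in drug_map.get(g, ()):
            per_drug[d] = per_drug.get(d, 0) + 1
    return per_gene, per_drug
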