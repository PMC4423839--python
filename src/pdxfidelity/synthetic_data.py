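"""Synthetic cohorts and drug-response panels with known ground truth.

The generator emulates the statistical structure the analysis assumes of
public PDX expression datasets: log2-scale gene baselines, per-patient
offsets, an engraftment-step expression shift concentrated in a planted
"stroma/immune" gene program (mostly down-shifted — xenografts lose
human stromal/immune transcripts), small per-passage drift, independent
per-sample measurement noise, and occasional noisy outlier samples. The
cell-line panel emulates an expression + log-IC50 resource where
sensitivity is a sparse linear function of expression plus noise.

Ground-truth objects record the planted genes, their shifts, the outlier
samples and the causal IC50 coefficients so recovery tests can score the
pipeline.

All randomness flows from a single master seed through named substreams
("cohort", "panel", "gene_sets", "probe_map") so artifacts can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ValidationError
from .expression_io import (
    AnnotationSet,
    ExpressionMatrix,
    GeneSetTerm,
    SampleAnnotation,
)

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "PanelTruth",
    "generate_cohort",
    "generate_cellline_panel",
    "generate_gene_sets",
    "generate_probe_map",
    "expand_to_probes",
]

CANCER_TYPES = (
    "colorectal",
    "hepatocellular",
    "pancreatic",
    "breast",
    "lung",
    "head_and_neck",
)

PLANTED_TERM_ID = "ENGRAFTMENT_PROGRAM"


@dataclass
class CohortConfig:
    """Study conditions for a synthetic patient/PDX cohort.

    Defaults describe a desk-scale meta-analysis: 20 patients spread
    round-robin over 5 datasets, each patient with a biopsy (F0) and a
    two-passage xenograft chain (F1, F2); 5% of 1000 genes carry an
    engraftment shift of ≥1 log2 unit (80% down), passages drift by
    0.1 log2 sd per gene, samples carry 0.2 log2 sd measurement noise,
    and 5% of samples are low-quality outliers with 2.0 extra noise sd.
    """

    n_patients: int = 20
    n_genes: int = 1000
    passages_per_patient: list = None  # xeno chain length per patient
    engraftment_gene_fraction: float = 0.05
    engraftment_effect_log2: float = 1.0
    passage_drift_sd: float = 0.1
    sample_noise_sd: float = 0.2
    outlier_fraction: float = 0.05
    outlier_noise_sd: float = 2.0
    n_datasets: int = None  # default: min(5, n_patients)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets is None:
            self.n_datasets = min(5, self.n_patients)
        if self.passages_per_patient is None:
            self.passages_per_patient = [2] * self.n_patients
        if len(self.passages_per_patient) != self.n_patients:
            raise ValidationError(
                "passages_per_patient length must equal n_patients "
                f"({len(self.passages_per_patient)} != {self.n_patients})"
            )
        if self.n_genes < 10:
            raise ValidationError("need at least 10 genes")
        if not (0 <= self.engraftment_gene_fraction <= 1):
            raise ValidationError("engraftment_gene_fraction must be in [0, 1]")
        if not (0 <= self.outlier_fraction <= 1):
            raise ValidationError("outlier_fraction must be in [0, 1]")
        for name in ("passage_drift_sd", "sample_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be ≥ 0")
        if self.engraftment_effect_log2 <= 0:
            raise ValidationError("engraftment_effect_log2 must be positive")
        if self.outlier_noise_sd <= 0:
            raise ValidationError("outlier_noise_sd must be positive")
        if self.n_datasets < 1 or self.n_datasets > self.n_patients:
            raise ValidationError("n_datasets must be in [1, n_patients]")


@dataclass
class CohortTruth:
    engraftment_genes: frozenset
    per_gene_shift: dict  # gene → signed log2 shift (0 off the program)
    outlier_samples: frozenset


@dataclass
class PanelTruth:
    causal_genes: frozenset
    coefficients: dict  # gene → nonzero coefficient (causal genes only)
    noise_sd: float


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, CohortTruth]:
    """Simulate an annotated patient/PDX cohort with planted truth.

    Per patient: a latent biopsy profile (gene baseline ~ N(8, 2) plus a
    patient offset ~ N(0, 0.5)); the F1 latent profile adds the signed
    engraftment shift on planted genes; each later passage adds
    per-gene drift ~ N(0, passage_drift_sd). Every observed sample is
    its latent profile plus N(0, sample_noise_sd), and outlier samples
    get N(0, outlier_noise_sd) on top. Deterministic given the seed.
    """
    rng = substream(config.seed, "cohort")
    genes = _gene_ids(config.n_genes)

    baseline = rng.normal(8.0, 2.0, config.n_genes)

    n_planted = int(round(config.engraftment_gene_fraction * config.n_genes))
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    magnitudes = config.engraftment_effect_log2 * (
        1.0 + np.abs(rng.normal(0.0, 0.25, n_planted))
    )
    n_down = int(round(0.8 * n_planted))
    signs = np.concatenate([-np.ones(n_down), np.ones(n_planted - n_down)])
    rng.shuffle(signs)
    shift = np.zeros(config.n_genes)
    shift[planted_idx] = signs * magnitudes

    columns = {}
    ann_rows = []
    outliers = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:03d}"
        ds_index = p % config.n_datasets
        dataset = f"DS{ds_index + 1}"
        cancer = CANCER_TYPES[ds_index % len(CANCER_TYPES)]
        patient_profile = baseline + rng.normal(0.0, 0.5, config.n_genes)
        latent = patient_profile
        for passage in range(config.passages_per_patient[p] + 1):
            if passage == 1:
                latent = latent + shift
            elif passage >= 2:
                latent = latent + rng.normal(0.0, config.passage_drift_sd, config.n_genes)
            sample_id = f"{patient}_F{passage}"
            values = latent + rng.normal(0.0, config.sample_noise_sd, config.n_genes)
            is_outlier = bool(rng.random() < config.outlier_fraction)
            if is_outlier:
                values = values + rng.normal(0.0, config.outlier_noise_sd, config.n_genes)
                outliers.append(sample_id)
            columns[sample_id] = values
            ann_rows.append((sample_id, patient, dataset, f"F{passage}", cancer, is_outlier))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes), scale="log2")
    ann = SampleAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=[
                "sample_id",
                "patient_id",
                "dataset_id",
                "passage_label",
                "cancer_type",
                "is_outlier",
            ],
        ).set_index("sample_id")
    )
    truth = CohortTruth(
        engraftment_genes=frozenset(genes[i] for i in planted_idx),
        per_gene_shift={g: float(s) for g, s in zip(genes, shift)},
        outlier_samples=frozenset(outliers),
    )
    return matrix, ann, truth


def generate_cellline_panel(
    n_lines: int,
    n_genes: int,
    n_causal: int,
    noise_sd: float,
    seed: int,
) -> tuple[ExpressionMatrix, pd.Series, PanelTruth]:
    """Simulate a cell-line expression panel with sparse-linear log-IC50.

    Expression per gene is N(μ_g, 1) with μ_g ~ N(8, 2); the response is
    the coefficient-weighted sum of the causal genes' expression plus
    N(0, noise_sd). With noise_sd = 0 the response is exactly linear.
    """
    if n_causal > n_genes:
        raise ValidationError("n_causal cannot exceed n_genes")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be ≥ 0")
    rng = substream(seed, "panel")
    genes = _gene_ids(n_genes)
    lines = [f"CL{i + 1:04d}" for i in range(n_lines)]
    mu = rng.normal(8.0, 2.0, n_genes)
    X = mu[:, None] + rng.normal(0.0, 1.0, (n_genes, n_lines))
    causal_idx = np.sort(rng.choice(n_genes, size=n_causal, replace=False))
    coefs = rng.normal(0.0, 1.0, n_causal)
    while n_causal and np.any(np.abs(coefs) < 1e-6):  # coefficients must be nonzero
        coefs = rng.normal(0.0, 1.0, n_causal)
    y = coefs @ X[causal_idx] + rng.normal(0.0, noise_sd, n_lines)
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=lines), scale="log2")
    ic50 = pd.Series(y, index=pd.Index(lines, name="cell_line"), name="log_ic50")
    truth = PanelTruth(
        causal_genes=frozenset(genes[i] for i in causal_idx),
        coefficients={genes[i]: float(c) for i, c in zip(causal_idx, coefs)},
        noise_sd=float(noise_sd),
    )
    return matrix, ic50, truth


def generate_gene_sets(
    truth: CohortTruth, n_decoy_terms: int, term_size: int, seed: int
) -> AnnotationSet:
    """Gene-set catalogue: the planted program plus random decoy terms.

    The first term is exactly the planted engraftment gene set; decoys
    are uniform draws of ``term_size`` genes from the cohort's gene
    universe. Deterministic given the seed (GMT output is byte-stable).
    """
    universe = sorted(truth.per_gene_shift)
    if term_size > len(universe):
        raise ValidationError("term_size exceeds the gene universe")
    rng = substream(seed, "gene_sets")
    out = AnnotationSet()
    out.add(
        GeneSetTerm(
            PLANTED_TERM_ID,
            "planted engraftment stroma/immune program",
            frozenset(truth.engraftment_genes),
        )
    )
    for i in range(n_decoy_terms):
        picks = rng.choice(len(universe), size=term_size, replace=False)
        out.add(
            GeneSetTerm(
                f"DECOY{i + 1:03d}",
                "random decoy term",
                frozenset(universe[j] for j in picks),
            )
        )
    return out


def generate_probe_map(
    gene_ids, seed: int, min_probes: int = 1, max_probes: int = 3
) -> dict:
    """Random probe→gene map with 1–3 probes per gene (fixture for the
    probe-collapse step)."""
    rng = substream(seed, "probe_map")
    probe_map = {}
    counter = 0
    for g in gene_ids:
        for _ in range(int(rng.integers(min_probes, max_probes + 1))):
            counter += 1
            probe_map[f"PR{counter:06d}"] = g
    return probe_map


def expand_to_probes(
    m: ExpressionMatrix, probe_map: dict, probe_noise_sd: float = 0.1, seed: int = 0
) -> ExpressionMatrix:
    """Expand a gene matrix to probe level (gene value + probe noise)."""
    rng = substream(seed, "probe_map")
    rng.integers(0, 1)  # keep stream aligned independently of map reuse
    probes = list(probe_map)
    rows = []
    for probe in probes:
        gene = probe_map[probe]
        rows.append(
            m.data.loc[gene].to_numpy() + rng.normal(0.0, probe_noise_sd, m.n_samples)
        )
    return ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=probes, columns=m.data.columns),
        scale=m.scale,
        probe_level=True,
    )
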