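"""Compare patient biopsies against alternative tumour models.

For each patient with both a biopsy (F0) and xenograft samples, three
reference panels are scored by the *maximum* Spearman correlation with
the biopsy: (1) the patient's own xenografts, (2) a cell-line panel, and
(3) biopsies of other patients with the same cancer type. Panels are
harmonized on the shared gene universe and batch-adjusted jointly before
comparison. Leakage guards ensure the cell-line and other-patient panels
never contain the query patient's own samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

import warnings

from .errors import ValidationError
from .expression_io import ExpressionMatrix, SampleAnnotation
from .fidelity import spearman_rcc
from .preprocess import merge_and_batch_adjust

__all__ = [
    "PDX_SELF",
    "CELL_LINE",
    "OTHER_PATIENT",
    "ReferencePanel",
    "build_panels",
    "best_match",
    "compare_models",
]

PDX_SELF = "pdx_self"
CELL_LINE = "cell_line"
OTHER_PATIENT = "other_patient"


@dataclass
class ReferencePanel:
    label: str
    matrix: ExpressionMatrix


def build_panels(
    query: ExpressionMatrix,
    panels: Sequence[ReferencePanel],
    batches: Mapping[str, str],
) -> tuple[ExpressionMatrix, list[ReferencePanel]]:
    """Harmonize query + panels: shared genes, then joint batch adjustment."""
    merged = merge_and_batch_adjust([query, *(p.matrix for p in panels)], batches)
    adjusted_query = merged.subset_samples(query.sample_ids)
    adjusted_panels = [
        ReferencePanel(p.label, merged.subset_samples(p.matrix.sample_ids))
        for p in panels
    ]
    return adjusted_query, adjusted_panels


def best_match(profile: pd.Series, panel: ExpressionMatrix) -> tuple[str, float]:
    """Panel sample with the maximum SRCC to the query profile.

    Ties break toward the earlier panel column. Gene universes must
    coincide; the panel is aligned to the profile's gene order.
    """
    if panel.n_samples == 0:
        raise ValidationError("empty reference panel")
    if set(profile.index) != set(panel.data.index):
        raise ValidationError("profile and panel gene universes differ")
    aligned = panel.data.loc[profile.index]
    srccs = np.array(
        [spearman_rcc(profile.to_numpy(), aligned[s].to_numpy()) for s in aligned.columns]
    )
    best = int(np.argmax(srccs))
    return str(aligned.columns[best]), float(srccs[best])


def compare_models(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    celllines: ExpressionMatrix,
    adjust: bool = True,
) -> pd.DataFrame:
    """Max-SRCC table of each F0 biopsy against the three model panels.

    ``expr`` holds the patient cohort (biopsies + xenografts, annotated
    by ``ann``); ``celllines`` the cell-line panel. Batch labels are the
    cohort's dataset ids plus one batch for the cell-line panel. Returns
    a long-format table (patient_id, panel, best_sample, max_srcc) ready
    for boxplotting; panels that are empty for a patient (e.g. no other
    patient of the same cancer type) are skipped with a warning.
    """
    ann.check_covers(expr)
    batches = {s: str(ann.table.loc[s, "dataset_id"]) for s in expr.sample_ids}
    batches.update({s: "__cell_line_panel__" for s in celllines.sample_ids})
    if adjust:
        merged = merge_and_batch_adjust([expr, celllines], batches)
    else:
        shared = [g for g in expr.gene_ids if g in set(celllines.gene_ids)]
        if not shared:
            raise ValidationError("no shared genes between cohort and cell lines")
        merged = ExpressionMatrix(
            pd.concat([expr.data.loc[shared], celllines.data.loc[shared]], axis=1),
            scale=expr.scale,
        )
    cohort = merged.subset_samples(expr.sample_ids)
    cells = merged.subset_samples(celllines.sample_ids)

    rows = []
    for patient in ann.patients():
        samples = [s for s in ann.samples_of_patient(patient) if s in cohort.data.columns]
        f0s = [s for s in samples if ann.is_biopsy(s)]
        xenos = [s for s in samples if not ann.is_biopsy(s)]
        if not f0s or not xenos:
            continue
        f0 = f0s[0]
        profile = cohort.data[f0]
        cancer_type = str(ann.table.loc[f0, "cancer_type"])
        other_f0s = [
            s
            for s in cohort.data.columns
            if ann.is_biopsy(s)
            and ann.table.loc[s, "patient_id"] != patient
            and str(ann.table.loc[s, "cancer_type"]) == cancer_type
        ]
        panels = {
            PDX_SELF: cohort.subset_samples(xenos),
            CELL_LINE: cells,
        }
        if other_f0s:
            panels[OTHER_PATIENT] = cohort.subset_samples(other_f0s)
        else:
            warnings.warn(
                f"patient {patient!r}: no other {cancer_type!r} biopsies; "
                "other_patient panel skipped",
                stacklevel=2,
            )
        for label, panel in panels.items():
            sample, srcc = best_match(profile, panel)
            rows.append((patient, label, sample, srcc))
    return pd.DataFrame(rows, columns=["patient_id", "panel", "best_sample", "max_srcc"])
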