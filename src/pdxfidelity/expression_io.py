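"""Readers, writers and in-memory containers for the pipeline's formats.

Everything tabular is UTF-8, tab-delimited TSV with "." decimals; gene
sets use the standard GMT layout. Readers validate and reject malformed
input rather than silently coercing it, and every writer produces a file
its paired reader parses back identically (round-trip property).

Gene and sample identifiers are opaque strings; no probe/symbol ontology
mapping is attempted beyond a user-supplied probe map (see
:mod:`pdxfidelity.preprocess`). GEO series matrices must be exported to
plain TSV before use — downloading/parsing GEO formats is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetTerm",
    "AnnotationSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_sets",
    "write_gene_sets",
    "read_drug_map",
    "write_drug_map",
    "read_response_table",
    "write_response_table",
]

PASSAGE_PATTERN = re.compile(r"^F(\d+|\?)$")

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values.

    ``data`` is indexed by gene (or probe) id with one column per sample.
    ``scale`` records whether values are raw intensities ("linear") or
    log2-transformed ("log2") — downstream fold-change code refuses
    linear input. ``probe_level=True`` permits duplicate row ids pending
    a probe collapse; otherwise row ids must be unique.
    """

    data: pd.DataFrame
    scale: str = LOG2
    probe_level: bool = False

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValidationError(f"unknown scale flag: {self.scale!r}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not self.probe_level and self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene ids (enable probe_level for probe matrices): {dups}"
            )
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite (no NaN/inf)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[sample_ids].copy(), self.scale, self.probe_level)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: patient, dataset, passage label, cancer type.

    Passage labels follow the field's convention: F0 is the patient
    biopsy, Fk the k-th xenograft passage, F? a xenograft of unknown
    passage. ``table`` is indexed by sample_id.
    """

    table: pd.DataFrame

    REQUIRED = ("patient_id", "dataset_id", "passage_label")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in sample sheet: {dups}")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"sample sheet missing required column {col!r}")
        if "cancer_type" not in self.table.columns:
            self.table = self.table.assign(cancer_type="")
        if "is_outlier" not in self.table.columns:
            self.table = self.table.assign(is_outlier=False)
        bad = [
            (s, lab)
            for s, lab in self.table["passage_label"].items()
            if not PASSAGE_PATTERN.match(str(lab))
        ]
        if bad:
            raise ValidationError(
                f"invalid passage labels (expected F<digits> or F?): {bad[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def passage_number(self, sample_id: str):
        """Numeric passage, or None for the unknown label F?."""
        label = str(self.table.loc[sample_id, "passage_label"])
        return None if label == "F?" else int(label[1:])

    def is_biopsy(self, sample_id: str) -> bool:
        return self.table.loc[sample_id, "passage_label"] == "F0"

    def samples_of_patient(self, patient_id: str) -> list[str]:
        mask = self.table["patient_id"] == patient_id
        return list(self.table.index[mask])

    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"matrix samples missing from sample sheet: {missing}")


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    description: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")


@dataclass
class AnnotationSet:
    """Ordered collection of named gene sets (local stand-in for a
    functional-term catalogue such as GO/KEGG)."""

    terms: dict = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSetTerm:
        return self.terms[term_id]

    def add(self, term: GeneSetTerm) -> None:
        if term.term_id in self.terms:
            raise ValidationError(f"duplicate term id {term.term_id!r}")
        self.terms[term.term_id] = term


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path, scale: str = LINEAR, probe_level: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ids, header = samples).

    Duplicate row ids are only accepted with ``probe_level=True`` (probe
    matrices awaiting collapse). The scale flag is caller-supplied; files
    carry no scale metadata and default to linear.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file or missing header")
    first_fields = header.rstrip("\n").split("\t")
    if len(first_fields) < 2:
        raise FormatError(f"{path}: header must contain id column plus ≥1 sample")
    for tok in first_fields[1:]:
        try:
            float(tok)
        except ValueError:
            continue
        raise FormatError(
            f"{path}: numeric value {tok!r} in header row — missing header line?"
        )
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            row = raw.index[(bad | raw[col].isna())][0]
            raise FormatError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
            )
        values[col] = converted
    try:
        return ExpressionMatrix(values, scale=scale, probe_level=probe_level)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    if "is_outlier" in df.columns:
        df["is_outlier"] = df["is_outlier"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).fillna(False)
    try:
        return SampleAnnotation(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_sheet(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path) -> AnnotationSet:
    """Parse a GMT file: term, description, then ≥1 gene id per line."""
    path = Path(path)
    out = AnnotationSet()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and ≥1 gene"
                )
            term_id, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            try:
                out.add(GeneSetTerm(term_id, description, genes))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_sets(ann: AnnotationSet, path) -> None:
    # genes written sorted so identical sets give byte-identical files
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in ann.terms.values():
            fh.write("\t".join([term.term_id, term.description, *sorted(term.genes)]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene → drug interaction maps


def read_drug_map(path) -> dict:
    """Read a two-column gene_id/drug_id TSV into a gene → drug-set map."""
    path = Path(path)
    out: dict[str, set] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "drug_id"]:
            raise FormatError(f"{path}: expected header 'gene_id\\tdrug_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: malformed gene/drug line")
            out.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(d) for g, d in out.items()}


def write_drug_map(drug_map: Mapping, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tdrug_id\n")
        for gene in sorted(drug_map):
            for drug in sorted(drug_map[gene]):
                fh.write(f"{gene}\t{drug}\n")


# ---------------------------------------------------------------------------
# drug-response tables (cell_line, log_ic50)


def read_response_table(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str})
    for col in ("cell_line", "log_ic50"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    series = pd.to_numeric(df["log_ic50"], errors="coerce")
    if series.isna().any():
        row = df.loc[series.isna(), "cell_line"].iloc[0]
        raise FormatError(f"{path}: non-numeric log_ic50 for cell line {row!r}")
    out = pd.Series(series.to_numpy(), index=df["cell_line"], name="log_ic50")
    if out.index.has_duplicates:
        raise FormatError(f"{path}: duplicate cell line ids")
    return out


def write_response_table(ic50: pd.Series, path) -> None:
    df = pd.DataFrame({"cell_line": ic50.index, "log_ic50": ic50.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
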