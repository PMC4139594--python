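"""Expression matrices and their TSV serialization.

An :class:`ExpressionMatrix` is a genes x samples table of non-negative
expression values (ISH expression energy, microarray intensity, or RPKM-like
units are all represented the same way) plus a sample sheet describing each
column: the anatomical structure it was sampled from, its developmental age
or stage, and the species.

On-disk layout (both files TSV, UTF-8, '#' comment lines allowed):

* matrix: first column ``gene``, remaining header = sample ids;
* sample sheet: columns ``sample_id``, ``structure``, ``age``, ``species``
  and optionally ``zone``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .symbols import FormatError, canonicalize


@dataclass
class SampleAnnotation:
    sample_id: str
    structure: str
    age: str
    species: str
    zone: str = ""


@dataclass
class ExpressionMatrix:
    """Validated genes x samples expression table."""

    values: pd.DataFrame            # index = gene symbols, columns = sample ids
    samples: pd.DataFrame           # index = sample ids
    species: str = "mouse"
    probe_to_gene: dict[str, str] | None = field(default=None)
    # probe_to_gene maps row ids to gene symbols when rows are probes rather
    # than genes; None means rows are genes already.

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dupes[:5]}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(arr).any():
            gene = vals.index[np.isnan(arr).any(axis=1)][0]
            raise FormatError(f"NaN expression value (gene {gene})")
        if (arr < 0).any():
            gene = vals.index[(arr < 0).any(axis=1)][0]
            raise FormatError(f"negative expression value (gene {gene})")
        missing = [s for s in vals.columns if s not in self.samples.index]
        if missing:
            raise FormatError(f"sample sheet lacks metadata for sample {missing[0]!r}")
        extra = [s for s in self.samples.index if s not in vals.columns]
        if extra:
            raise FormatError(f"sample sheet row {extra[0]!r} has no matrix column")
        if self.samples.index.has_duplicates:
            raise FormatError("duplicate sample_id in sample sheet")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids_where(self, **conditions: object) -> list[str]:
        """Sample ids whose annotation matches every keyword condition.

        Values may be scalars or collections, e.g.
        ``sample_ids_where(structure="VZ", age="E15.5")`` or
        ``sample_ids_where(structure=("VZ", "SVZ"))``.
        """
        keep = pd.Series(True, index=self.samples.index)
        for column, wanted in conditions.items():
            if column not in self.samples.columns:
                raise KeyError(f"no sample-sheet column {column!r}")
            if isinstance(wanted, (list, tuple, set, frozenset)):
                keep &= self.samples[column].isin(list(wanted))
            else:
                keep &= self.samples[column] == wanted
        return [s for s in self.values.columns if keep.loc[s]]

    def subset(self, genes: list[str] | None = None, sample_ids: list[str] | None = None) -> "ExpressionMatrix":
        vals = self.values
        if genes is not None:
            vals = vals.loc[genes]
        if sample_ids is not None:
            vals = vals[sample_ids]
        sheet = self.samples.loc[vals.columns]
        return ExpressionMatrix(vals.copy(), sheet.copy(), species=self.species,
                                probe_to_gene=self.probe_to_gene)


SHEET_COLUMNS = ("sample_id", "structure", "age", "species", "zone")


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path: str | Path,
                            sample_sheet_path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(matrix_path, sep="\t", index=False)
    sheet = matrix.samples.copy()
    sheet.insert(0, "sample_id", sheet.index)
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def read_expression_matrix(matrix_path: str | Path, sample_sheet_path: str | Path,
                           species: str | None = None) -> ExpressionMatrix:
    """Read and validate a TSV expression matrix + sample sheet pair."""
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", dtype={0: str})
    if raw.columns[0] != "gene":
        raise FormatError(f"{matrix_path}: first matrix column must be 'gene', got {raw.columns[0]!r}")
    raw = raw.set_index("gene")
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise FormatError(f"{matrix_path}: non-numeric value at gene {gene!r}, sample {col!r}")
        raw[col] = parsed.astype(float)
    raw.columns.name = "sample_id"
    sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in sheet.columns:
        raise FormatError(f"{sample_sheet_path}: missing 'sample_id' column")
    sheet = sheet.set_index("sample_id")
    if "zone" not in sheet.columns:
        sheet["zone"] = ""
    sheet["zone"] = sheet["zone"].fillna("")
    if species is None:
        species = sheet["species"].iloc[0] if "species" in sheet.columns and len(sheet) else "mouse"
    return ExpressionMatrix(raw, sheet, species=species)


def matrix_from_arrays(genes: list[str], annotations: list[SampleAnnotation],
                       values: np.ndarray, species: str,
                       canonicalize_genes: bool = True) -> ExpressionMatrix:
    """Assemble a validated matrix from in-memory pieces."""
    if canonicalize_genes:
        genes = [canonicalize(g, species) for g in genes]
    sheet = pd.DataFrame(
        {
            "structure": [a.structure for a in annotations],
            "age": [a.age for a in annotations],
            "species": [a.species for a in annotations],
            "zone": [a.zone for a in annotations],
        },
        index=pd.Index([a.sample_id for a in annotations], name="sample_id"),
    )
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=pd.Index(genes, name="gene"),
                         columns=sheet.index)
    return ExpressionMatrix(frame, sheet, species=species)
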