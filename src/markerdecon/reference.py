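"""Unique-marker cell-type reference construction.

A cell-type reference is a table of marker genes taken from a published
scRNA-Seq atlas, restricted to genes reported for exactly one cell type.
Any gene listed under two or more distinct cell types is ambiguous as a
presence marker and is removed entirely; a gene repeated within a single
cell type is collapsed to one row, keeping the largest expression value.
Gene symbols are upper-cased and whitespace-trimmed before any comparison
so that orthologous genes match across species nomenclature conventions
(rat ``Lep`` vs primate ``LEP``).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import EmptyReferenceError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of a marker table / reference CSV
REF_COLUMNS = ["gene_symbol", "expression", "cell_type"]

_SYMBOL_ALIASES = {"gene_symbol", "symbol", "gene", "official_gene_symbol", "gene_name"}
_EXPRESSION_ALIASES = {"expression", "expr", "value", "abundance", "whole_kidney_expression"}
_CELLTYPE_ALIASES = {"cell_type", "celltype", "cell type", "cluster", "annotation"}


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an official gene symbol (trim whitespace, upper-case)."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class MarkerRecord:
    """One marker-gene row: symbol, source-study expression, cell type."""

    gene_symbol: str
    expression: float
    cell_type: str

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        if not self.cell_type:
            raise ValidationError("cell_type must be non-empty")
        if not self.expression >= 0:
            raise ValidationError(
                f"expression must be >= 0, got {self.expression!r} for {self.gene_symbol}"
            )


@dataclass
class CellTypeReference:
    """Marker genes uniquely assignable to exactly one cell type.

    ``records`` is a DataFrame with columns ``gene_symbol``, ``expression``,
    ``cell_type``; every gene symbol occurs exactly once.
    """

    records: pd.DataFrame
    provenance: str = ""
    cell_types: list[str] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in REF_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"reference table lacks columns: {missing}")
        if self.records.empty:
            raise EmptyReferenceError("reference contains no marker genes")
        dup = self.records["gene_symbol"].duplicated()
        if dup.any():
            offenders = sorted(self.records.loc[dup, "gene_symbol"].unique())
            raise ValidationError(
                f"gene symbols mapped to more than one record: {offenders[:10]}"
            )
        # distinct labels in order of first appearance
        self.cell_types = list(dict.fromkeys(self.records["cell_type"]))

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def cell_type_of(self, gene_symbol: str) -> str:
        sub = self.records.loc[self.records["gene_symbol"] == normalize_symbol(gene_symbol)]
        if sub.empty:
            raise KeyError(gene_symbol)
        return sub["cell_type"].iloc[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellTypeReference):
            return NotImplemented
        a = self.records.sort_values("gene_symbol").reset_index(drop=True)
        b = other.records.sort_values("gene_symbol").reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[REF_COLUMNS], b[REF_COLUMNS], check_exact=False)
        except AssertionError:
            return False
        return True


def _sniff_sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _find_column(columns: Iterable[str], aliases: set[str]) -> str | None:
    for col in columns:
        if str(col).strip().lower() in aliases:
            return col
    return None


def load_marker_tables(
    paths: Sequence[str | Path],
    cell_type_labels: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read per-cell-type marker tables and concatenate them.

    Each file needs a gene-symbol column and an expression column; the cell
    type comes from a ``cell_type`` column when present, otherwise from the
    label supplied for that file in ``cell_type_labels``. Symbols are
    case-normalized. Returns a DataFrame with columns ``gene_symbol``,
    ``expression``, ``cell_type`` (one row per input row).
    """
    paths = [Path(p) for p in paths]
    if cell_type_labels is not None and len(cell_type_labels) != len(paths):
        raise ValueError(
            f"{len(cell_type_labels)} labels supplied for {len(paths)} files"
        )
    frames: list[pd.DataFrame] = []
    for i, path in enumerate(paths):
        try:
            df = pd.read_csv(path, sep=_sniff_sep(path, delimiter))
        except pd.errors.EmptyDataError:
            warnings.warn(f"marker table {path} is empty; contributes no records")
            continue
        if df.empty:
            warnings.warn(f"marker table {path} has no rows; contributes no records")
            continue
        sym_col = _find_column(df.columns, _SYMBOL_ALIASES)
        if sym_col is None:
            raise FormatError(f"{path}: no gene-symbol column (looked for {sorted(_SYMBOL_ALIASES)})")
        expr_col = _find_column(df.columns, _EXPRESSION_ALIASES)
        if expr_col is None:
            raise FormatError(f"{path}: no expression column (looked for {sorted(_EXPRESSION_ALIASES)})")
        ct_col = _find_column(df.columns, _CELLTYPE_ALIASES)
        if ct_col is not None:
            cell_type = df[ct_col].astype(str).str.strip()
        elif cell_type_labels is not None:
            cell_type = pd.Series([cell_type_labels[i]] * len(df), index=df.index)
        else:
            raise FormatError(
                f"{path}: no cell_type column and no label supplied for this file"
            )
        expression = pd.to_numeric(df[expr_col], errors="coerce")
        if expression.isna().any():
            bad = df.index[expression.isna()][0]
            raise FormatError(f"{path}: non-numeric expression value in row {bad + 2}")
        frames.append(
            pd.DataFrame(
                {
                    "gene_symbol": df[sym_col].astype(str).map(normalize_symbol),
                    "expression": expression.astype(float),
                    "cell_type": cell_type,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=REF_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    if (out["gene_symbol"] == "").any():
        raise FormatError("empty gene symbol encountered in marker tables")
    if (out["expression"] < 0).any():
        raise FormatError("negative expression value encountered in marker tables")
    return out


def build_reference(records: pd.DataFrame, provenance: str = "") -> CellTypeReference:
    """Apply duplicate removal to marker records, yielding a unique-marker reference.

    Genes listed under two or more distinct cell types are dropped entirely
    (both copies), mirroring the deletion of highlighted duplicates in a
    spreadsheet-based workflow. Exact within-cell-type repeats collapse to a
    single row, keeping the maximum expression value.
    """
    if records is None or len(records) == 0:
        raise ValueError("no marker records supplied")
    df = records.copy()
    df["gene_symbol"] = df["gene_symbol"].map(normalize_symbol)
    n_types = df.groupby("gene_symbol")["cell_type"].nunique()
    ambiguous = set(n_types.index[n_types > 1])
    if ambiguous:
        logger.info("dropping %d cross-cell-type duplicate genes", len(ambiguous))
    unique = df[~df["gene_symbol"].isin(ambiguous)]
    if unique.empty:
        raise EmptyReferenceError(
            "every gene is duplicated across cell types; dropped symbols: "
            + ", ".join(sorted(ambiguous))
        )
    # collapse within-cell-type repeats, keep max expression
    collapsed = (
        unique.groupby(["gene_symbol", "cell_type"], as_index=False, sort=False)["expression"]
        .max()[REF_COLUMNS]
        .reset_index(drop=True)
    )
    return CellTypeReference(records=collapsed, provenance=provenance)


def write_reference(ref: CellTypeReference, path: str | Path) -> None:
    """Write a reference as CSV with header ``gene_symbol,expression,cell_type``."""
    if not isinstance(ref, CellTypeReference):
        raise TypeError("write_reference expects a CellTypeReference")
    ref.records[REF_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_reference(path: str | Path, provenance: str | None = None) -> CellTypeReference:
    """Read a reference CSV written by :func:`write_reference`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed reference file ({exc})") from exc
    missing = [c for c in REF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: reference file lacks columns {missing}")
    expr = pd.to_numeric(df["expression"], errors="coerce")
    if expr.isna().any():
        line = int(df.index[expr.isna()][0]) + 2  # header + 1-based
        raise FormatError(f"{path}: non-numeric expression on line {line}")
    df["expression"] = expr.astype(float)
    df["gene_symbol"] = df["gene_symbol"].astype(str).map(normalize_symbol)
    df["cell_type"] = df["cell_type"].astype(str)
    return CellTypeReference(records=df[REF_COLUMNS], provenance=provenance or str(path))
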