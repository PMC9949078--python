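"""Join the quality-filtered bulk matrix to the unique-marker reference.

The join key is the case-normalized official gene symbol, so a rat-derived
reference annotates a primate bulk matrix wherever orthologs share a symbol.
Every transcript isoform of a matched gene receives its own annotated row
carrying the gene's single cell type.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import EmptyResultError, FormatError, ValidationError
from .preprocess import ExpressionMatrix, SampleGroups
from .reference import CellTypeReference, normalize_symbol

META_COLUMNS = ["gene_symbol", "cell_type", "ref_expression"]


@dataclass
class AnnotatedMatrix:
    """Cell-type-annotated subset of the bulk matrix.

    ``data`` is indexed by transcript_id with columns ``gene_symbol``,
    ``cell_type``, ``ref_expression`` followed by one column per sample.
    ``summary`` records join diagnostics (matched and unmatched counts).
    """

    data: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotated table lacks columns {missing}")
        per_gene = self.data.groupby("gene_symbol")["cell_type"].nunique()
        if (per_gene > 1).any():
            bad = list(per_gene.index[per_gene > 1])
            raise ValidationError(f"genes mapped to multiple cell types: {bad[:10]}")
        self.summary.setdefault("n_transcripts", self.n_transcripts)
        self.summary.setdefault("n_genes", self.n_genes)
        self.summary.setdefault("n_cell_types", self.n_cell_types)

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def abundances(self) -> pd.DataFrame:
        return self.data[self.sample_ids]

    @property
    def n_transcripts(self) -> int:
        return len(self.data)

    @property
    def n_genes(self) -> int:
        return self.data["gene_symbol"].nunique()

    @property
    def n_cell_types(self) -> int:
        return self.data["cell_type"].nunique()


def annotate_matrix(m: ExpressionMatrix, ref: CellTypeReference) -> AnnotatedMatrix:
    """Inner-join the bulk matrix to the reference on gene symbol.

    Unmatched transcripts and unmatched reference genes are excluded from the
    output but counted in ``summary`` — the number of reference cell types
    detected in the bulk data is itself a result.
    """
    if not m.normalized:
        raise ValidationError("annotate_matrix expects a normalized (and filtered) matrix")
    symbols = m.gene_symbols.map(normalize_symbol)
    ref_map = ref.records.set_index("gene_symbol")
    matched = symbols.isin(ref_map.index)
    if not matched.any():
        raise EmptyResultError(
            "no bulk gene symbol matches the reference; check that both use "
            "official gene symbols with the same conventions"
        )
    data = m.values.loc[matched].copy()
    gene = symbols.loc[matched]
    data.insert(0, "gene_symbol", gene)
    data.insert(1, "cell_type", ref_map["cell_type"].reindex(gene).values)
    data.insert(2, "ref_expression", ref_map["expression"].reindex(gene).values)
    matched_genes = set(gene)
    summary = {
        "n_transcripts": int(matched.sum()),
        "n_genes": len(matched_genes),
        "n_cell_types": int(data["cell_type"].nunique()),
        "n_reference_genes": ref.n_genes,
        "n_reference_cell_types": len(ref.cell_types),
        "n_unmatched_transcripts": int((~matched).sum()),
        "n_unmatched_reference_genes": ref.n_genes - len(matched_genes),
    }
    return AnnotatedMatrix(data=data, summary=summary)


def top_expressed(
    a: AnnotatedMatrix, n: int = 40, groups: SampleGroups | None = None
) -> pd.DataFrame:
    """Rank annotated transcripts by mean abundance across all samples.

    Descending by mean; ties broken by transcript_id. When ``groups`` is
    given, per-group mean and SD columns are appended (the standard display
    for a top-marker figure).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > a.n_transcripts:
        warnings.warn(
            f"requested top {n} but only {a.n_transcripts} annotated transcripts; returning all"
        )
        n = a.n_transcripts
    mean_all = a.abundances.mean(axis=1)
    out = a.data[META_COLUMNS].copy()
    out["mean_abundance"] = mean_all
    if groups is not None:
        for g in groups.labels:
            cols = [s for s in a.sample_ids if groups.mapping.get(s) == g]
            out[f"mean_{g}"] = a.abundances[cols].mean(axis=1)
            out[f"sd_{g}"] = a.abundances[cols].std(axis=1, ddof=1)
    # mean descending, transcript_id ascending as the tie-break
    out.index.name = "transcript_id"
    out = (
        out.reset_index()
        .sort_values(by=["mean_abundance", "transcript_id"], ascending=[False, True], kind="mergesort")
        .set_index("transcript_id")
    )
    return out.head(n)


def write_annotated(a: AnnotatedMatrix, path: str | Path) -> None:
    out = a.data.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, float_format="%.12g")


def read_annotated(path: str | Path) -> AnnotatedMatrix:
    df = pd.read_csv(path)
    if "transcript_id" not in df.columns:
        raise FormatError(f"{path}: missing transcript_id column")
    df = df.set_index("transcript_id")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotated file lacks columns {missing}")
    return AnnotatedMatrix(data=df)
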