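"""Bulk matrix I/O, TMM normalization with a +1 offset, and mean-expression filtering.

The between-sample normalization is the trimmed mean of M-values (TMM):
per-sample scaling factors are computed from doubly trimmed, precision-
weighted log2 expression ratios against a reference sample, then rescaled
so their geometric mean is 1. Normalized abundance for gene g in sample s is

    count / (library_size_s * factor_s) * scale + offset

where ``scale`` is the mean raw library size (or 1e6 for counts-per-million)
and ``offset`` defaults to 1, so unexpressed transcripts sit at a floor of 1
("TMM+1").
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import EmptyResultError, FormatError, ValidationError

GROUPS_COLUMNS = ["sample_id", "group"]


@dataclass
class ExpressionMatrix:
    """Transcript-by-sample abundance with gene-symbol metadata.

    ``values`` is indexed by transcript_id with one numeric column per sample;
    ``gene_symbols`` is a parallel Series indexed the same way.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript_id rows: {dups[:10]}")
        if not self.values.index.equals(self.gene_symbols.index):
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)
            if self.gene_symbols.isna().any():
                raise ValidationError("gene_symbols do not cover all transcript_ids")
        if (self.values.values < 0).any():
            raise ValidationError("negative abundance values")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_symbols=self.gene_symbols.copy(),
            normalized=self.normalized,
        )


@dataclass
class SampleGroups:
    """Mapping sample_id -> group label; group order follows first appearance."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValidationError("empty sample->group mapping")

    @property
    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.mapping.values()))

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def pair(self) -> tuple[str, str]:
        """The two group labels, in order of first appearance."""
        labels = self.labels
        if len(labels) != 2:
            raise ValidationError(f"exactly two groups required, found {labels}")
        return labels[0], labels[1]

    def validate_against(self, sample_ids: Sequence[str]) -> None:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples without a group assignment: {missing}")
        for g in self.labels:
            if not any(self.mapping.get(s) == g for s in sample_ids):
                raise ValidationError(f"group {g!r} has no samples in the matrix")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleGroups":
        df = pd.read_csv(path)
        missing = [c for c in GROUPS_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: groups file lacks columns {missing}")
        return cls(dict(zip(df["sample_id"].astype(str), df["group"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class NormalizationResult:
    """Per-sample TMM scaling factors and the normalization settings used."""

    factors: pd.Series
    reference_sample: str
    offset: float = 1.0
    scale: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(self.factors.values)))
        if abs(log_gm) > 1e-8:
            raise ValidationError(f"TMM factors not geometric-mean-1 (log gm {log_gm:g})")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighted: bool = True,
) -> float:
    """Scaling factor of one sample against the reference sample.

    Doubly trimmed (trim_m on M, trim_a on A), precision-weighted mean of
    per-gene log2 count-proportion ratios, over genes finite in both samples.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        m = np.log2(p_obs / p_ref)
        a = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        # asymptotic variance of M (delta method on binomial proportions)
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        warnings.warn(
            f"only {int(keep.sum())} genes survive TMM trimming; "
            "falling back to untrimmed mean for this sample"
        )
        keep = np.ones_like(keep, dtype=bool)
    if weighted:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def choose_reference_sample(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile count fraction is closest to the mean fraction."""
    lib = counts.sum(axis=0).values.astype(float)
    q75 = np.quantile(counts.values.astype(float), 0.75, axis=0) / lib
    return counts.columns[int(np.argmin(np.abs(q75 - q75.mean())))]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> tuple[pd.Series, str]:
    """Geometric-mean-1 TMM scaling factors for a raw count matrix."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValidationError(f"samples with zero library size: {bad}")
    ref_sample = choose_reference_sample(counts)
    ref = counts[ref_sample].values.astype(float)
    factors = pd.Series(
        {
            s: _tmm_pair_factor(counts[s].values.astype(float), ref, trim_m, trim_a, weighted)
            for s in counts.columns
        }
    )
    factors /= np.exp(np.mean(np.log(factors.values)))
    return factors, ref_sample


def tmm_normalize(
    m: ExpressionMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    offset: float = 1.0,
    cpm: bool = False,
    weighted: bool = True,
) -> tuple[ExpressionMatrix, NormalizationResult]:
    """TMM-normalize a raw count matrix and add the constant offset.

    Returns the normalized matrix (flagged ``normalized=True``) and the
    per-sample factors. ``cpm=True`` rescales to counts-per-million instead
    of counts-per-mean-library-size.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    if m.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    factors, ref_sample = tmm_factors(m.values, trim_m=trim_m, trim_a=trim_a, weighted=weighted)
    lib = m.values.sum(axis=0)
    scale = 1e6 if cpm else float(lib.mean())
    eff = lib * factors
    norm = m.values.div(eff, axis=1) * scale + offset
    result = NormalizationResult(
        factors=factors, reference_sample=ref_sample, offset=offset, scale=scale
    )
    out = ExpressionMatrix(values=norm, gene_symbols=m.gene_symbols.copy(), normalized=True)
    return out, result


def filter_low_expression(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Drop transcripts whose mean abundance across all samples is below ``threshold``.

    The mean pools every sample regardless of group; the cut is strict
    ("expressed an average of less than ``threshold``" is removed), so a row
    with mean exactly at the threshold is retained. Row order is preserved.
    """
    if not m.normalized:
        raise ValidationError("filter_low_expression expects a normalized matrix")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = m.values.mean(axis=1) >= threshold
    if not keep.any():
        raise EmptyResultError(f"no transcript has mean abundance >= {threshold}")
    return ExpressionMatrix(
        values=m.values.loc[keep],
        gene_symbols=m.gene_symbols.loc[keep],
        normalized=True,
    )


def read_matrix(
    path: str | Path,
    id_col: str = "transcript_id",
    symbol_col: str = "gene_symbol",
    normalized: bool = False,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a transcript-by-sample matrix CSV/TSV.

    Layout: one row per transcript; columns ``transcript_id``, ``gene_symbol``,
    then one numeric column per sample.
    """
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, symbol_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in (id_col, symbol_col)]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        row = int(values.index[values[col].isna()][0]) + 2
        raise FormatError(f"{path}: non-numeric value in column {col!r}, line {row}")
    values.index = pd.Index(df[id_col].astype(str), name=id_col)
    symbols = pd.Series(df[symbol_col].astype(str).values, index=values.index, name=symbol_col)
    return ExpressionMatrix(values=values.astype(float), gene_symbols=symbols, normalized=normalized)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as CSV (12 significant digits, round-trip safe)."""
    out = m.values.copy()
    out.insert(0, "gene_symbol", m.gene_symbols)
    out.index.name = "transcript_id"
    out.to_csv(path, float_format="%.12g")
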