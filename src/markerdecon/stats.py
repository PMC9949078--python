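"""Group-composition statistics.

Per-transcript two-group comparisons use unpaired t-tests — pooled-variance
(Student) by default, Welch by option — with the Benjamini–Krieger–Yekutieli
two-stage adaptive FDR procedure applied across all annotated transcripts.
Cell-type presence is inferred from marker abundance above the normalization
floor, and group-exclusive genes are genes detected in every sample of one
group and no sample of the other. Sequencing-QC metrics are compared with
Welch's t-test per metric, uncorrected (one test per panel).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import fdrcorrection, fdrcorrection_twostage

from .annotate import AnnotatedMatrix
from .exceptions import ValidationError
from .preprocess import SampleGroups

QC_METRICS = [
    "total_reads",
    "avg_read_length",
    "avg_phred",
    "avg_depth",
    "avg_coverage",
    "pct_aligned",
]


@dataclass
class StatsConfig:
    """Tunables for the composition comparison.

    fdr_q: target FDR level for the two-stage procedure.
    welch_for_multiple: use Welch instead of pooled-variance t for the
        per-transcript tests (the QC comparison always uses Welch).
    presence_threshold: abundance a marker transcript must exceed (strictly)
        to count as expressed; defaults to the +1 normalization offset, i.e.
        any evidence above the unexpressed floor.
    exclusive_rule: "all-vs-none" requires every sample of the owning group
        above threshold; "any-vs-none" requires at least one.
    """

    fdr_q: float = 0.05
    welch_for_multiple: bool = False
    presence_threshold: float = 1.0
    exclusive_rule: Literal["all-vs-none", "any-vs-none"] = "all-vs-none"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValidationError(f"fdr_q must be in (0,1), got {self.fdr_q}")
        if self.presence_threshold < 0:
            raise ValidationError("presence_threshold must be >= 0")
        if self.exclusive_rule not in ("all-vs-none", "any-vs-none"):
            raise ValidationError(f"unknown exclusive_rule {self.exclusive_rule!r}")


def _check_group_sizes(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values for a t-test")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unpaired t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_group_sizes(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def student_t(x, y) -> tuple[float, float, float]:
    """Pooled-variance unpaired t-test: (t, df = n_x+n_y-2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_group_sizes(x, y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bky_two_stage(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive linear step-up FDR procedure.

    Stage 1 is Benjamini–Hochberg at q' = q/(1+q); its rejection count r1
    estimates the number of true nulls as m - r1. If 0 < r1 < m, stage 2
    reruns the step-up at q'·m/(m−r1). Returns (q_values, rejected); the
    rejection decisions, not the adjusted values, are the primary contract.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        rejected, q_values, _, _ = fdrcorrection_twostage(
            p, alpha=q, method="bky", maxiter=1
        )
    return np.clip(q_values, 0.0, 1.0), rejected


def stage1_rejections(p_values, q: float = 0.05) -> np.ndarray:
    """Stage-1 (plain BH at q/(1+q)) rejection mask of the two-stage procedure."""
    p = np.asarray(p_values, dtype=float)
    rejected, _ = fdrcorrection(p, alpha=q / (1.0 + q), method="indep")
    return rejected


def _group_arrays(
    a: AnnotatedMatrix, g: SampleGroups
) -> tuple[str, str, np.ndarray, np.ndarray]:
    ga, gb = g.pair()
    g.validate_against(a.sample_ids)
    cols_a = [s for s in a.sample_ids if g.mapping[s] == ga]
    cols_b = [s for s in a.sample_ids if g.mapping[s] == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    return ga, gb, a.abundances[cols_a].values, a.abundances[cols_b].values


def compare_groups(
    a: AnnotatedMatrix, g: SampleGroups, cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """One unpaired t-test per annotated transcript, BKY-adjusted across all.

    Returns a table indexed by transcript_id with per-group mean/SD, t, df,
    raw p, two-stage q and the FDR significance call. Transcripts constant
    and equal in both groups get t=0, p=1 (no evidence, not an error).
    """
    cfg = cfg or StatsConfig()
    ga, gb, xa, xb = _group_arrays(a, g)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(xa, xb, axis=1, equal_var=not cfg.welch_for_multiple)
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    # zero variance in both groups: equal means -> no evidence; unequal -> certainty
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(mean_a, mean_b)
    t[degenerate & equal_means] = 0.0
    p[degenerate & equal_means] = 1.0
    t[degenerate & ~equal_means] = np.sign(mean_a - mean_b)[degenerate & ~equal_means] * np.inf
    p[degenerate & ~equal_means] = 0.0
    df[~np.isfinite(df)] = xa.shape[1] + xb.shape[1] - 2
    q_values, rejected = bky_two_stage(p, q=cfg.fdr_q)
    out = pd.DataFrame(
        {
            "gene_symbol": a.data["gene_symbol"].values,
            "cell_type": a.data["cell_type"].values,
            f"mean_{ga}": mean_a,
            f"sd_{ga}": xa.std(axis=1, ddof=1),
            f"mean_{gb}": mean_b,
            f"sd_{gb}": xb.std(axis=1, ddof=1),
            "t": t,
            "df": df,
            "p": p,
            "q": q_values,
            "significant": rejected,
        },
        index=a.data.index,
    )
    out.index.name = "transcript_id"
    return out


def presence_table(
    a: AnnotatedMatrix, g: SampleGroups, cfg: StatsConfig | None = None
) -> pd.DataFrame:
    """Per-(cell type, group) presence calls with supporting marker counts.

    A cell type is present in a group iff at least one of its marker
    transcripts has group-mean abundance strictly above the presence
    threshold. The table covers every cell type observed in the annotated
    matrix; ``attrs['n_cell_types_detected']`` counts those present in at
    least one group.
    """
    cfg = cfg or StatsConfig()
    if a.n_transcripts == 0:
        raise ValidationError("annotated matrix is empty")
    ga, gb, xa, xb = _group_arrays(a, g)
    df = pd.DataFrame(
        {
            "cell_type": a.data["cell_type"].values,
            f"mean_{ga}": xa.mean(axis=1),
            f"mean_{gb}": xb.mean(axis=1),
        }
    )
    rows = []
    for ct, sub in df.groupby("cell_type", sort=True):
        na = int((sub[f"mean_{ga}"] > cfg.presence_threshold).sum())
        nb = int((sub[f"mean_{gb}"] > cfg.presence_threshold).sum())
        rows.append(
            {
                "cell_type": ct,
                f"present_{ga}": na > 0,
                f"present_{gb}": nb > 0,
                f"n_markers_{ga}": na,
                f"n_markers_{gb}": nb,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_cell_types_detected"] = int(
        (table[f"present_{ga}"] | table[f"present_{gb}"]).sum()
    )
    table.attrs["groups"] = (ga, gb)
    return table


def exclusive_genes(
    a: AnnotatedMatrix, g: SampleGroups, cfg: StatsConfig | None = None
) -> dict[str, list[str]]:
    """Genes detected only in one group.

    A sample expresses a gene when any of the gene's transcript isoforms is
    strictly above the presence threshold. Under "all-vs-none" a gene is
    exclusive to group G iff every G sample expresses it and no sample of
    the other group does; "any-vs-none" relaxes 'every' to 'at least one'.
    """
    cfg = cfg or StatsConfig()
    ga, gb, xa, xb = _group_arrays(a, g)
    genes = a.data["gene_symbol"].values
    expr_a = pd.DataFrame(xa > cfg.presence_threshold, index=genes)
    expr_b = pd.DataFrame(xb > cfg.presence_threshold, index=genes)
    # per (gene, sample): any isoform above threshold
    by_gene_a = expr_a.groupby(level=0).any()
    by_gene_b = expr_b.groupby(level=0).any()
    need_all = cfg.exclusive_rule == "all-vs-none"
    own_a = by_gene_a.all(axis=1) if need_all else by_gene_a.any(axis=1)
    own_b = by_gene_b.all(axis=1) if need_all else by_gene_b.any(axis=1)
    none_a = ~by_gene_a.any(axis=1)
    none_b = ~by_gene_b.any(axis=1)
    return {
        ga: sorted(own_a.index[own_a & none_b]),
        gb: sorted(own_b.index[own_b & none_a]),
    }


def compare_qc_metrics(qc: pd.DataFrame, g: SampleGroups) -> pd.DataFrame:
    """Welch's t-test per sequencing-QC metric, males-vs-females style.

    ``qc`` is indexed by sample_id with one numeric column per metric.
    No multiplicity correction is applied across metrics (each panel is
    reported with its raw Welch p-value). Metrics with missing values are
    skipped with a warning.
    """
    ga, gb = g.pair()
    g.validate_against(list(qc.index))
    idx_a = [s for s in qc.index if g.mapping[s] == ga]
    idx_b = [s for s in qc.index if g.mapping[s] == gb]
    rows = []
    for metric in qc.columns:
        col = pd.to_numeric(qc[metric], errors="coerce")
        if col.loc[idx_a + idx_b].isna().any():
            warnings.warn(f"QC metric {metric!r} has missing values; skipped")
            continue
        x, y = col.loc[idx_a].values, col.loc[idx_b].values
        t, df, p = welch_t(x, y)
        rows.append(
            {
                "metric": metric,
                f"mean_{ga}": x.mean(),
                f"sd_{ga}": x.std(ddof=1),
                f"mean_{gb}": y.mean(),
                f"sd_{gb}": y.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
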