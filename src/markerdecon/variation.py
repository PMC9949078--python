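"""Between-sample variation: per-group CV and PCA with 2-SD group ellipsoids.

Both operate on the full quality-filtered normalized matrix (all transcripts,
not only the cell-type-annotated subset). PCA treats samples as observations
and transcripts as features, mean-centers features (covariance PCA; optional
unit-variance scaling gives correlation PCA), and summarises each group in
component space by its mean score and an axis-aligned ellipsoid of radius
two score standard deviations per retained component.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import ValidationError
from .preprocess import ExpressionMatrix, SampleGroups

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def cv_by_group(m: ExpressionMatrix, g: SampleGroups) -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean) per transcript per group.

    Returns a table indexed by transcript_id with columns ``cv_<A>``,
    ``cv_<B>``, ``higher_group`` (group with the larger mean, ``"equal"`` on
    ties) and ``defined`` (False where a group mean is zero, which cannot
    occur on a +1-offset matrix).
    """
    ga, gb = g.pair()
    g.validate_against(m.sample_ids)
    cols_a = [s for s in m.sample_ids if g.mapping[s] == ga]
    cols_b = [s for s in m.sample_ids if g.mapping[s] == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("each group needs at least 2 samples for a CV")
    xa, xb = m.values[cols_a], m.values[cols_b]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a, sd_b = xa.std(axis=1, ddof=1), xb.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_a = sd_a / mean_a
        cv_b = sd_b / mean_b
    higher = np.where(mean_a > mean_b, ga, np.where(mean_b > mean_a, gb, "equal"))
    out = pd.DataFrame(
        {
            f"cv_{ga}": cv_a,
            f"cv_{gb}": cv_b,
            "higher_group": higher,
            "defined": (mean_a != 0) & (mean_b != 0),
        },
        index=m.values.index,
    )
    out.attrs["groups"] = (ga, gb)
    return out


@dataclass
class PCAResult:
    """Sample scores, per-component explained variance, 2-SD group ellipsoids."""

    scores: pd.DataFrame          # samples x retained components
    explained_pct: np.ndarray     # all min(n-1, p) components, sums to 100
    components: np.ndarray        # retained components x features (orthonormal rows)
    ellipsoids: pd.DataFrame      # group, component, center, radius

    def __post_init__(self) -> None:
        total = float(np.sum(self.explained_pct))
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"explained variance sums to {total}, not 100")
        if (self.explained_pct < -1e-12).any():
            raise ValidationError("negative explained variance")


def pca(
    m: ExpressionMatrix,
    g: SampleGroups | None = None,
    n_components: int = 3,
    scale: bool = False,
) -> PCAResult:
    """Principal component analysis of samples in transcript space.

    ``scale=False`` (default) is covariance PCA on mean-centered features;
    ``scale=True`` standardizes each transcript to unit variance first
    (zero-variance transcripts are dropped with a warning). ``explained_pct``
    covers every component of the centered data so it always sums to 100;
    ``scores`` and ``ellipsoids`` keep the top ``n_components``.
    """
    X = m.values.T.values.astype(float)  # samples x transcripts
    n, p = X.shape
    if n < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(samples-1, transcripts)={min(n - 1, p)}"
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance transcripts for correlation PCA")
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    fit = PCA(n_components=None, svd_solver="full").fit(X)
    explained_pct = fit.explained_variance_ratio_ * 100.0
    explained_pct *= 100.0 / explained_pct.sum()  # guard fp drift in the ratio sum
    scores_all = fit.transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(scores_all[:, :n_components], index=m.sample_ids, columns=comp_names)
    rows = []
    if g is not None:
        g.validate_against(m.sample_ids)
        for label in g.labels:
            sub = scores.loc[[s for s in m.sample_ids if g.mapping[s] == label]]
            for c in comp_names:
                rows.append(
                    {
                        "group": label,
                        "component": c,
                        "center": float(sub[c].mean()),
                        "radius": float(2.0 * sub[c].std(ddof=1)),
                    }
                )
    ellipsoids = pd.DataFrame(rows, columns=["group", "component", "center", "radius"])
    return PCAResult(
        scores=scores,
        explained_pct=explained_pct,
        components=fit.components_[:n_components],
        ellipsoids=ellipsoids,
    )


_GROUP_COLORS = ("tab:red", "tab:blue")


def cv_scatter(
    records: pd.DataFrame, path: str | Path, csv_path: str | Path | None = None
) -> pd.DataFrame:
    """Scatter of per-transcript CV, group A on x vs group B on y.

    Points are colored by which group has the larger mean expression; the
    plotted table (undefined-CV records excluded) is also written as CSV so
    the figure is reproducible data. Returns the plotted table.
    """
    if records.empty:
        raise ValidationError("no CV records to plot")
    ga, gb = records.attrs.get("groups") or (
        records.columns[0].removeprefix("cv_"),
        records.columns[1].removeprefix("cv_"),
    )
    data = records[records.get("defined", True) == True]  # noqa: E712
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, color in zip((ga, gb, "equal"), (*_GROUP_COLORS, "0.6")):
        sub = data[data["higher_group"] == label]
        if len(sub):
            ax.scatter(sub[f"cv_{ga}"], sub[f"cv_{gb}"], s=6, c=color, label=label, alpha=0.6)
    ax.set_xlabel(f"CV ({ga})")
    ax.set_ylabel(f"CV ({gb})")
    ax.legend(title="higher mean", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    if csv_path is None:
        csv_path = Path(path).with_suffix(".csv")
    data.to_csv(csv_path, float_format="%.12g")
    return data


def pca_plot(result: PCAResult, g: SampleGroups, path: str | Path) -> None:
    """PC1-vs-PC2 score plot with axis-aligned 2-SD group ellipses."""
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, color in zip(g.labels, _GROUP_COLORS):
        samples = [s for s in result.scores.index if g.mapping[s] == label]
        sub = result.scores.loc[samples]
        ax.scatter(sub["PC1"], sub["PC2"], c=color, label=label)
        ell = result.ellipsoids[result.ellipsoids["group"] == label].set_index("component")
        if {"PC1", "PC2"} <= set(ell.index):
            ax.add_patch(
                Ellipse(
                    (ell.loc["PC1", "center"], ell.loc["PC2", "center"]),
                    width=2 * ell.loc["PC1", "radius"],
                    height=2 * ell.loc["PC2", "radius"],
                    facecolor=color,
                    alpha=0.15,
                    edgecolor=color,
                )
            )
    pc1, pc2 = result.explained_pct[:2]
    ax.set_xlabel(f"PC1 ({pc1:.1f}%)")
    ax.set_ylabel(f"PC2 ({pc2:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
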