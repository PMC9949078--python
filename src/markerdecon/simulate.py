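"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design this package targets: a published
scRNA-Seq atlas supplying per-cell-type marker gene lists (including genes
deliberately shared between cell types, which a correct reference builder
must drop), and a two-group bulk RNA-Seq experiment on a tissue mixture of
those cell types. Bulk counts are negative binomial around expected
abundances of the form

    E[count of marker g of cell type c in sample s]
        = library_size_s * weight(c, group of s) * intensity(g) / total

with background genes providing the rest of the library, a configurable
fraction of them silent (structural zeros) to exercise the low-expression
filter. Group-different genes receive a log2 fold change in the second
group; group-exclusive genes are structurally zero in the other group. Some
marker genes are emitted as two transcript isoforms of one symbol to
exercise isoform fan-out during annotation. A per-sample sequencing-QC
table (normal draws per metric) emulates the run-quality comparison.

Everything is a deterministic function of the configuration, including its
seed: identical configs produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotatedMatrix
from .preprocess import SampleGroups
from .stats import QC_METRICS

#: plausible mammalian kidney cell-type labels used for default simulations
KIDNEY_CELL_TYPES = [
    "podocyte",
    "mesangial cell",
    "glomerular endothelial cell",
    "parietal epithelial cell",
    "proximal tubule S1",
    "proximal tubule S2",
    "proximal tubule S3",
    "thin descending limb",
    "thin ascending limb",
    "thick ascending limb",
    "macula densa",
    "distal convoluted tubule",
    "connecting tubule",
    "principal cell CCD",
    "principal cell OMCD",
    "principal cell IMCD",
    "intercalated cell type A",
    "intercalated cell type B",
    "non-A non-B intercalated cell",
    "juxtaglomerular cell",
    "fenestrated endothelial cell",
    "peritubular capillary endothelial",
    "vasa recta ascending",
    "vasa recta descending",
    "arteriolar endothelial cell",
    "lymphatic endothelial cell",
    "vascular smooth muscle cell",
    "pericyte",
    "fibroblast",
    "medullary interstitial cell",
    "renin-positive interstitial cell",
    "macrophage",
    "dendritic cell",
    "T lymphocyte",
    "B lymphocyte",
    "natural killer cell",
    "neutrophil",
    "mast cell",
    "plasma cell",
    "urothelial cell",
    "neural axon cell",
    "Schwann cell",
    "erythroid cell",
]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the target study design: two groups of 8 and 9 bulk
    samples, a 43-cell-type reference with a handful of ambiguous (shared)
    markers, and a few thousand background transcripts.
    """

    n_cell_types: int = 43
    markers_per_type: int = 3
    n_shared_markers: int = 10
    n_background_genes: int = 2000
    bg_silent_fraction: float = 0.25
    n_samples_per_group: tuple[int, int] = (8, 9)
    group_labels: tuple[str, str] = ("female", "male")
    proportions: dict[str, list[float]] | None = None
    dirichlet_alpha: float = 5.0
    zero_weight_cell_types: int = 0
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.1
    nb_dispersion: float = 0.1
    n_group_diff_genes: int = 0
    effect_size: float = 1.0  # log2 fold change applied in the second group
    n_exclusive_genes: tuple[int, int] = (0, 0)
    isoform_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type < 1:
            raise ValueError("markers_per_type must be >= 1")
        if self.n_cell_types < 1:
            raise ValueError("n_cell_types must be >= 1")
        if not 0 <= self.zero_weight_cell_types < self.n_cell_types:
            raise ValueError("zero_weight_cell_types must leave at least one active cell type")
        if any(n < 2 for n in self.n_samples_per_group):
            raise ValueError("each group needs at least 2 samples")
        if self.proportions is not None:
            for g, w in self.proportions.items():
                w = np.asarray(w, dtype=float)
                if len(w) != self.n_cell_types or (w < 0).any():
                    raise ValueError(f"proportions[{g!r}] must be {self.n_cell_types} weights >= 0")
                if abs(w.sum() - 1.0) > 1e-9:
                    raise ValueError(f"proportions[{g!r}] must sum to 1")
        if not 0 <= self.bg_silent_fraction <= 1:
            raise ValueError("bg_silent_fraction must be in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        base = list(KIDNEY_CELL_TYPES)
        while len(base) < self.n_cell_types:
            base.append(f"cell type {len(base) + 1}")
        return base[: self.n_cell_types]


@dataclass
class GroundTruth:
    """What a correct pipeline must recover from the generated files."""

    unique_marker_map: dict[str, str] = field(default_factory=dict)
    shared_markers: dict[str, list[str]] = field(default_factory=dict)
    marker_intensity: dict[str, float] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    present_cell_types: dict[str, list[str]] = field(default_factory=dict)
    group_diff_genes: dict[str, float] = field(default_factory=dict)
    exclusive_genes: dict[str, list[str]] = field(default_factory=dict)
    isoform_genes: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _slug(label: str) -> str:
    keep = string.ascii_letters + string.digits
    return "".join(c if c in keep else "_" for c in label)


def _sample_ids(ga: str, gb: str, n_a: int, n_b: int) -> list[str]:
    pa, pb = ga[0].upper(), gb[0].upper()
    if pa == pb:  # disambiguate when both labels share an initial
        pa, pb = _slug(ga) + "_", _slug(gb) + "_"
    return [f"{pa}{i + 1:02d}" for i in range(n_a)] + [f"{pb}{i + 1:02d}" for i in range(n_b)]


def _marker_symbol(type_idx: int, marker_idx: int) -> str:
    return f"MK{type_idx:02d}{string.ascii_uppercase[marker_idx % 26]}{marker_idx // 26 or ''}"


def simulate_markers(
    cfg: SimulationConfig, out_dir: str | Path
) -> tuple[list[Path], GroundTruth]:
    """Write one marker-table CSV per cell type; return paths and ground truth.

    Each cell type receives ``markers_per_type`` unique marker genes; in
    addition ``n_shared_markers`` genes are listed under two distinct cell
    types each (with independent expression values), so the ground-truth
    unique set is exactly the per-type markers.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = GroundTruth()
    cell_types = cfg.cell_types
    tables: dict[str, list[tuple[str, float]]] = {ct: [] for ct in cell_types}
    for i, ct in enumerate(cell_types):
        for j in range(cfg.markers_per_type):
            sym = _marker_symbol(i, j)
            intensity = float(rng.lognormal(mean=np.log(20.0), sigma=1.0))
            tables[ct].append((sym, intensity))
            gt.unique_marker_map[sym] = ct
            gt.marker_intensity[sym] = intensity
    for j in range(cfg.n_shared_markers):
        sym = f"SHR{j:02d}"
        pair = rng.choice(len(cell_types), size=2, replace=False)
        owners = [cell_types[int(k)] for k in sorted(pair)]
        for ct in owners:
            tables[ct].append((sym, float(rng.lognormal(mean=np.log(20.0), sigma=1.0))))
        gt.shared_markers[sym] = owners
    paths = []
    for ct in cell_types:
        df = pd.DataFrame(tables[ct], columns=["gene_symbol", "expression"])
        df["cell_type"] = ct
        path = out_dir / f"{_slug(ct)}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        paths.append(path)
    gt.manifest.update(
        {
            "n_marker_files": len(paths),
            "n_marker_records": int(sum(len(v) for v in tables.values())),
            "n_unique_marker_genes": len(gt.unique_marker_map),
            "n_reference_cell_types": len(cell_types),
        }
    )
    return paths, gt


def _group_weights(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-group mixture weights over cell types (identical across groups by default)."""
    if cfg.proportions is not None:
        return {g: np.asarray(cfg.proportions[g], dtype=float) for g in cfg.group_labels}
    k = cfg.n_cell_types
    k_active = k - cfg.zero_weight_cell_types
    # Dirichlet mixed with uniform: keeps every active cell type above
    # 0.3/k_active so all mixed-in types are genuinely detectable
    raw = rng.dirichlet([cfg.dirichlet_alpha] * k_active)
    active = 0.7 * raw + 0.3 / k_active
    w = np.concatenate([active, np.zeros(cfg.zero_weight_cell_types)])
    return {g: w.copy() for g in cfg.group_labels}


def simulate_bulk(
    cfg: SimulationConfig, gt: GroundTruth, out_dir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    """Write a raw bulk count matrix and sample-group table; complete ground truth."""
    rng = np.random.default_rng([cfg.seed, 2])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_types = cfg.cell_types
    ga, gb = cfg.group_labels
    weights = _group_weights(cfg, rng)
    gt.weights = {g: dict(zip(cell_types, map(float, w))) for g, w in weights.items()}
    gt.present_cell_types = {
        g: [ct for ct, wi in zip(cell_types, w) if wi > 0] for g, w in weights.items()
    }

    marker_genes = list(gt.unique_marker_map)
    type_index = {ct: i for i, ct in enumerate(cell_types)}
    # base relative rate per gene and group
    rate = {g: {} for g in cfg.group_labels}
    for sym in marker_genes:
        ct = gt.unique_marker_map[sym]
        for g in cfg.group_labels:
            rate[g][sym] = weights[g][type_index[ct]] * gt.marker_intensity[sym]

    # group-exclusive genes: structural zeros in the other group, boosted so
    # every owning-group sample is detected
    eligible = [
        s
        for s in marker_genes
        if weights[ga][type_index[gt.unique_marker_map[s]]] > 0
        and sum(gt.unique_marker_map[x] == gt.unique_marker_map[s] for x in marker_genes) >= 2
    ]
    rng.shuffle(eligible)
    n_ex_a, n_ex_b = cfg.n_exclusive_genes
    excl_a = sorted(eligible[:n_ex_a])
    excl_b = sorted(eligible[n_ex_a : n_ex_a + n_ex_b])
    gt.exclusive_genes = {ga: excl_a, gb: excl_b}
    for sym in excl_a:
        rate[ga][sym] = max(rate[ga][sym], 2.0)
        rate[gb][sym] = 0.0
    for sym in excl_b:
        rate[gb][sym] = max(rate[gb][sym], 2.0)
        rate[ga][sym] = 0.0

    # group-different genes: log2 fold change applied in the second group
    remaining = [s for s in marker_genes if s not in excl_a and s not in excl_b]
    rng.shuffle(remaining)
    diff = sorted(remaining[: cfg.n_group_diff_genes])
    gt.group_diff_genes = {s: float(cfg.effect_size) for s in diff}
    for sym in diff:
        rate[gb][sym] = rate[gb][sym] * 2.0**cfg.effect_size

    # background genes, a fraction of them structurally silent
    n_bg = cfg.n_background_genes
    bg_intensity = rng.lognormal(mean=0.0, sigma=2.0, size=n_bg)
    silent = rng.random(n_bg) < cfg.bg_silent_fraction
    bg_intensity[silent] = 0.0
    for j in range(n_bg):
        sym = f"BG{j:05d}"
        for g in cfg.group_labels:
            rate[g][sym] = float(bg_intensity[j])

    # transcript table: some marker genes fan out into two isoforms
    n_iso = int(np.floor(cfg.isoform_fraction * len(marker_genes)))
    gt.isoform_genes = sorted(marker_genes[:n_iso])
    transcripts: list[tuple[str, str, float]] = []  # (transcript_id, gene_symbol, share)
    tid = 0
    for sym in sorted(rate[ga]):
        if sym in set(gt.isoform_genes):
            for share in (0.6, 0.4):
                transcripts.append((f"XM_{tid:06d}.1", sym, share))
                tid += 1
        else:
            transcripts.append((f"XM_{tid:06d}.1", sym, 1.0))
            tid += 1

    n_a, n_b = cfg.n_samples_per_group
    sample_ids = _sample_ids(ga, gb, n_a, n_b)
    sample_groups = [ga] * n_a + [gb] * n_b
    lib_sigma = np.sqrt(np.log1p(cfg.library_size_cv**2))
    lib = rng.lognormal(np.log(cfg.library_size_mean) - lib_sigma**2 / 2, lib_sigma, len(sample_ids))

    counts = np.zeros((len(transcripts), len(sample_ids)), dtype=np.int64)
    totals = {g: sum(rate[g].values()) for g in cfg.group_labels}
    base_rates = {
        g: np.array([rate[g][sym] * share for (_, sym, share) in transcripts]) / totals[g]
        for g in cfg.group_labels
    }
    phi = cfg.nb_dispersion
    for j, (sid, g) in enumerate(zip(sample_ids, sample_groups)):
        mu = lib[j] * base_rates[g]
        if phi > 0:
            shape = 1.0 / phi
            counts[:, j] = rng.poisson(rng.gamma(shape, mu * phi))
        else:
            counts[:, j] = rng.poisson(mu)

    df = pd.DataFrame(counts, columns=sample_ids)
    df.insert(0, "gene_symbol", [sym for (_, sym, _) in transcripts])
    df.insert(0, "transcript_id", [t for (t, _, _) in transcripts])
    counts_path = out_dir / "counts.csv"
    df.to_csv(counts_path, index=False)
    groups_path = out_dir / "groups.csv"
    SampleGroups(dict(zip(sample_ids, sample_groups))).to_csv(groups_path)
    gt.manifest.update(
        {
            "n_transcripts": len(transcripts),
            "n_samples": len(sample_ids),
            "n_samples_per_group": {ga: n_a, gb: n_b},
            "n_isoform_genes": len(gt.isoform_genes),
            "n_background_genes": n_bg,
            "n_silent_background_genes": int(silent.sum()),
        }
    )
    return counts_path, groups_path, gt


#: default (mean, sd) per QC metric, shared by both groups unless shifted
QC_DEFAULTS = {
    "total_reads": (30e6, 4e6),
    "avg_read_length": (92.0, 2.0),
    "avg_phred": (35.0, 0.8),
    "avg_depth": (30.0, 5.0),
    "avg_coverage": (25.0, 4.0),
    "pct_aligned": (85.0, 4.0),
}


def simulate_qc(
    cfg: SimulationConfig,
    path: str | Path,
    metric_shift: dict[str, float] | None = None,
) -> Path:
    """Write a per-sample sequencing-QC metrics table.

    Metrics are normal draws around :data:`QC_DEFAULTS`; ``metric_shift``
    adds the given offset to the second group's mean for that metric, to
    plant (or not plant) run-quality group differences.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    metric_shift = metric_shift or {}
    ga, gb = cfg.group_labels
    n_a, n_b = cfg.n_samples_per_group
    sample_ids = _sample_ids(ga, gb, n_a, n_b)
    rows = {"sample_id": sample_ids}
    for metric in QC_METRICS:
        mean, sd = QC_DEFAULTS[metric]
        shift = metric_shift.get(metric, 0.0)
        vals = np.concatenate(
            [rng.normal(mean, sd, n_a), rng.normal(mean + shift, sd, n_b)]
        )
        rows[metric] = np.round(vals, 4)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path


def simulate_all(
    cfg: SimulationConfig,
    out_dir: str | Path,
    qc_metric_shift: dict[str, float] | None = None,
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full input set: markers/, counts, groups, QC, truth.json."""
    out_dir = Path(out_dir)
    marker_paths, gt = simulate_markers(cfg, out_dir / "markers")
    counts_path, groups_path, gt = simulate_bulk(cfg, gt, out_dir)
    qc_path = simulate_qc(cfg, out_dir / "qc.csv", metric_shift=qc_metric_shift)
    truth_path = out_dir / "truth.json"
    gt.to_json(truth_path)
    return (
        {
            "markers": marker_paths,
            "counts": counts_path,
            "groups": groups_path,
            "qc": qc_path,
            "truth": truth_path,
        },
        gt,
    )


def simulate_gaussian_groups(
    n_null: int = 200,
    n_diff: int = 0,
    effect_sd: float = 3.0,
    n_a: int = 8,
    n_b: int = 9,
    base_mean: float = 100.0,
    sd: float = 10.0,
    seed: int = 0,
    group_labels: tuple[str, str] = ("female", "male"),
) -> tuple[AnnotatedMatrix, SampleGroups, list[str]]:
    """Gaussian two-group expression with planted mean shifts.

    ``n_diff`` transcripts receive a shift of ``effect_sd`` standard
    deviations in the second group; the rest are exchangeable between
    groups. Returns an annotated matrix (one synthetic cell type), the
    groups, and the planted transcript ids — the direct test-bed for the
    per-transcript t-test / FDR machinery.
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_diff
    ga, gb = group_labels
    sample_ids = _sample_ids(ga, gb, n_a, n_b)
    values = rng.normal(base_mean, sd, size=(n, n_a + n_b))
    diff_rows = rng.choice(n, size=n_diff, replace=False)
    values[np.ix_(diff_rows, np.arange(n_a, n_a + n_b))] += effect_sd * sd
    values = np.clip(values, 0.0, None)
    tids = [f"XM_{i:06d}.1" for i in range(n)]
    data = pd.DataFrame(values, index=pd.Index(tids, name="transcript_id"), columns=sample_ids)
    data.insert(0, "gene_symbol", [f"G{i:05d}" for i in range(n)])
    data.insert(1, "cell_type", "synthetic cell type")
    data.insert(2, "ref_expression", 1.0)
    groups = SampleGroups(dict(zip(sample_ids, [ga] * n_a + [gb] * n_b)))
    planted = sorted(tids[i] for i in diff_rows)
    return AnnotatedMatrix(data=data), groups, planted
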