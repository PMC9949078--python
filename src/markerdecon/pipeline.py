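"""End-to-end orchestration: build-ref -> preprocess -> annotate -> compare -> variation.

A run is declared by a :class:`RunConfig` (YAML-loadable); every stage's
output is written to the run directory and a JSON manifest records input
checksums, the parameters used, and the row counts at each stage, so a rerun
with identical inputs and config reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import preprocess as pre
from . import reference as refmod
from . import stats as st
from . import variation as var
from .exceptions import MarkerDeconError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and tunables of a full pipeline run."""

    markers: list[str]
    counts: str
    groups: str
    out_dir: str
    qc: str | None = None
    marker_labels: list[str] | None = None
    # preprocessing
    offset: float = 1.0
    min_mean: float = 1.0
    trim_m: float = 0.3
    trim_a: float = 0.05
    cpm: bool = False
    # statistics
    fdr_q: float = 0.05
    welch: bool = False
    presence_threshold: float | None = None  # defaults to the offset
    exclusive_rule: str = "all-vs-none"
    # variation
    n_components: int = 3
    corr_pca: bool = False
    top_n: int = 40
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stats_config(self) -> st.StatsConfig:
        thr = self.offset if self.presence_threshold is None else self.presence_threshold
        return st.StatsConfig(
            fdr_q=self.fdr_q,
            welch_for_multiple=self.welch,
            presence_threshold=thr,
            exclusive_rule=self.exclusive_rule,  # type: ignore[arg-type]
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _resolve_marker_paths(markers: list[str]) -> list[Path]:
    paths: list[Path] = []
    for entry in markers:
        p = Path(entry)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.csv")) + sorted(p.glob("*.tsv")))
        else:
            paths.append(p)
    return paths


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("markerdecon")
    root.addHandler(handler)
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))

    manifest: dict = {"parameters": dataclasses.asdict(cfg), "stages": {}}
    stage = "setup"
    try:
        marker_paths = _resolve_marker_paths(cfg.markers)
        for p in [*marker_paths, cfg.counts, cfg.groups] + ([cfg.qc] if cfg.qc else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        manifest["inputs"] = {str(p): _sha256(p) for p in marker_paths}
        manifest["inputs"][str(cfg.counts)] = _sha256(cfg.counts)
        manifest["inputs"][str(cfg.groups)] = _sha256(cfg.groups)
        if cfg.qc:
            manifest["inputs"][str(cfg.qc)] = _sha256(cfg.qc)

        stage = "build_reference"
        records = refmod.load_marker_tables(marker_paths, cfg.marker_labels)
        ref = refmod.build_reference(records, provenance=";".join(map(str, marker_paths)))
        refmod.write_reference(ref, out_dir / "reference.csv")
        # downstream stages consume the written artifact, so a chained run is
        # file-for-file identical to running the stage commands by hand
        ref = refmod.read_reference(out_dir / "reference.csv")
        manifest["stages"][stage] = {
            "n_marker_records": int(len(records)),
            "n_unique_genes": ref.n_genes,
            "n_cell_types": len(ref.cell_types),
        }
        logger.info("reference: %d unique genes, %d cell types", ref.n_genes, len(ref.cell_types))

        stage = "preprocess"
        groups = pre.SampleGroups.from_csv(cfg.groups)
        raw = pre.read_matrix(cfg.counts)
        groups.validate_against(raw.sample_ids)
        norm, norm_res = pre.tmm_normalize(
            raw, trim_m=cfg.trim_m, trim_a=cfg.trim_a, offset=cfg.offset, cpm=cfg.cpm
        )
        filtered = pre.filter_low_expression(norm, threshold=cfg.min_mean)
        pre.write_matrix(filtered, out_dir / "normalized.csv")
        filtered = pre.read_matrix(out_dir / "normalized.csv", normalized=True)
        manifest["stages"][stage] = {
            "n_transcripts_raw": raw.shape[0],
            "n_samples": raw.shape[1],
            "n_transcripts_after_filter": filtered.shape[0],
            "tmm_factors": {s: float(f) for s, f in norm_res.factors.items()},
            "tmm_reference_sample": norm_res.reference_sample,
        }

        stage = "annotate"
        annotated = ann.annotate_matrix(filtered, ref)
        ann.write_annotated(annotated, out_dir / "annotated.csv")
        annotated = ann.read_annotated(out_dir / "annotated.csv")
        top = ann.top_expressed(annotated, n=min(cfg.top_n, annotated.n_transcripts), groups=groups)
        top.to_csv(out_dir / f"top{cfg.top_n}.csv", float_format="%.12g")
        manifest["stages"][stage] = dict(annotated.summary)

        stage = "compare"
        scfg = cfg.stats_config()
        tests = st.compare_groups(annotated, groups, scfg)
        tests.to_csv(out_dir / "transcript_tests.csv", float_format="%.12g")
        presence = st.presence_table(annotated, groups, scfg)
        presence.to_csv(out_dir / "presence.csv", index=False)
        excl = st.exclusive_genes(annotated, groups, scfg)
        ga, gb = groups.pair()
        pd.DataFrame(
            [(g, sym) for g in (ga, gb) for sym in excl[g]], columns=["group", "gene_symbol"]
        ).to_csv(out_dir / "exclusive_genes.csv", index=False)
        manifest["stages"][stage] = {
            "n_tests": int(len(tests)),
            "n_significant_fdr": int(tests["significant"].sum()),
            "n_raw_p_below_q": int((tests["p"] < scfg.fdr_q).sum()),
            "n_cell_types_detected": presence.attrs["n_cell_types_detected"],
            "exclusive_genes": {g: list(excl[g]) for g in (ga, gb)},
        }
        if cfg.qc:
            qc = pd.read_csv(cfg.qc).set_index("sample_id")
            qc_res = st.compare_qc_metrics(qc, groups)
            qc_res.to_csv(out_dir / "qc_comparison.csv", index=False, float_format="%.12g")
            manifest["stages"]["qc"] = {
                "n_metrics": int(len(qc_res)),
                "significant_metrics": qc_res.loc[qc_res["p"] < 0.05, "metric"].tolist(),
            }

        stage = "variation"
        cv = var.cv_by_group(filtered, groups)
        cv.to_csv(out_dir / "cv.csv", float_format="%.12g")
        var.cv_scatter(cv, out_dir / "cv_scatter.png", out_dir / "cv_scatter.csv")
        n_comp = min(cfg.n_components, len(filtered.sample_ids) - 1, filtered.shape[0])
        pres = var.pca(filtered, groups, n_components=n_comp, scale=cfg.corr_pca)
        pres.scores.rename_axis("sample_id").to_csv(out_dir / "pca_scores.csv", float_format="%.12g")
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pres.explained_pct))],
                "explained_pct": pres.explained_pct,
            }
        ).to_csv(out_dir / "pca_explained.csv", index=False, float_format="%.12g")
        pres.ellipsoids.to_csv(out_dir / "pca_ellipsoids.csv", index=False, float_format="%.12g")
        var.pca_plot(pres, groups, out_dir / "pca.png")
        manifest["stages"][stage] = {
            "n_cv_records": int(len(cv)),
            "explained_pct_top": [float(x) for x in pres.explained_pct[:n_comp]],
        }
    except (MarkerDeconError, FileNotFoundError, ValueError) as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        root.removeHandler(handler)
        handler.close()
        raise MarkerDeconError(f"pipeline aborted at stage {stage!r}: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    root.removeHandler(handler)
    handler.close()
    return manifest
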