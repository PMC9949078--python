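import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import markerdecon as md
from markerdecon.simulate import SimulationConfig, simulate_all

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One small simulated study: 10 cell types (2 absent), 3 female-exclusive genes."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(
        n_cell_types=10,
        markers_per_type=3,
        n_shared_markers=4,
        n_background_genes=300,
        zero_weight_cell_types=2,
        n_exclusive_genes=(3, 0),
        seed=7,
    )
    paths, gt = simulate_all(cfg, out)
    return cfg, paths, gt


@pytest.fixture(scope="session")
def sim_processed(sim_run):
    """The simulated study pushed through reference building, TMM and annotation."""
    cfg, paths, gt = sim_run
    ref = md.build_reference(md.load_marker_tables(paths["markers"]))
    raw = md.read_matrix(paths["counts"])
    groups = md.SampleGroups.from_csv(paths["groups"])
    norm, norm_res = md.tmm_normalize(raw)
    filtered = md.filter_low_expression(norm)
    annotated = md.annotate_matrix(filtered, ref)
    return {
        "cfg": cfg,
        "paths": paths,
        "gt": gt,
        "ref": ref,
        "raw": raw,
        "groups": groups,
        "norm": norm,
        "norm_res": norm_res,
        "filtered": filtered,
        "annotated": annotated,
    }


@pytest.fixture
def tiny_matrix():
    """4 transcripts x 4 samples, already on the normalized scale."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 1.0, 5.0, 2.0],
            "s2": [12.0, 1.0, 6.0, 2.5],
            "s3": [11.0, 1.0, 5.5, 2.2],
            "s4": [13.0, 1.0, 6.5, 2.8],
        },
        index=pd.Index(["t1", "t2", "t3", "t4"], name="transcript_id"),
    )
    symbols = pd.Series(["NPHS2", "LEP", "NPHS2", "UMOD"], index=values.index)
    return md.ExpressionMatrix(values=values, gene_symbols=symbols, normalized=True)
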