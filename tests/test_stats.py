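"""t-tests, two-stage FDR, presence inference, exclusive genes, QC comparison."""
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from statsmodels.stats.multitest import multipletests

import markerdecon as md
from markerdecon.exceptions import ValidationError
from markerdecon.simulate import simulate_gaussian_groups
from markerdecon.stats import QC_METRICS, StatsConfig, stage1_rejections

from helpers import bh_reject, bky_reject_bruteforce

DATA = Path(__file__).parent / "data"

X8 = [101.3, 98.7, 105.2, 99.9, 102.4, 97.1, 103.8, 100.6]
Y9 = [104.9, 108.2, 103.1, 110.5, 106.7, 102.8, 109.3, 105.4, 107.6]


class TestTTests:
    def test_identical_groups(self):
        for fn in (md.welch_t, md.student_t):
            t, df, p = fn([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
            assert t == 0.0 and p == 1.0

    def test_permutation_invariance(self):
        t, df, p = md.welch_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_welch_matches_r_oracle(self):
        oracle = json.loads((DATA / "ttest_r_oracle.json").read_text())["welch_4v4"]
        t, df, p = md.welch_t([10, 12, 11, 13], [20, 19, 21, 22])
        assert t == pytest.approx(oracle["t"], abs=1e-10)
        assert df == pytest.approx(oracle["df"], abs=1e-10)
        assert p == pytest.approx(oracle["p"], abs=1e-10)

    def test_student_8v9_matches_r_oracle(self):
        oracle = json.loads((DATA / "ttest_r_oracle.json").read_text())["student_8v9"]
        t, df, p = md.student_t(X8, Y9)
        assert t == pytest.approx(oracle["t"], abs=1e-10)
        assert df == oracle["df"] == len(X8) + len(Y9) - 2
        assert p == pytest.approx(oracle["p"], abs=1e-10)

    def test_welch_8v9_matches_r_oracle(self):
        oracle = json.loads((DATA / "ttest_r_oracle.json").read_text())["welch_8v9"]
        t, df, p = md.welch_t(X8, Y9)
        assert (t, df, p) == pytest.approx((oracle["t"], oracle["df"], oracle["p"]), abs=1e-10)

    def test_welch_student_agree_for_large_equal_groups(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0.2, 1, 50)
        _, _, p_w = md.welch_t(x, y)
        _, _, p_s = md.student_t(x, y)
        assert abs(p_w - p_s) < 1e-3

    def test_group_too_small_rejected(self):
        with pytest.raises(ValidationError):
            md.welch_t([1.0], [2.0, 3.0])


class TestBKY:
    def test_all_p_one_rejects_nothing(self):
        q, rej = md.bky_two_stage(np.ones(10), 0.05)
        assert not rej.any()
        assert np.allclose(q, 1.0)

    def test_all_p_zero_rejects_everything(self):
        q, rej = md.bky_two_stage(np.zeros(10), 0.05)
        assert rej.all()

    def test_empty_input(self):
        q, rej = md.bky_two_stage([], 0.05)
        assert q.size == 0 and rej.size == 0

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            md.bky_two_stage([0.5, 1.2], 0.05)

    def test_fixed_25_pvalue_example(self):
        # frozen from the brute-force two-stage enumerator: stage 1 (BH at
        # 0.05/1.05) rejects only p=0.001, stage 2 at q'*25/24 adds nothing
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341,
                      0.384, 0.569, 0.594, 0.696, 0.762, 0.94, 0.942, 0.975, 0.986])
        q, rej = md.bky_two_stage(p, 0.05)
        expected = bky_reject_bruteforce(p, 0.05)
        assert (rej == expected).all()
        assert list(p[rej]) == [0.001]
        assert ((q >= 0) & (q <= 1)).all()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_on_random_vectors(self, seed):
        rng = np.random.default_rng([77, seed])
        m = int(rng.integers(1, 51))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        level = float(rng.uniform(0.01, 0.2))
        _, rej = md.bky_two_stage(p, level)
        assert (rej == bky_reject_bruteforce(p, level)).all()

    def test_stage1_equals_bh_at_shrunken_level(self):
        rng = np.random.default_rng(3)
        p = rng.random(40) ** 2
        assert (stage1_rejections(p, 0.05) == bh_reject(p, 0.05 / 1.05)).all()

    def test_agrees_with_statsmodels_multipletests(self):
        rng = np.random.default_rng(8)
        p = rng.random(60) ** 3
        _, rej = md.bky_two_stage(p, 0.05)
        rej_sm = multipletests(p, alpha=0.05, method="fdr_tsbky", maxiter=1)[0]
        assert (rej == rej_sm).all()

    @given(hst.integers(min_value=0, max_value=1000))
    def test_rejection_set_monotone_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(2, 40))) ** 2
        _, r_small = md.bky_two_stage(p, 0.02)
        _, r_big = md.bky_two_stage(p, 0.1)
        assert (r_big | ~r_small).all()  # r_small subset of r_big


class TestCompareGroups:
    def test_copied_groups_yield_no_significance(self):
        a, g, _ = simulate_gaussian_groups(n_null=50, n_diff=0, n_a=4, n_b=4, seed=1)
        ga, gb = g.pair()
        cols_a = g.samples(ga)
        # make group B an exact copy of group A
        for ca, cb in zip(cols_a, g.samples(gb)):
            a.data[cb] = a.data[ca]
        res = md.compare_groups(a, g)
        assert res["significant"].sum() == 0
        assert np.allclose(res["p"], 1.0)

    def test_extreme_separation_is_significant(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {
                "gene_symbol": ["G1"],
                "cell_type": ["X"],
                "ref_expression": [1.0],
                **{f"a{i}": [100.0 + rng.normal(0, 0.1)] for i in range(3)},
                **{f"b{i}": [0.0 + abs(rng.normal(0, 0.1))] for i in range(3)},
            },
            index=pd.Index(["t1"], name="transcript_id"),
        )
        g = md.SampleGroups({**{f"a{i}": "A" for i in range(3)}, **{f"b{i}": "B" for i in range(3)}})
        res = md.compare_groups(md.AnnotatedMatrix(data=data), g)
        assert bool(res["significant"].iloc[0])

    def test_constant_equal_transcript_gets_p_one(self):
        a, g, _ = simulate_gaussian_groups(n_null=5, n_diff=0, n_a=3, n_b=3, seed=3)
        a.data.loc[a.data.index[0], g.samples(g.pair()[0]) + g.samples(g.pair()[1])] = 7.0
        res = md.compare_groups(a, g)
        assert res["p"].iloc[0] == 1.0
        assert res["t"].iloc[0] == 0.0

    def test_permutation_within_groups_invariant(self):
        a, g, _ = simulate_gaussian_groups(n_null=30, n_diff=3, seed=4)
        res1 = md.compare_groups(a, g)
        ga, gb = g.pair()
        order = g.samples(ga)[::-1] + g.samples(gb)[::-1]
        a2 = md.AnnotatedMatrix(
            data=a.data[["gene_symbol", "cell_type", "ref_expression"] + order]
        )
        res2 = md.compare_groups(a2, g)
        pd.testing.assert_series_equal(res1["p"], res2["p"])
        pd.testing.assert_series_equal(res1["q"], res2["q"])

    def test_planted_effects_recovered(self):
        hits = 0
        fdps = []
        for seed in range(20):
            a, g, planted = simulate_gaussian_groups(
                n_null=200, n_diff=10, effect_sd=3.0, seed=seed
            )
            res = md.compare_groups(a, g)
            called = set(res.index[res["significant"]])
            hits += len(called & set(planted)) / len(planted)
            fdps.append(len(called - set(planted)) / max(1, len(called)))
        assert hits / 20 >= 0.9
        assert np.mean(fdps) <= 0.1

    def test_welch_option_changes_df_not_contract(self):
        a, g, _ = simulate_gaussian_groups(n_null=20, n_diff=0, seed=6)
        res_s = md.compare_groups(a, g, StatsConfig())
        res_w = md.compare_groups(a, g, StatsConfig(welch_for_multiple=True))
        assert (res_s["df"] == 15).all()
        assert (res_w["df"] <= 15 + 1e-9).all()


class TestPresence:
    def test_markers_at_floor_mean_absent(self):
        a, g, _ = simulate_gaussian_groups(n_null=3, n_diff=0, seed=7)
        a.data.loc[:, a.sample_ids] = 1.0  # exactly the +1 floor
        table = md.presence_table(a, g)
        ga, gb = g.pair()
        assert not table[f"present_{ga}"].any()
        assert not table[f"present_{gb}"].any()
        assert table.attrs["n_cell_types_detected"] == 0

    def test_single_strong_marker_present_in_both(self, sim_processed):
        a = sim_processed["annotated"]
        g = sim_processed["groups"]
        table = md.presence_table(a, g)
        gt = sim_processed["gt"]
        ga, gb = g.pair()
        present_a = set(table.loc[table[f"present_{ga}"], "cell_type"])
        assert present_a == set(gt.present_cell_types[ga])
        present_b = set(table.loc[table[f"present_{gb}"], "cell_type"])
        assert present_b == set(gt.present_cell_types[gb])

    def test_supporting_marker_counts_positive_where_present(self, sim_processed):
        table = md.presence_table(sim_processed["annotated"], sim_processed["groups"])
        ga, gb = sim_processed["groups"].pair()
        assert (table.loc[table[f"present_{ga}"], f"n_markers_{ga}"] >= 1).all()
        assert (table.loc[~table[f"present_{ga}"], f"n_markers_{ga}"] == 0).all()

    def test_presence_monotone_in_threshold(self, sim_processed):
        a, g = sim_processed["annotated"], sim_processed["groups"]
        ga, _ = g.pair()
        lo = md.presence_table(a, g, StatsConfig(presence_threshold=1.0))
        hi = md.presence_table(a, g, StatsConfig(presence_threshold=50.0))
        lo_set = set(lo.loc[lo[f"present_{ga}"], "cell_type"])
        hi_set = set(hi.loc[hi[f"present_{ga}"], "cell_type"])
        assert hi_set <= lo_set


class TestExclusiveGenes:
    def test_gene_in_both_groups_in_neither_list(self, sim_processed):
        a, g, gt = sim_processed["annotated"], sim_processed["groups"], sim_processed["gt"]
        excl = md.exclusive_genes(a, g)
        ga, gb = g.pair()
        planted = set(gt.exclusive_genes[ga]) | set(gt.exclusive_genes[gb])
        shared = set(a.data["gene_symbol"]) - planted
        assert not (set(excl[ga]) | set(excl[gb])) & shared

    def test_planted_exclusives_recovered_exactly(self, sim_processed):
        a, g, gt = sim_processed["annotated"], sim_processed["groups"], sim_processed["gt"]
        excl = md.exclusive_genes(a, g)
        ga, gb = g.pair()
        assert excl[ga] == gt.exclusive_genes[ga]
        assert excl[gb] == gt.exclusive_genes[gb]

    def test_all_vs_none_definition_forced(self):
        a, g, _ = simulate_gaussian_groups(n_null=2, n_diff=0, n_a=3, n_b=3, seed=9)
        ga, gb = g.pair()
        a.data.loc[a.data.index[0], g.samples(ga)] = 50.0
        a.data.loc[a.data.index[0], g.samples(gb)] = 1.0  # at the floor: not expressed
        a.data.loc[a.data.index[1], a.sample_ids] = 50.0
        excl = md.exclusive_genes(a, g)
        assert excl[ga] == [a.data["gene_symbol"].iloc[0]]
        assert excl[gb] == []

    def test_any_vs_none_relaxation(self):
        a, g, _ = simulate_gaussian_groups(n_null=1, n_diff=0, n_a=3, n_b=3, seed=10)
        ga, gb = g.pair()
        cols_a, cols_b = g.samples(ga), g.samples(gb)
        a.data.loc[a.data.index[0], cols_a] = [50.0, 1.0, 1.0]
        a.data.loc[a.data.index[0], cols_b] = 1.0
        strict = md.exclusive_genes(a, g, StatsConfig(exclusive_rule="all-vs-none"))
        relaxed = md.exclusive_genes(a, g, StatsConfig(exclusive_rule="any-vs-none"))
        assert strict[ga] == []
        assert relaxed[ga] == [a.data["gene_symbol"].iloc[0]]

    def test_lists_disjoint_between_groups(self, sim_processed):
        excl = md.exclusive_genes(sim_processed["annotated"], sim_processed["groups"])
        ga, gb = sim_processed["groups"].pair()
        assert not set(excl[ga]) & set(excl[gb])


class TestQCComparison:
    def _qc(self, seed=0, shift=None):
        from markerdecon.simulate import SimulationConfig, simulate_qc

        cfg = SimulationConfig(n_cell_types=2, n_background_genes=10, seed=seed)
        import tempfile

        path = Path(tempfile.mkdtemp()) / "qc.csv"
        simulate_qc(cfg, path, metric_shift=shift)
        qc = pd.read_csv(path).set_index("sample_id")
        groups = md.SampleGroups(
            {s: ("female" if s.startswith("F") else "male") for s in qc.index}
        )
        return qc, groups

    def test_identical_groups_give_p_one(self):
        qc, g = self._qc()
        fem = qc.iloc[:8].values  # mirror one group's block into the other
        res = md.compare_qc_metrics(
            pd.DataFrame(
                np.vstack([fem, fem]), columns=qc.columns,
                index=[f"F{i:02d}" for i in range(8)] + [f"M{i:02d}" for i in range(8)],
            ),
            md.SampleGroups(
                {**{f"F{i:02d}": "female" for i in range(8)},
                 **{f"M{i:02d}": "male" for i in range(8)}}
            ),
        )
        assert np.allclose(res["p"], 1.0)

    def test_planted_large_shift_detected(self):
        qc, g = self._qc(seed=1, shift={"avg_read_length": 10.0})  # 5 SD of 2.0
        res = md.compare_qc_metrics(qc, g).set_index("metric")
        assert res.loc["avg_read_length", "p"] < 0.001

    def test_fixture_pvalues_match_welch_oracle(self):
        qc, g = self._qc(seed=2)
        res = md.compare_qc_metrics(qc, g).set_index("metric")
        ga, gb = g.pair()
        for metric in QC_METRICS:
            x = qc.loc[[s for s in qc.index if g.mapping[s] == ga], metric].values
            y = qc.loc[[s for s in qc.index if g.mapping[s] == gb], metric].values
            t, df, p = md.welch_t(x, y)
            assert res.loc[metric, "p"] == pytest.approx(p, abs=1e-12)

    def test_missing_values_skip_metric_with_warning(self):
        qc, g = self._qc(seed=3)
        qc.loc[qc.index[0], "avg_depth"] = np.nan
        with pytest.warns(UserWarning, match="avg_depth"):
            res = md.compare_qc_metrics(qc, g)
        assert "avg_depth" not in set(res["metric"])
        assert len(res) == len(QC_METRICS) - 1
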