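import math

import numpy as np
import pandas as pd
import pytest

import eegoracle as eo
from eegoracle.selection import ConfigSummary, selection_table


def _summary(family, rrmse, tdec, grid_index, kind="eog", bin_="ALL", values=None):
    cfg = eo.enumerate_grid(family)[grid_index]
    values = np.asarray(values if values is not None else [rrmse - 0.01, rrmse + 0.01])
    return ConfigSummary(
        family=family, kind=kind, bin=bin_, config=cfg, grid_index=grid_index,
        n=values.size, mean_rrmse=rrmse, sd_rrmse=float(values.std(ddof=1)),
        mean_pcc=0.9, sd_pcc=0.01, mean_tdec=tdec, rrmse_values=values,
    )


def _results_frame(config_specs, kinds=("eog",), bins=("[-10,-5)", "[-5,0)", "[0,5)", "[5,10]"),
                   n_per_bin=4, family="vmd"):
    """Synthetic per-epoch results with controlled per-config RRMSE offsets."""
    rng = np.random.default_rng(0)
    rows = []
    for kind in kinds:
        for b in bins:
            base = rng.uniform(0.3, 0.5, size=n_per_bin)
            for grid_index, offset, tdec in config_specs:
                cfg = eo.enumerate_grid(family)[grid_index]
                for i in range(n_per_bin):
                    rows.append(
                        {
                            "epoch_id": f"{kind}-{b}-{i}",
                            "kind": kind,
                            "bin": b,
                            "family": family,
                            "config_label": cfg.label,
                            "rrmse": base[i] + offset,
                            "pcc": 0.9,
                            "t_dec": tdec,
                        }
                    )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_computed_mean_and_sd(self):
        df = _results_frame([(0, 0.0, 0.01)], bins=("[0,5)",), n_per_bin=2)
        df["rrmse"] = [0.2, 0.4]
        (s,) = eo.summarize(df)
        assert s.mean_rrmse == pytest.approx(0.3)
        assert s.sd_rrmse == pytest.approx(0.1414, abs=1e-4)

    def test_unequal_epoch_sets_rejected(self):
        df = _results_frame([(0, 0.0, 0.01), (1, 0.1, 0.02)], bins=("[0,5)",))
        df = df.drop(df[(df["config_label"] == df["config_label"].iloc[-1])].index[:1])
        with pytest.raises(ValueError, match="paired design"):
            eo.summarize(df)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            eo.summarize(pd.DataFrame(columns=["epoch_id", "family", "kind", "bin",
                                               "config_label", "rrmse", "pcc", "t_dec"]))

    def test_nan_pcc_excluded_from_pcc_mean_only(self):
        df = _results_frame([(0, 0.0, 0.01)], bins=("[0,5)",), n_per_bin=3)
        df.loc[df.index[0], "pcc"] = np.nan
        (s,) = eo.summarize(df)
        assert s.n == 3
        assert s.mean_pcc == pytest.approx(0.9)


class TestSelectBest:
    def test_argmin_of_mean_rrmse(self):
        sums = [_summary("vmd", m, 0.1, i) for i, m in enumerate([0.5, 0.4, 0.6])]
        assert eo.select_best(sums).mean_rrmse == 0.4

    def test_tie_broken_by_latency_then_grid_order(self):
        tie = [_summary("vmd", 0.4, 0.2, 0), _summary("vmd", 0.4, 0.1, 1)]
        assert eo.select_best(tie).grid_index == 1
        same = [_summary("vmd", 0.4, 0.1, 2), _summary("vmd", 0.4, 0.1, 1)]
        assert eo.select_best(same).grid_index == 1


class TestCohensD:
    def test_identical_distributions(self):
        x = np.array([0.3, 0.4, 0.5])
        assert eo.cohens_d(x, x.copy()) == 0.0

    def test_hand_computed_value(self):
        assert eo.cohens_d(np.array([1.0, 2, 3]), np.array([2.0, 3, 4])) == pytest.approx(-1.0)

    def test_zero_spread_unequal_means_flags_infinity(self):
        assert eo.cohens_d(np.ones(3) * 2, np.ones(3)) == math.inf
        assert eo.cohens_d(np.ones(3), np.ones(3) * 2) == -math.inf


class TestOpt1:
    def test_singleton_tolerance_set_returns_best(self):
        best = _summary("vmd", 0.4, 0.2, 0, values=[0.39, 0.41])
        far = _summary("vmd", 0.9, 0.01, 1, values=[0.89, 0.91])
        opt1, d = eo.select_opt1([best, far], best, d0=0.05)
        assert opt1 is best and d == 0.0

    def test_fastest_tolerance_member_wins(self):
        best = _summary("vmd", 0.4, 0.12, 0, values=[0.39, 0.41])
        near = _summary("vmd", 0.4001, 0.06, 1, values=[0.3901, 0.4101])
        opt1, d = eo.select_opt1([best, near], best, d0=0.05)
        assert opt1 is near and abs(d) <= 0.05

    def test_infinite_d0_gives_global_fastest(self):
        sums = [
            _summary("vmd", 0.4, 0.3, 0, values=[0.39, 0.41]),
            _summary("vmd", 0.9, 0.05, 1, values=[0.89, 0.91]),
        ]
        opt1, _ = eo.select_opt1(sums, sums[0], d0=math.inf)
        assert opt1 is sums[1]


class TestPareto:
    def test_dominated_point_removed(self):
        pts = [
            _summary("vmd", 0.4, 0.10, 0),
            _summary("vmd", 0.5, 0.05, 1),
            _summary("vmd", 0.6, 0.20, 2),
        ]
        front = eo.pareto_front(pts)
        assert [s.grid_index for s in front] == [0, 1]

    def test_singleton(self):
        pts = [_summary("vmd", 0.4, 0.1, 0)]
        assert eo.pareto_front(pts) == pts

    def test_opt2_tie_breaks_to_lower_rrmse(self):
        pts = [_summary("vmd", 0.4, 0.10, 0), _summary("vmd", 0.5, 0.05, 1)]
        opt2, front = eo.select_opt2(pts)
        assert opt2.grid_index == 0
        assert len(front) == 2

    def test_opt2_invariant_to_affine_latency_rescaling(self):
        rng = np.random.default_rng(3)
        pts = [
            _summary("vmd", float(r), float(t), i)
            for i, (r, t) in enumerate(zip(rng.uniform(0.3, 0.7, 8), rng.uniform(0.01, 0.3, 8)))
        ]
        ref, _ = eo.select_opt2(pts)
        scaled = [
            _summary("vmd", p.mean_rrmse, p.mean_tdec * 1000.0 + 5.0, p.grid_index) for p in pts
        ]
        out, _ = eo.select_opt2(scaled)
        assert out.grid_index == ref.grid_index


class TestRunSelection:
    def test_strata_counts_and_invariants(self):
        df = _results_frame([(0, 0.0, 0.03), (3, 0.001, 0.01), (10, 0.3, 0.002)])
        triples = eo.run_selection(df, d0=0.05)
        assert len(triples) == 5  # 4 bins + ALL for one (family, kind)
        for t in triples:
            assert abs(t.d_opt1) <= 0.05
            assert t.opt2.config in t.pareto_set
            assert t.best.mean_rrmse == min(
                s.mean_rrmse for s in [t.best, t.opt1, t.opt2]
            )

    def test_vmd_small_k_excluded_from_opt2_only(self):
        # K=4 (grid 0) dominates on both objectives, but sits below the K floor
        df = _results_frame([(0, 0.0, 0.001), (8, 0.05, 0.01)])  # K=4 vs K=12
        triples = eo.run_selection(df, d0=1e-9)
        for t in triples:
            assert t.best.config["K"] == 4
            assert t.opt2.config["K"] == 12
        # disabling the floor lets the dominant config win Opt2 as well
        triples = eo.run_selection(df, d0=1e-9, vmd_opt2_k_floor=None)
        assert all(t.opt2.config["K"] == 4 for t in triples)

    def test_missing_family_cell_reported(self):
        df = pd.concat(
            [
                _results_frame([(0, 0.0, 0.01)], family="vmd"),
                _results_frame([(0, 0.0, 0.02)], family="ssa"),
            ],
            ignore_index=True,
        )
        df = df[~((df["family"] == "ssa") & (df["bin"] == "[0,5)"))]
        with pytest.raises(ValueError, match="missing"):
            eo.run_selection(df)

    def test_thin_strata_skipped_for_all_families(self):
        df = _results_frame([(0, 0.0, 0.01), (3, 0.01, 0.02)], n_per_bin=4)
        # leave a single epoch in one bin: that stratum must be skipped, not fatal
        drop = (df["bin"] == "[5,10]") & (df["epoch_id"] != "eog-[5,10]-0")
        triples = eo.run_selection(df[~drop])
        assert {(t.kind, t.bin) for t in triples} == {
            ("eog", "[-10,-5)"), ("eog", "[-5,0)"), ("eog", "[0,5)"), ("eog", "ALL"),
        }

    def test_report_table_shape(self):
        df = _results_frame([(0, 0.0, 0.03), (3, 0.001, 0.01)])
        table = selection_table(eo.run_selection(df))
        assert len(table) == 5
        assert {"best", "opt1", "opt2", "d_opt1"} <= set(table.columns)
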