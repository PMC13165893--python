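import numpy as np
import pytest

import eegoracle as eo
from eegoracle.mixture import ALL_BIN, BIN_LABELS, binning_axis


class TestGainForNsr:
    def test_equal_powers_at_0db(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert eo.gain_for_nsr(0.0, x, x.copy()) == pytest.approx(1.0)

    def test_plus_10db(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert eo.gain_for_nsr(10.0, x, x.copy()) == pytest.approx(np.sqrt(10.0), rel=1e-12)

    def test_roundtrip_recovers_target(self):
        rng = np.random.default_rng(0)
        X = 2.0 * rng.standard_normal(250)  # mean power 4-ish
        N = rng.standard_normal(250)
        lam = eo.gain_for_nsr(-10.0, X, N)
        measured = 10 * np.log10(np.mean((lam * N) ** 2) / np.mean(X**2))
        assert measured == pytest.approx(-10.0, abs=1e-12)

    def test_closed_form_value(self):
        X = np.full(10, 2.0)  # mean power 4
        N = np.array([1.0, -1.0] * 5)  # mean power 1
        assert eo.gain_for_nsr(-10.0, X, N) == pytest.approx(np.sqrt(0.4), rel=1e-12)

    def test_zero_power_errors(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            eo.gain_for_nsr(0.0, x, np.zeros(10))
        with pytest.raises(ValueError):
            eo.gain_for_nsr(0.0, np.zeros(10), x)


class TestSplitTotal:
    def test_even_split_at_0db(self):
        assert eo.split_total(0.0, 0.5) == pytest.approx((0.5, 0.5))

    def test_boundary_share(self):
        q_eog, q_emg = eo.split_total(5.0, 1.0)
        assert q_emg == 0.0 and q_eog == pytest.approx(10 ** 0.5)

    def test_quarter_share_at_10db(self):
        assert eo.split_total(10.0, 0.25) == pytest.approx((2.5, 7.5))

    def test_bad_share_rejected(self):
        with pytest.raises(ValueError):
            eo.split_total(0.0, 1.5)


class TestSampleShare:
    def test_uniform_mean(self):
        rng = np.random.default_rng(1)
        draws = [eo.sample_share("uniform", 0.0, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_increasing_at_top_is_beta_5_1(self):
        rng = np.random.default_rng(2)
        draws = [eo.sample_share("increasing", 10.0, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(5 / 6, abs=0.01)

    def test_increasing_decreasing_symmetric(self):
        rng = np.random.default_rng(3)
        inc = np.mean([eo.sample_share("increasing", 5.0, rng) for _ in range(100_000)])
        dec = np.mean([eo.sample_share("decreasing", 5.0, rng) for _ in range(100_000)])
        assert inc + dec == pytest.approx(1.0, abs=0.01)

    def test_unknown_pattern(self):
        with pytest.raises(ValueError, match="pattern"):
            eo.sample_share("quadratic", 0.0, np.random.default_rng(0))


class TestBuildBenchmark:
    def test_counts_and_kinds(self, small_benchmark):
        kinds = [e.kind for e in small_benchmark]
        assert kinds.count("eog") == 10 and kinds.count("emg") == 10 and kinds.count("mixed") == 10

    def test_floor_convention(self, pools):
        rng = np.random.default_rng(4)
        epochs = eo.build_benchmark(pools, eo.BenchmarkConfig(n_eog=3, n_emg=0, n_mixed=0), rng)
        assert len(epochs) == 3
        for e in epochs:
            assert e.kind == "eog"
            assert e.Z_emg == -10.0
            assert np.array_equal(e.N_emg_scaled, np.zeros(250))

    def test_construction_identity_machine_precision(self, small_benchmark):
        for e in small_benchmark:
            assert np.array_equal(e.Y, e.X + e.N_eog_scaled + e.N_emg_scaled)

    def test_label_recovery_within_1e9_db(self, small_benchmark):
        for e in small_benchmark:
            if np.any(e.N_eog_scaled):
                z = 10 * np.log10(np.mean(e.N_eog_scaled**2) / np.mean(e.X**2))
                assert z == pytest.approx(e.Z_eog, abs=1e-9)
            if np.any(e.N_emg_scaled):
                z = 10 * np.log10(np.mean(e.N_emg_scaled**2) / np.mean(e.X**2))
                assert z == pytest.approx(e.Z_emg, abs=1e-9)

    def test_mixed_pattern_allocation(self, pools):
        rng = np.random.default_rng(5)
        epochs = eo.build_benchmark(pools, eo.BenchmarkConfig(n_eog=0, n_emg=0, n_mixed=20), rng)
        patterns = [e.pattern for e in epochs]
        assert patterns.count("uniform") == 7
        assert patterns.count("increasing") == 7
        assert patterns.count("decreasing") == 6

    def test_empty_pool_rejected(self, pools):
        with pytest.raises(ValueError, match="empty exemplar pool"):
            eo.build_benchmark({**pools, "emg": []}, eo.BenchmarkConfig(n_eog=1, n_emg=1, n_mixed=0),
                               np.random.default_rng(0))


class TestAssignBin:
    def _epoch(self, kind, z):
        x = np.sin(np.arange(250))
        n = np.cos(np.arange(250)) * eo.gain_for_nsr(z, x, np.cos(np.arange(250)))
        kw = dict(Y=x + n, X=x, epoch_id="t", kind=kind)
        if kind == "eog":
            return eo.Epoch(N_eog_scaled=n, N_emg_scaled=np.zeros(250), Z_eog=z, Z_emg=-10,
                            Z_tot=z, **kw)
        return eo.Epoch(N_eog_scaled=np.zeros(250), N_emg_scaled=n, Z_eog=-10, Z_emg=z,
                        Z_tot=z, **kw)

    def test_half_open_lower_edge(self):
        assert eo.assign_bin(self._epoch("eog", -5.0)) == "[-5,0)"

    def test_top_bin_closed(self):
        assert eo.assign_bin(self._epoch("emg", 10.0)) == "[5,10]"

    def test_out_of_range_rejected(self):
        e = self._epoch("eog", 0.0)
        e.Z_eog = 11.0
        with pytest.raises(ValueError, match="outside"):
            eo.assign_bin(e)

    def test_bins_partition_the_benchmark(self, small_benchmark):
        per_kind = {}
        for e in small_benchmark:
            per_kind.setdefault(e.kind, []).append(eo.assign_bin(e))
        for kind, bins in per_kind.items():
            assert len(bins) == 10
            assert set(bins) <= set(BIN_LABELS)

    def test_axis_follows_kind(self, small_benchmark):
        for e in small_benchmark:
            expected = {"eog": e.Z_eog, "emg": e.Z_emg, "mixed": e.Z_tot}[e.kind]
            assert binning_axis(e) == expected


class TestNoisyBaseline:
    def test_single_artifact_closed_form(self, small_benchmark):
        for e in small_benchmark:
            if e.kind == "mixed":
                continue
            z = e.Z_eog if e.kind == "eog" else e.Z_emg
            assert eo.noisy_baseline_rrmse(e) == pytest.approx(10 ** (z / 20), abs=1e-9)

    def test_mixed_exact_norm_identity(self, small_benchmark):
        for e in small_benchmark:
            if e.kind != "mixed":
                continue
            expected = np.linalg.norm(e.N_eog_scaled + e.N_emg_scaled) / np.linalg.norm(e.X)
            assert eo.noisy_baseline_rrmse(e) == pytest.approx(expected, abs=1e-12)
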