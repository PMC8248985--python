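import numpy as np
import pandas as pd
import pytest

from conftest import dip_lp_oracle
from etype_sync.synthetic import gen_waveform
from etype_sync.waveforms import (
    compute_metrics,
    dip_statistic,
    dip_test_calibrated,
    normalize_align,
    split_narrow_broad,
)

DT = 1.0 / 32000.0
STEP_FINE = 1.0 / 320000.0


class TestNormalizeAlign:
    def test_negative_gaussian_pulse_aligns_to_minimum(self):
        t = np.arange(0, 3e-3, DT)
        raw = -np.exp(-0.5 * ((t - 1e-3) / 2e-4) ** 2)
        w = normalize_align(raw)
        assert w.samples.min() == pytest.approx(-1.0)
        assert abs(w.time()[np.argmin(w.samples)]) < STEP_FINE
        assert w.samples[w.trough_index] == pytest.approx(-1.0)

    def test_w_shaped_waveform_rejected(self):
        t = np.arange(0, 3e-3, DT)
        raw = -np.exp(-0.5 * ((t - 1e-3) / 1e-4) ** 2) - np.exp(
            -0.5 * ((t - 2e-3) / 1e-4) ** 2
        )
        with pytest.raises(ValueError, match="double"):
            normalize_align(raw)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_align(np.zeros(16))


class TestComputeMetrics:
    @pytest.mark.parametrize("t2p_ms", [0.2, 0.3, 0.6, 1.0])
    def test_generator_roundtrip_within_one_interpolated_step(self, t2p_ms):
        w = gen_waveform(t2p_ms, noise_sd=0.0)
        m = compute_metrics(normalize_align(w.samples))
        assert abs(m.T2P - t2p_ms * 1e-3) <= STEP_FINE

    def test_triangular_peak_t4r_quarter_halfwidth(self):
        # symmetric triangle of half-width h after the trough: the 75%
        # crossing on a linear flank sits at 0.25 h past the peak
        dt = STEP_FINE
        h = 0.5e-3
        t = np.arange(0, 3e-3, dt)
        tri = np.maximum(0.0, 1.0 - np.abs(t - 1.5e-3) / h)
        raw = tri - 2.0 * np.exp(-0.5 * ((t - 0.5e-3) / 5e-5) ** 2)
        from etype_sync.datatypes import Waveform

        w = Waveform(samples=raw, dt=dt)
        m = compute_metrics(w)
        assert m.T4R == pytest.approx(0.25 * h, rel=0.01)

    def test_linear_rise_hr_is_inverse_037_rise_time(self):
        dt = STEP_FINE
        r = 0.4e-3
        t = np.arange(0, 2e-3, dt)
        rise = np.clip((t - 1.0e-3) / r, 0.0, 1.0)
        fall = np.where(t > 1.0e-3 + r, 1.0 - (t - 1.0e-3 - r) / r, 1.0)
        raw = np.minimum(rise, np.clip(fall, 0, 1)) - 2.0 * np.exp(
            -0.5 * ((t - 0.4e-3) / 4e-5) ** 2
        )
        from etype_sync.datatypes import Waveform

        m = compute_metrics(Waveform(samples=raw, dt=dt))
        assert m.HR == pytest.approx(1.0 / (0.37 * r), rel=0.02)

    def test_amplitude_and_offset_invariance(self):
        w = gen_waveform(0.4, noise_sd=0.0)
        m1 = compute_metrics(normalize_align(w.samples))
        m2 = compute_metrics(normalize_align(17.0 * w.samples + 3.0))
        assert m1.T2P == pytest.approx(m2.T2P)
        assert m1.T4R == pytest.approx(m2.T4R)
        assert m1.HR == pytest.approx(m2.HR)

    def test_no_post_trough_peak_errors(self):
        from etype_sync.datatypes import Waveform

        raw = -np.linspace(0, 1, 64)  # monotone fall, trough at the end
        with pytest.raises(ValueError):
            compute_metrics(Waveform(samples=raw, dt=DT))


class TestGenWaveform:
    def test_noise_increases_metric_variance(self):
        t2ps = {sd: [] for sd in (0.0, 0.05, 0.15)}
        for sd in t2ps:
            for seed in range(15):
                w = gen_waveform(0.35, noise_sd=sd, seed=seed)
                m = compute_metrics(normalize_align(w.samples))
                t2ps[sd].append(m.T2P)
        v = {sd: np.var(vals) for sd, vals in t2ps.items()}
        assert v[0.0] <= v[0.05] <= v[0.15]

    def test_out_of_range_t2p_rejected(self):
        with pytest.raises(ValueError):
            gen_waveform(0.01)
        with pytest.raises(ValueError):
            gen_waveform(2.0)


class TestDipStatistic:
    def test_exact_small_cases(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)
        assert dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25)
        assert dip_statistic(np.full(20, 3.0)) == 0.0
        n = 10
        assert dip_statistic(np.arange(n)) == pytest.approx(1.0 / (2 * n))

    def test_matches_lp_oracle_on_random_small_samples(self):
        rng = np.random.default_rng(3)
        for trial in range(25):
            n = int(rng.integers(4, 11))
            if trial % 3 == 0:
                x = rng.normal(size=n)
            elif trial % 3 == 1:
                x = np.concatenate(
                    [rng.normal(-4, 1, n // 2), rng.normal(4, 1, n - n // 2)]
                )
            else:
                x = rng.integers(0, 4, n).astype(float)
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        d = dip_statistic(x)
        assert dip_statistic(5.0 * x - 3.0) == pytest.approx(d)


class TestDipTestCalibrated:
    def test_constant_vector_gives_p_one(self):
        d, p = dip_test_calibrated(np.full(50, 2.0), n_boot=50, seed=0)
        assert d == 0.0
        assert p == 1.0

    def test_bimodal_sample_rejected_at_small_p(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 1, 250), rng.normal(3, 1, 250)])
        _, p = dip_test_calibrated(x, n_boot=1000, seed=1)
        assert p < 0.001

    def test_unimodal_gaussian_usually_not_rejected(self):
        rng = np.random.default_rng(6)
        _, p = dip_test_calibrated(rng.normal(size=500), n_boot=300, seed=2)
        assert p > 0.05

    def test_type_one_error_near_nominal(self):
        # Gaussian nulls against the uniform calibration: rejection rate at
        # alpha=0.05 should sit at or below alpha (Gaussians are "more
        # unimodal" than the uniform null); the shared null table is the
        # standard Monte-Carlo calibration trick.
        rng = np.random.default_rng(7)
        n = 120
        null = np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(400)])
        rejections = 0
        runs = 400
        crit = np.quantile(null, 0.95)
        for _ in range(runs):
            rejections += dip_statistic(rng.normal(size=n)) > crit
        rate = rejections / runs
        se = np.sqrt(0.05 * 0.95 / runs)
        assert rate < 0.05 + 2 * se

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            dip_test_calibrated(np.arange(5), n_boot=10)


class TestSplitNarrowBroad:
    def _metrics(self, rng, n_per, sep):
        hr_a = rng.normal(3000.0, 200.0, n_per)
        hr_b = rng.normal(3000.0 + sep * 200.0, 200.0, n_per)
        t4r_a = rng.normal(4e-4, 4e-5, n_per)
        t4r_b = rng.normal(2.2e-4, 4e-5, n_per)
        return pd.DataFrame(
            {"HR": np.r_[hr_a, hr_b], "T4R": np.r_[t4r_a, t4r_b]}
        ), np.r_[np.zeros(n_per, bool), np.ones(n_per, bool)]

    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(8)
        metrics, truth = self._metrics(rng, 60, sep=5.0)
        narrow, report = split_narrow_broad(metrics, seed=0)
        assert report["two_components_preferred"]
        assert np.mean(narrow == truth) >= 0.95
        assert report["weights"].sum() == pytest.approx(1.0)

    def test_single_cluster_prefers_one_component(self):
        wins = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            metrics = pd.DataFrame(
                {
                    "HR": rng.normal(3000, 300, 60),
                    "T4R": rng.normal(3e-4, 5e-5, 60),
                }
            )
            _, report = split_narrow_broad(metrics, n_init=5, seed=seed)
            wins += report["bic"][("HR_T4R", 1)] <= report["bic"][("HR_T4R", 2)]
        assert wins > 15  # majority outcome over seeds

    def test_degenerate_feature_rejected(self):
        metrics = pd.DataFrame({"HR": np.full(40, 1.0), "T4R": np.arange(40.0)})
        with pytest.raises(ValueError, match="zero-variance|degenerate"):
            split_narrow_broad(metrics)

    def test_too_few_units_rejected(self):
        metrics = pd.DataFrame({"HR": np.arange(10.0), "T4R": np.arange(10.0)})
        with pytest.raises(ValueError):
            split_narrow_broad(metrics)
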