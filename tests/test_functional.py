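import numpy as np
import pytest

from etype_sync.datatypes import SpikeTrain
from etype_sync.functional import (
    class_correlation_test,
    class_effect_size,
    decode_classes,
    selectivity_proportion,
    sliding_correlation,
    spike_density,
    windowed_rates,
)
from etype_sync.synthetic import gen_spiketrain


@pytest.fixture(scope="module")
def poisson_events():
    train = gen_spiketrain(20.0, 400.0, seed=0)
    events = np.arange(5.0, 395.0, 4.0)
    return train, events


class TestSpikeDensity:
    def test_kernel_mass_conserves_spike_count(self):
        # isolated single spikes at the event: density integrates to 1
        events = np.arange(5.0, 100.0, 5.0)
        train = SpikeTrain("u", events.copy(), 105.0)
        rt = spike_density(train, events, t_range=(-0.5, 0.5), dt=0.005)
        integrals = rt.rate.sum(axis=1) * 0.005
        assert np.allclose(integrals, 1.0, atol=0.02)

    def test_homogeneous_train_has_flat_z_trace(self, poisson_events):
        train, events = poisson_events
        rt = spike_density(train, events)
        assert abs(np.nanmean(rt.zrate)) < 0.1

    def test_planted_step_raises_post_event_density(self):
        rng = np.random.default_rng(1)
        events = np.arange(5.0, 200.0, 4.0)
        times = []
        for ev in events:  # 5 Hz baseline, 25 Hz for 300 ms after event
            times.append(ev + rng.uniform(-2, 2, rng.poisson(20)))
            times.append(ev + rng.uniform(0, 0.3, rng.poisson(7.5)))
        times = np.unique(np.concatenate(times))
        train = SpikeTrain("u", times[(times > 0) & (times < 205)], 205.0)
        rt = spike_density(train, events)
        post = (rt.time > 0.1) & (rt.time < 0.2)
        pre = (rt.time > -0.4) & (rt.time < -0.2)
        assert rt.zrate[:, post].mean() > rt.zrate[:, pre].mean() + 1.0

    def test_silent_baseline_flagged(self):
        train = SpikeTrain("u", np.array([10.0]), 20.0)
        rt = spike_density(train, np.array([5.0]))
        assert rt.baseline_sd_zero


class TestSlidingCorrelation:
    def test_monotone_rate_gives_perfect_rho(self):
        n = 60
        var = np.linspace(0, 1, n)
        rates = np.tile((var**2)[:, None], (1, 5))  # monotone in var
        rho, sig = sliding_correlation(rates, var)
        assert np.allclose(rho, 1.0)
        assert sig.all()

    def test_null_significance_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        hits, total = 0, 0
        for _ in range(200):
            rates = rng.normal(size=(40, 3))
            var = rng.normal(size=40)
            _, sig = sliding_correlation(rates, var)
            hits += sig.sum()
            total += sig.size
        assert hits / total == pytest.approx(0.05, abs=0.02)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            sliding_correlation(np.random.default_rng(0).normal(size=(40, 3)), np.ones(40))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            sliding_correlation(np.zeros((10, 3)), np.arange(10.0))


class TestClassCorrelationTest:
    def test_planted_class_deviation_detected(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(0.0, 0.1, (40, 12))
        labels = np.array(["a"] * 10 + ["b"] * 30)
        maps[:10, 6:9] += 0.3
        out = class_correlation_test(maps, labels, n_boot=400, seed=4)
        assert out["a"]["significant"][6:9].any()
        assert not out["b"]["significant"][:6].any()

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(5)
        fp = 0
        for s in range(30):
            maps = rng.normal(size=(30, 10))
            labels = np.array(["a"] * 10 + ["b"] * 20)
            out = class_correlation_test(maps, labels, n_boot=200, seed=s)
            fp += out["a"]["significant"].any()
        assert fp <= 5


class TestSelectivity:
    def test_planted_condition_difference_detected(self):
        rng = np.random.default_rng(6)
        unit_rates, conds = [], []
        for u in range(12):
            cond = rng.random(60) < 0.5
            r = rng.normal(size=(60, 8))
            r[cond, 4:6] += 1.5  # selective in two windows
            unit_rates.append(r)
            conds.append(cond)
        out = selectivity_proportion(unit_rates, conds, n_boot=300, seed=7)
        assert out["significant"][4:6].all()
        assert not out["significant"][:3].any()

    def test_null_proportion_near_alpha(self):
        rng = np.random.default_rng(8)
        unit_rates = [rng.normal(size=(50, 6)) for _ in range(15)]
        conds = [rng.random(50) < 0.5 for _ in range(15)]
        out = selectivity_proportion(unit_rates, conds, n_boot=300, seed=9)
        assert abs(out["proportion"].mean() - 0.05) < 0.06
        assert not out["significant"].any()

    def test_units_without_enough_trials_excluded(self):
        rng = np.random.default_rng(10)
        r = rng.normal(size=(30, 4))
        all_one_cond = np.ones(30, dtype=bool)
        with pytest.raises(ValueError):
            selectivity_proportion([r], [all_one_cond], n_boot=10)


class TestEffectSize:
    def test_shifted_class_has_unit_effect_size(self):
        rng = np.random.default_rng(11)
        resp = rng.normal(0.0, 1.0, 300)
        labels = np.array(["pop"] * 280 + ["c"] * 20)
        resp[280:] += 1.0
        out = class_effect_size(resp, labels, n_boot=400, seed=12)
        assert out["c"] == pytest.approx(1.0, abs=0.25)

    def test_population_class_has_small_effect(self):
        rng = np.random.default_rng(13)
        resp = rng.normal(size=200)
        labels = np.array(["a"] * 100 + ["b"] * 100)
        out = class_effect_size(resp, labels, n_boot=400, seed=14)
        assert out["a"] < 0.3

    def test_affine_invariance(self):
        rng = np.random.default_rng(15)
        resp = rng.normal(size=120)
        labels = np.array(["a"] * 40 + ["b"] * 80)
        a = class_effect_size(resp, labels, n_boot=200, seed=16)["a"]
        b = class_effect_size(5.0 * resp - 2.0, labels, n_boot=200, seed=16)["a"]
        assert a == pytest.approx(b, abs=1e-9)


class TestDecoding:
    def test_confusion_rows_sum_to_one(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=60)
        labels = np.repeat(["a", "b", "c"], 20)
        out = decode_classes(vals, labels, n_sub=30, seed=18)
        assert np.allclose(out["confusion"].sum(axis=1), 1.0)

    def test_separable_class_is_decodable(self):
        rng = np.random.default_rng(19)
        labels = np.repeat(["a", "b", "c"], 20)
        vals = rng.normal(size=60) * 0.3
        vals[:20] += 3.0  # class "a" strongly shifted
        out = decode_classes(vals, labels, n_sub=100, seed=20)
        ia = list(out["classes"]).index("a")
        assert out["confusion"][ia, ia] > 1 / 3
        assert out["significant"][ia, ia]

    def test_small_classes_dissolved_into_noise(self):
        rng = np.random.default_rng(21)
        labels = np.array(["a"] * 20 + ["b"] * 20 + ["tiny"] * 3)
        vals = rng.normal(size=43)
        out = decode_classes(vals, labels, n_sub=20, seed=22)
        assert "tiny" not in out["classes"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decode_classes(np.zeros(10), np.array(["a"] * 10))


def test_windowed_rates_counts_in_hz(poisson_events):
    train, events = poisson_events
    centers = np.array([0.0])
    r = windowed_rates(train, events, centers, win_half=0.5)
    assert r.mean() == pytest.approx(train.rate, rel=0.1)
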