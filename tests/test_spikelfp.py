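import numpy as np
import pytest
from scipy.special import i0, i1

from etype_sync.datatypes import LfpChannel, SpikeTrain
from etype_sync.spikelfp import (
    PPCSpectrum,
    contrast_maps,
    detect_peaks,
    evoked_subtraction,
    peak_density,
    ppc,
    ppc_spectrum,
    rayleigh_p,
    remove_spike_artifacts,
    spike_phases,
    time_resolved_ppc,
)
from etype_sync.synthetic import (
    couple_spikes_in_windows,
    couple_spikes_to_lfp,
    gen_lfp,
    gen_spiketrain,
)


class TestArtifactRemoval:
    def test_no_spikes_is_identity(self):
        lfp = gen_lfp(5.0, seed=0)
        out = remove_spike_artifacts(lfp, np.array([]))
        assert np.array_equal(out.samples, lfp.samples)

    def test_delta_artifacts_on_sine_recover_power(self):
        fs = 1000.0
        t = np.arange(0, 20.0, 1 / fs)
        clean = np.cos(2 * np.pi * 10.0 * t)
        spikes = np.arange(0.5, 19.5, 0.23)
        dirty = clean.copy()
        dirty[np.round(spikes * fs).astype(int)] += 8.0
        lfp = LfpChannel("c", fs, dirty)
        out = remove_spike_artifacts(lfp, spikes)
        p_clean = np.mean(clean**2)
        p_out = np.mean(out.samples**2)
        assert abs(p_out - p_clean) / p_clean < 0.05

    def test_edge_spike_handled_one_sided(self):
        lfp = gen_lfp(2.0, seed=1)
        out = remove_spike_artifacts(lfp, np.array([0.0005, 1.0]))
        assert np.all(np.isfinite(out.samples))


class TestSpikePhasesAndPPC:
    def test_window_is_five_cycles(self):
        lfp = gen_lfp(10.0, components=((10.0, 1.0, 0.0),), noise_sd=0.0, seed=0)
        sp = spike_phases(np.array([0.2, 5.0]), lfp, freqs=np.array([10.0]))
        # 5 cycles at 10 Hz = 0.5 s: the spike at 0.2 s lacks a full window
        assert not sp.valid[0, 0]
        assert sp.valid[1, 0]

    def test_ppc_exact_degenerate_values(self):
        assert ppc(np.zeros(10)) == pytest.approx(1.0)
        assert ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            ppc(np.array([0.1]))

    def test_ppc_unbiased_for_uniform_phases(self):
        rng = np.random.default_rng(2)
        vals = [ppc(rng.uniform(-np.pi, np.pi, 50)) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.005

    def test_ppc_invariant_to_global_rotation(self):
        rng = np.random.default_rng(3)
        ph = rng.vonmises(0.0, 1.0, 500)
        assert ppc(ph + 1.234) == pytest.approx(ppc(ph), abs=1e-12)

    @pytest.mark.parametrize("kappa", [1.0, 4.0])
    def test_analytic_von_mises_ppc(self, kappa):
        rng = np.random.default_rng(4)
        ph = rng.vonmises(0.0, kappa, 10_000)
        expected = (i1(kappa) / i0(kappa)) ** 2
        assert ppc(ph) == pytest.approx(expected, abs=0.02)

    def test_rayleigh_detects_concentration(self):
        rng = np.random.default_rng(5)
        assert rayleigh_p(rng.vonmises(0.0, 2.0, 200)) < 1e-6
        assert rayleigh_p(rng.uniform(-np.pi, np.pi, 200)) > 0.01


class TestDetectPeaks:
    def _spectrum(self, y, p=None):
        f = np.arange(4.0, 81.0)
        return PPCSpectrum(
            freqs=f,
            ppc=np.asarray(y, dtype=float),
            n_spikes=np.full(f.size, 500),
            rayleigh_p=np.full(f.size, 1e-6) if p is None else p,
        )

    def test_flat_zero_spectrum_has_no_peaks(self):
        assert detect_peaks(self._spectrum(np.zeros(77))) == []

    def test_subthreshold_peak_rejected_by_ppc_floor(self):
        y = np.zeros(77)
        y[36] = 0.004  # below the 0.005 criterion
        assert detect_peaks(self._spectrum(y)) == []

    def test_planted_gamma_coupling_gives_single_banded_peak(self):
        lfp = gen_lfp(60.0, components=((40.0, 1.0),), noise_sd=0.3, seed=6)
        train = gen_spiketrain(9.0, 60.0, seed=7)
        c = couple_spikes_to_lfp(train, lfp, 40.0, 1.5, seed=8)
        assert c.n_spikes >= 400
        spec = ppc_spectrum(spike_phases(c.times, lfp))
        assert len(spec.peaks) == 1
        pk = spec.peaks[0]
        assert pk.band[0] <= 40 <= pk.band[1]
        assert pk.mass > pk.ppc

    def test_uncoupled_control_has_no_peaks(self):
        # the 0.005 absolute PPC floor is calibrated for session-scale
        # spike counts; controls therefore use ~2000 spikes
        for seed in (9, 19):
            lfp = gen_lfp(120.0, components=((40.0, 1.0),), noise_sd=0.3, seed=seed)
            train = gen_spiketrain(17.0, 120.0, seed=seed + 1)
            spec = ppc_spectrum(spike_phases(train.times, lfp))
            assert spec.peaks == []


class TestPeakDensity:
    def _population(self, coupled_class_size=8, other_size=24, seed=0):
        rng = np.random.default_rng(seed)
        lfp = gen_lfp(60.0, components=((40.0, 1.0),), noise_sd=0.3, seed=rng.integers(2**31))
        spectra, labels = [], []
        for i in range(coupled_class_size + other_size):
            train = gen_spiketrain(9.0, 60.0, seed=rng.integers(2**31))
            if i < coupled_class_size:
                train = couple_spikes_to_lfp(train, lfp, 40.0, 1.5, seed=rng.integers(2**31))
                labels.append("gamma")
            else:
                labels.append("other")
            spectra.append(ppc_spectrum(spike_phases(train.times, lfp)))
        return spectra, np.array(labels)

    def test_coupled_class_exceeds_population_ci_in_gamma(self):
        spectra, labels = self._population()
        out = peak_density(spectra, labels, n_boot=400, seed=1)
        freqs = spectra[0].freqs
        band = (freqs >= 35) & (freqs <= 45)
        assert out["gamma"]["exceeds"][band].any()
        assert not out["other"]["exceeds"][band].any()

    def test_identical_coupling_stays_within_ci_mostly(self):
        spectra, labels = self._population(coupled_class_size=0, other_size=24)
        labels = np.array(["a"] * 12 + ["b"] * 12)
        out = peak_density(spectra, labels, n_boot=400, seed=2)
        frac = np.mean([out[c]["exceeds"].mean() for c in ("a", "b")])
        assert frac < 0.1

    def test_small_class_excluded(self):
        spectra, labels = self._population(coupled_class_size=2, other_size=10)
        out = peak_density(spectra, labels, min_size=5, n_boot=50, seed=3)
        assert "gamma" not in out


class TestEvokedSubtraction:
    def test_identical_trials_leave_zero_residual(self):
        trials = np.tile(np.sin(np.linspace(0, 10, 500)), (12, 1))
        out = evoked_subtraction(trials)
        assert np.allclose(out, 0.0)

    def test_mean_of_corrected_trials_is_zero(self):
        rng = np.random.default_rng(8)
        out = evoked_subtraction(rng.normal(size=(20, 300)))
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_nonlocked_oscillation_ppc_preserved(self):
        # a phase-locked evoked bump rides on a non-locked oscillation;
        # subtracting the trial average removes the bump, not the locking
        # of spikes to the per-trial oscillation phase
        fs = 1000.0
        rng = np.random.default_rng(9)
        n_tr, n_s = 40, 1500
        t = np.arange(n_s) / fs
        bump = 2.0 * np.exp(-0.5 * ((t - 0.75) / 0.05) ** 2)
        trials = np.stack(
            [bump + np.cos(2 * np.pi * 10 * t + rng.uniform(-np.pi, np.pi)) for _ in range(n_tr)]
        )
        corrected = evoked_subtraction(trials)
        resid_bump = np.abs(corrected.mean(axis=0)).max()
        assert resid_bump < 0.05 * bump.max()
        # oscillation power per trial survives
        assert corrected.std(axis=1).mean() > 0.6

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            evoked_subtraction(np.zeros((5, 100)))


class TestTimeResolved:
    def _session(self, coupled="low", seed=0):
        rng = np.random.default_rng(seed)
        n_trials = 60
        events = 4.0 + 5.0 * np.arange(n_trials)
        duration = events[-1] + 3.0
        values = rng.uniform(0, 1, n_trials)
        lfp = gen_lfp(duration, components=((40.0, 1.0),), noise_sd=0.3,
                      seed=rng.integers(2**31))
        train = gen_spiketrain(25.0, duration, seed=rng.integers(2**31))
        if coupled is not None:
            med = np.median(values)
            sel = values <= med if coupled == "low" else values > med
            windows = [(ev, ev + 0.5) for ev in events[sel]]
            train = couple_spikes_in_windows(
                train, lfp, 40.0, 3.0, windows, seed=rng.integers(2**31)
            )
        return train, lfp, events, values

    def test_condition_restricted_coupling_localizes(self):
        train, lfp, events, values = self._session("low", seed=1)
        freqs = np.array([25.0, 40.0, 60.0])
        res = time_resolved_ppc(
            train, lfp, events, values, freqs=freqs,
            centers=np.arange(-0.4, 0.81, 0.2), n_sub=100, seed=2,
        )
        post = (res.centers >= 0.2) & (res.centers <= 0.4)
        pre = res.centers <= -0.2
        low40 = res.ppc["low"][:, 1]
        high40 = res.ppc["high"][:, 1]
        assert np.nanmean(low40[post]) > 0.1
        assert np.nanmean(low40[pre]) < 0.05
        assert np.nanmean(high40[post]) < 0.05

    def test_subsampling_removes_spike_count_bias(self):
        # doubling the firing rate must not change the expected PPC
        rng = np.random.default_rng(3)
        lfp = gen_lfp(200.0, components=((40.0, 1.0),), noise_sd=0.2, seed=4)
        vals = []
        for rate in (10.0, 20.0):
            train = gen_spiketrain(rate, 200.0, seed=5)
            c = couple_spikes_to_lfp(train, lfp, 40.0, 1.0, seed=6)
            sp = spike_phases(c.times, lfp, freqs=np.array([40.0]))
            ph = sp.phases[sp.valid[:, 0], 0]
            z = np.exp(1j * ph)
            sub = []
            for _ in range(300):
                pick = rng.choice(ph.size, 50, replace=False)
                R2 = np.abs(z[pick].sum()) ** 2
                sub.append((R2 - 50) / (50 * 49))
            vals.append(np.mean(sub))
        assert vals[0] == pytest.approx(vals[1], abs=0.03)


class TestContrastMaps:
    def _maps(self, n_units, shift=0.0, seed=0, shape=(10, 8)):
        rng = np.random.default_rng(seed)
        maps = rng.normal(1.0, 0.3, (n_units, *shape))
        if shift:
            maps[:, 5:8, 3:5] += shift
        return maps

    def test_label_swap_mirrors_difference(self):
        a = self._maps(8, 0.5, seed=1)
        b = self._maps(8, 0.0, seed=2)
        ab = contrast_maps(a, b, n_boot=200, seed=3)
        ba = contrast_maps(b, a, n_boot=200, seed=3)
        assert np.allclose(ab["difference"], -ba["difference"])

    def test_planted_difference_detected_post_event(self):
        a = self._maps(10, 1.0, seed=4)
        b = self._maps(10, 0.0, seed=5)
        centers = np.linspace(-0.5, 0.7, 10)
        out = contrast_maps(
            a, b, n_boot=400, centers=centers, band_axis=np.arange(8),
            band_window=(0.0, 0.5), seed=6,
        )
        assert out["significant"][5:8, 3:5].any()
        assert out["band_significant"].any()

    def test_identical_groups_rarely_significant(self):
        fp = 0
        for s in range(20):
            a = self._maps(8, 0.0, seed=100 + s)
            b = self._maps(8, 0.0, seed=200 + s)
            out = contrast_maps(a, b, n_boot=200, seed=s)
            fp += out["significant"].any()
        assert fp <= 4  # max-statistic correction: ~5% familywise

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            contrast_maps(self._maps(3), self._maps(8))
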