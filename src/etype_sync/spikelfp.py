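"""Spike-LFP phase synchronization: phases, PPC, peaks and condition contrasts.

Phase convention
----------------
The phase of a spike at frequency ``f`` is the argument of the Hann-tapered
discrete Fourier component of the LFP over an adaptive window of five
complete cycles (2.5 cycles either side of the spike), referenced to the
spike time with cosine convention: a spike on the crest of a cosine has
phase 0; on a rising zero-crossing, -pi/2.

Pairwise phase consistency (PPC) is the mean over all unordered spike pairs
of ``cos(theta_i - theta_j)``, computed through the algebraic identity
``(n^2 R^2 - n) / (n (n - 1))`` with ``R`` the resultant length; it is
unbiased by spike count (expectation 0 for uniform phases).

Peak detection applies four criteria to the 4-80 Hz PPC spectrum: Rayleigh
test p < 0.05 at the peak, PPC > 0.005, peak prominence >= 0.0025, and PPC
above 25% of the spectrum's range.

Time-resolved PPC uses +/-350 ms windows stepped every 50 ms around an
event, averaging PPC over random 50-spike subsamples (500 by default) to
remove spike-count bias, normalized to the pre-event baseline (-850..0 ms,
ratio).  Group contrasts are tested by a permutation scheme whose
multiple-comparison correction takes the most extreme 5% across the whole
time-frequency map (max-statistic), not per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .datatypes import LfpChannel, SpikeTrain

__all__ = [
    "SpikePhases",
    "PPCSpectrum",
    "PpcPeak",
    "TimeResolvedPPC",
    "remove_spike_artifacts",
    "spike_phases",
    "ppc",
    "rayleigh_p",
    "ppc_spectrum",
    "detect_peaks",
    "peak_density",
    "time_resolved_ppc",
    "contrast_maps",
    "evoked_subtraction",
]

DEFAULT_FREQS = np.arange(4.0, 81.0, 1.0)
N_CYCLES = 5.0


@dataclass
class SpikePhases:
    """Per-spike, per-frequency LFP phases."""

    spike_times: np.ndarray  # (n_spikes,)
    freqs: np.ndarray  # (n_freqs,)
    phases: np.ndarray  # (n_spikes, n_freqs), NaN where invalid
    valid: np.ndarray  # (n_spikes, n_freqs) bool


@dataclass
class PpcPeak:
    freq: float
    band: tuple  # (f_lo, f_hi) of the peak's base
    ppc: float
    mass: float  # summed PPC over the band
    prominence: float


@dataclass
class PPCSpectrum:
    freqs: np.ndarray
    ppc: np.ndarray
    n_spikes: np.ndarray
    rayleigh_p: np.ndarray
    peaks: list = field(default_factory=list)


@dataclass
class TimeResolvedPPC:
    centers: np.ndarray  # window centers (s) relative to event
    freqs: np.ndarray
    ppc: dict  # condition -> (n_windows, n_freqs)
    normalized: dict  # condition -> same, divided by baseline
    baseline: dict  # condition -> (n_freqs,)
    n_spikes: dict  # condition -> (n_windows,)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def remove_spike_artifacts(
    lfp: LfpChannel, spike_times: np.ndarray, half_width: float = 0.002
) -> LfpChannel:
    """Replace +/-``half_width`` around each spike by cubic interpolation.

    Overlapping removal windows are merged; windows touching the recording
    edge fall back to one-sided (nearest-sample) extension.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return lfp
    n = lfp.samples.size
    mask = np.zeros(n, dtype=bool)
    h = int(round(half_width * lfp.fs))
    centers = np.round((spike_times - lfp.t0) * lfp.fs).astype(int)
    for c in centers:
        mask[max(0, c - h) : min(n, c + h + 1)] = True
    if mask.all():
        raise ValueError("artifact windows cover the whole recording")
    idx = np.arange(n)
    good = ~mask
    cs = CubicSpline(idx[good], lfp.samples[good])
    cleaned = lfp.samples.copy()
    inner = mask & (idx >= idx[good][0]) & (idx <= idx[good][-1])
    cleaned[inner] = cs(idx[inner])
    edge = mask & ~inner  # one-sided: hold the nearest valid sample
    if edge.any():
        cleaned[edge & (idx < idx[good][0])] = lfp.samples[good][0]
        cleaned[edge & (idx > idx[good][-1])] = lfp.samples[good][-1]
    return LfpChannel(channel_id=lfp.channel_id, fs=lfp.fs, samples=cleaned, t0=lfp.t0)


# ---------------------------------------------------------------------------
# Phases and PPC
# ---------------------------------------------------------------------------


def spike_phases(
    spike_times: np.ndarray,
    lfp: LfpChannel,
    freqs: np.ndarray = DEFAULT_FREQS,
    block: int = 4096,
) -> SpikePhases:
    """Hann-tapered DFT phase of the LFP around each spike, per frequency."""
    spike_times = np.asarray(spike_times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    x = lfp.samples
    fs = lfp.fs
    n = x.size
    n_s, n_f = spike_times.size, freqs.size
    phases = np.full((n_s, n_f), np.nan)
    valid = np.zeros((n_s, n_f), dtype=bool)
    centers = np.round((spike_times - lfp.t0) * fs).astype(int)
    t_center = centers / fs + lfp.t0
    for j, f in enumerate(freqs):
        half = int(round(N_CYCLES / f * fs / 2))
        L = 2 * half + 1
        ok = (centers - half >= 0) & (centers + half < n)
        if not ok.any():
            continue
        offs = np.arange(-half, half + 1)
        taper = np.hanning(L) * np.exp(-2j * np.pi * f * offs / fs)
        idx_ok = np.nonzero(ok)[0]
        coef = np.empty(idx_ok.size, dtype=complex)
        for s in range(0, idx_ok.size, block):
            sel = idx_ok[s : s + block]
            seg = x[centers[sel][:, None] + offs[None, :]]
            coef[s : s + block] = seg @ taper
        # refer the phase to the true spike time, not the nearest sample
        coef *= np.exp(-2j * np.pi * f * (t_center[idx_ok] - spike_times[idx_ok]))
        phases[idx_ok, j] = np.angle(coef)
        valid[idx_ok, j] = True
    return SpikePhases(spike_times=spike_times, freqs=freqs, phases=phases, valid=valid)


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency of one frequency's spike phases."""
    phases = np.asarray(phases, dtype=float)
    phases = phases[np.isfinite(phases)]
    n = phases.size
    if n < 2:
        raise ValueError("need at least 2 phases")
    R2 = np.abs(np.exp(1j * phases).sum()) ** 2
    return float((R2 - n) / (n * (n - 1)))


def rayleigh_p(phases: np.ndarray) -> float:
    """Rayleigh uniformity test p-value (Z = n R^2 with finite-n correction)."""
    phases = np.asarray(phases, dtype=float)
    phases = phases[np.isfinite(phases)]
    n = phases.size
    if n < 2:
        return 1.0
    Rbar = np.abs(np.exp(1j * phases).mean())
    Z = n * Rbar**2
    p = np.exp(-Z) * (
        1
        + (2 * Z - Z**2) / (4 * n)
        - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2)
    )
    return float(np.clip(p, 0.0, 1.0))


def ppc_spectrum(sp: SpikePhases) -> PPCSpectrum:
    """PPC and Rayleigh p across the frequency grid."""
    n_f = sp.freqs.size
    vals = np.full(n_f, np.nan)
    ns = np.zeros(n_f, dtype=int)
    pr = np.ones(n_f)
    for j in range(n_f):
        ph = sp.phases[sp.valid[:, j], j]
        ns[j] = ph.size
        if ph.size >= 2:
            vals[j] = ppc(ph)
            pr[j] = rayleigh_p(ph)
    spec = PPCSpectrum(freqs=sp.freqs, ppc=vals, n_spikes=ns, rayleigh_p=pr)
    spec.peaks = detect_peaks(spec)
    return spec


def detect_peaks(
    spec: PPCSpectrum,
    alpha: float = 0.05,
    min_ppc: float = 0.005,
    min_prominence: float = 0.0025,
    range_frac: float = 0.25,
) -> list:
    """Local PPC maxima passing the four reliability criteria."""
    from scipy.signal import find_peaks, peak_prominences

    y = np.nan_to_num(spec.ppc, nan=0.0)
    if not np.any(y > 0):
        return []
    idx, props = find_peaks(y, prominence=0.0)
    if idx.size == 0:
        return []
    prom, left, right = peak_prominences(y, idx)
    lo_thr = y.min() + range_frac * (y.max() - y.min())
    peaks = []
    for i, p, lb, rb in zip(idx, prom, left, right):
        if (
            spec.rayleigh_p[i] < alpha
            and y[i] > min_ppc
            and p >= min_prominence
            and y[i] > lo_thr
        ):
            band = (float(spec.freqs[lb]), float(spec.freqs[rb]))
            mass = float(y[lb : rb + 1].sum())
            peaks.append(
                PpcPeak(
                    freq=float(spec.freqs[i]),
                    band=band,
                    ppc=float(y[i]),
                    mass=mass,
                    prominence=float(p),
                )
            )
    return peaks


def peak_density(
    spectra: list,
    labels: np.ndarray,
    n_boot: int = 1000,
    min_size: int = 5,
    ci: float = 0.95,
    seed=0,
) -> dict:
    """Per-class proportion of units with a PPC peak at each frequency.

    Each class's density is compared with the 95% CI of ``n_boot``
    size-matched samples drawn from the whole population (bootstrap), the
    null being that no class differs from the population.
    Classes smaller than ``min_size`` are excluded.
    """
    labels = np.asarray(labels)
    freqs = spectra[0].freqs
    has_peak = np.zeros((len(spectra), freqs.size), dtype=float)
    for u, spec in enumerate(spectra):
        for pk in spec.peaks:
            in_band = (freqs >= pk.band[0]) & (freqs <= pk.band[1])
            has_peak[u, in_band] = 1.0
    rng = np.random.default_rng(seed)
    out = {}
    qlo, qhi = (1 - ci) / 2, 1 - (1 - ci) / 2
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        if members.size < min_size:
            continue
        density = has_peak[members].mean(axis=0)
        samples = np.stack(
            [
                has_peak[rng.integers(0, len(spectra), members.size)].mean(axis=0)
                for _ in range(n_boot)
            ]
        )
        lo = np.quantile(samples, qlo, axis=0)
        hi = np.quantile(samples, qhi, axis=0)
        out[c] = {
            "freqs": freqs,
            "density": density,
            "ci_lo": lo,
            "ci_hi": hi,
            "exceeds": density > hi,
        }
    return out


# ---------------------------------------------------------------------------
# Time-resolved PPC with spike-count control
# ---------------------------------------------------------------------------


def _subsampled_ppc(
    phases: np.ndarray, valid: np.ndarray, n_sub: int, n_spk: int, rng
) -> np.ndarray:
    """Mean PPC over random ``n_spk``-spike subsamples, per frequency."""
    n_f = phases.shape[1]
    out = np.full(n_f, np.nan)
    for j in range(n_f):
        ph = phases[valid[:, j], j]
        if ph.size < n_spk:
            continue
        z = np.exp(1j * ph)
        # n_sub without-replacement subsamples in one shot
        picks = np.argpartition(rng.random((n_sub, ph.size)), n_spk - 1, axis=1)[:, :n_spk]
        R2 = np.abs(z[picks].sum(axis=1)) ** 2
        out[j] = float(np.mean((R2 - n_spk) / (n_spk * (n_spk - 1))))
    return out


def time_resolved_ppc(
    train: SpikeTrain,
    lfp: LfpChannel,
    events: np.ndarray,
    values: np.ndarray,
    freqs: np.ndarray = DEFAULT_FREQS,
    centers: np.ndarray = None,
    win_half: float = 0.35,
    baseline_window: tuple = (-0.85, 0.0),
    n_sub: int = 500,
    n_spk: int = 50,
    seed=0,
) -> TimeResolvedPPC:
    """Time-resolved, subsample-controlled PPC split by a behavioral variable.

    Trials are divided at the median of ``values`` (ties go to "low").  Per
    condition and window, the PPC is the mean over ``n_sub`` random
    subsamples of ``n_spk`` spikes pooled across trials; windows (or the
    baseline) with fewer than ``n_spk`` spikes stay NaN.  The normalized
    variant divides by the pre-event baseline PPC (ratio).
    """
    events = np.asarray(events, dtype=float)
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = np.arange(-0.6, 0.601, 0.05)
    centers = np.asarray(centers, dtype=float)
    rng = np.random.default_rng(seed)
    med = np.nanmedian(values)
    cond_trials = {"low": values <= med, "high": values > med}

    sp = spike_phases(train.times, lfp, freqs)
    # spike time relative to the nearest event
    rel = np.full(train.n_spikes, np.nan)
    trial_of_spike = np.full(train.n_spikes, -1)
    for ti, ev in enumerate(events):
        d = train.times - ev
        in_range = (d >= min(baseline_window[0], centers[0] - win_half)) & (
            d <= centers[-1] + win_half
        )
        rel[in_range] = d[in_range]
        trial_of_spike[in_range] = ti
    result_ppc, result_norm, result_base, result_n = {}, {}, {}, {}
    for cond, tmask in cond_trials.items():
        smask = tmask[trial_of_spike] & (trial_of_spike >= 0)
        base_sel = smask & (rel >= baseline_window[0]) & (rel < baseline_window[1])
        base = _subsampled_ppc(sp.phases[base_sel], sp.valid[base_sel], n_sub, n_spk, rng)
        maps = np.full((centers.size, freqs.size), np.nan)
        nsp = np.zeros(centers.size, dtype=int)
        for wi, c in enumerate(centers):
            sel = smask & (rel >= c - win_half) & (rel < c + win_half)
            nsp[wi] = int(sel.sum())
            if nsp[wi] >= n_spk:
                maps[wi] = _subsampled_ppc(sp.phases[sel], sp.valid[sel], n_sub, n_spk, rng)
        result_ppc[cond] = maps
        result_base[cond] = base
        with np.errstate(divide="ignore", invalid="ignore"):
            result_norm[cond] = maps / base[None, :]
        result_n[cond] = nsp
    return TimeResolvedPPC(
        centers=centers,
        freqs=freqs,
        ppc=result_ppc,
        normalized=result_norm,
        baseline=result_base,
        n_spikes=result_n,
    )


def contrast_maps(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    band_axis: np.ndarray = None,
    band_window: tuple = (0.0, 0.5),
    centers: np.ndarray = None,
    seed=0,
) -> dict:
    """Two-step permutation contrast of per-unit (window x frequency) maps.

    Step 1: the observed mean difference map (group A - group B) is compared
    against the permutation distribution of label-shuffled differences; the
    threshold is the (1-alpha) quantile of the map-wide maximum absolute
    difference (the most extreme 5% across the whole map), giving
    family-wise corrected significance.

    Step 2: the same test on the per-frequency mean over the post-event
    ``band_window``, corrected across frequencies.

    Units with any non-finite pixel are dropped.  Requires both groups to
    have at least 5 units.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if len(maps_a) < 5 or len(maps_b) < 5:
        raise ValueError("both groups need at least 5 units")
    pooled = np.concatenate([maps_a, maps_b], axis=0)
    finite = np.all(np.isfinite(pooled.reshape(len(pooled), -1)), axis=1)
    pooled = pooled[finite]
    n_a = int(finite[: len(maps_a)].sum())
    if n_a < 5 or len(pooled) - n_a < 5:
        raise ValueError("both groups need at least 5 units with complete maps")
    rng = np.random.default_rng(seed)
    obs = pooled[:n_a].mean(axis=0) - pooled[n_a:].mean(axis=0)
    null_max = np.empty(n_boot)
    if centers is not None and band_axis is not None:
        wsel = (centers >= band_window[0]) & (centers <= band_window[1])
        obs_band = obs[wsel].mean(axis=0)
        null_band_max = np.empty(n_boot)
    else:
        wsel = None
    for b in range(n_boot):
        perm = rng.permutation(len(pooled))
        d = pooled[perm[:n_a]].mean(axis=0) - pooled[perm[n_a:]].mean(axis=0)
        null_max[b] = np.max(np.abs(d))
        if wsel is not None:
            null_band_max[b] = np.max(np.abs(d[wsel].mean(axis=0)))
    thr = float(np.quantile(null_max, 1 - alpha))
    out = {
        "difference": obs,
        "threshold": thr,
        "significant": np.abs(obs) > thr,
    }
    if wsel is not None:
        out["band_difference"] = obs_band
        out["band_threshold"] = float(np.quantile(null_band_max, 1 - alpha))
        out["band_significant"] = np.abs(obs_band) > out["band_threshold"]
    return out


def evoked_subtraction(trials_lfp: np.ndarray) -> np.ndarray:
    """Subtract the per-sample trial-average evoked LFP from each trial."""
    trials_lfp = np.asarray(trials_lfp, dtype=float)
    if trials_lfp.ndim != 2 or trials_lfp.shape[0] < 10:
        raise ValueError("need a (trials x samples) array with >= 10 trials")
    return trials_lfp - trials_lfp.mean(axis=0, keepdims=True)
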