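"""Ground-truth session generator for every downstream analysis stage.

The generators emulate the study conditions of a two-monkey color-reversal
experiment so that each analysis can be exercised by parameter recovery:

- spike trains as gamma-renewal processes optionally mixed with burst
  doublets (controls rate, CV, LV and the burst index);
- mean action-potential waveforms with a controllable trough-to-peak time
  and repolarization shape, sampled at 32 kHz;
- LFP channels as sums of sinusoids plus 1/f Gaussian noise at 1 kHz;
- spike-phase coupling by moving spikes so their phase at a carrier
  frequency follows a von Mises distribution of known concentration;
- wideband multiunit traces with a planted pre/post-spike envelope
  asymmetry (the SMUM target);
- task behavior played by the Rescorla-Wagner agent of :mod:`etype_sync.rl`
  with known (eta, omega, beta), reversing blocks after 30-100 trials or a
  90%-over-last-12-trials criterion.

All generators are bit-reproducible under a fixed seed.  Times are in
seconds on the half-open interval ``[0, duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import LfpChannel, SpikeTrain, Waveform
from .rl import N_FEATURES, V0, RlParams

__all__ = [
    "GroundTruth",
    "UnitSpec",
    "gen_spiketrain",
    "gen_waveform",
    "gen_lfp",
    "couple_spikes_to_lfp",
    "couple_spikes_in_windows",
    "gen_mua",
    "gen_session",
    "build_session",
    "planted_feature_matrix",
]

RAW_WAVEFORM_FS = 32_000.0


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside a generated session."""

    agent: RlParams | None = None
    units: pd.DataFrame | None = None  # per-unit planted parameters
    extra: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def gen_spiketrain(
    rate: float,
    duration: float,
    shape: float = 1.0,
    burst_mix: float = 0.0,
    intra_burst_isi: float = 0.003,
    seed=0,
    unit_id: str = "u0",
    area: str = "synthetic",
) -> SpikeTrain:
    """Gamma-renewal spike train, optionally mixed with burst doublets.

    ``shape`` is the gamma-interval shape parameter: 1 gives exponential
    ISIs (Poisson process, LV = CV = 1), large values give near-constant
    ISIs (LV -> 0).  With probability ``burst_mix`` each renewal spike is
    followed by an extra spike ``intra_burst_isi`` later, raising LV above
    1; the renewal rate is rescaled so the overall mean rate stays at
    ``rate``.
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if not (0.0 <= burst_mix < 1.0):
        raise ValueError("burst_mix must lie in [0, 1)")
    rng = _rng(seed)
    base_rate = rate / (1.0 + burst_mix)
    mean_isi = 1.0 / base_rate
    n_target = int(duration * base_rate * 1.5) + 50
    times = []
    t = float(rng.gamma(shape, mean_isi / shape))  # first arrival
    while t < duration:
        times.append(t)
        if burst_mix > 0 and rng.random() < burst_mix:
            tb = t + intra_burst_isi
            if tb < duration:
                times.append(tb)
            t = tb
        t += float(rng.gamma(shape, mean_isi / shape))
        if len(times) > 20 * n_target:  # safety net against runaway loops
            break
    times = np.unique(np.asarray(times))
    return SpikeTrain(unit_id=unit_id, times=times, duration=duration, area=area)


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------


def _waveform_template(t: np.ndarray, t2p: float, repol_frac: float, peak_shift: float):
    """Two-Gaussian action-potential template: unit trough + positive peak.

    Widths scale with the trough-to-peak distance (with small absolute
    floors) so the two lobes never merge into a degenerate shape.
    """
    sigma_t = max(0.08e-3, 0.15 * t2p)  # trough width
    sigma_p = max(0.04e-3, repol_frac * t2p)  # peak (repolarization) width
    return -np.exp(-0.5 * (t / sigma_t) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - peak_shift) / sigma_p) ** 2
    )


def gen_waveform(
    t2p_ms: float,
    repol_frac: float = 0.35,
    noise_sd: float = 0.0,
    seed=0,
) -> Waveform:
    """Mean action potential with trough-to-peak time ``t2p_ms`` (ms).

    The template is a negative Gaussian trough plus a positive
    repolarization bump.  Because the two lobes overlap, the peak center is
    calibrated iteratively on a dense (10x upsampled) grid until the
    realized trough-to-peak distance matches ``t2p_ms`` to within one
    interpolated step.  ``repol_frac`` scales the width of the
    repolarization bump relative to T2P (shapes T4R and HR);
    ``noise_sd`` adds white noise relative to unit trough depth.

    Raises ``ValueError`` if the requested parameters produce a
    double-troughed template.
    """
    if not (0.05 <= t2p_ms <= 1.5):
        raise ValueError("t2p_ms must lie in [0.05, 1.5] ms")
    t2p = t2p_ms * 1e-3
    dt_fine = 1.0 / (10.0 * RAW_WAVEFORM_FS)
    t_fine = np.arange(-1.0e-3, 3.0e-3, dt_fine)
    peak_shift = t2p
    for _ in range(40):  # fixed-point calibration of the peak position
        w = _waveform_template(t_fine, t2p, repol_frac, peak_shift)
        measured = t_fine[np.argmax(w)] - t_fine[np.argmin(w)]
        err = t2p - measured
        if abs(err) < dt_fine / 4:
            break
        peak_shift += err
    w = _waveform_template(t_fine, t2p, repol_frac, peak_shift)
    # degenerate-template guard: the lobes must not cancel each other
    if w.min() > -0.9 or w.max() < 0.15:
        raise ValueError("parameters produce a degenerate (merged-lobe) waveform")
    # double-trough guard: local minima below 80% of the global trough depth
    local_min = (w[1:-1] < w[:-2]) & (w[1:-1] < w[2:])
    deep = local_min & (w[1:-1] < 0.8 * w.min())
    if deep.sum() > 1:
        raise ValueError("parameters produce a double-troughed waveform")
    # sample down to the raw 32 kHz grid
    raw = w[::10].copy()
    if noise_sd > 0:
        raw = raw + _rng(seed).normal(0.0, noise_sd, raw.size)
    return Waveform(samples=raw, dt=1.0 / RAW_WAVEFORM_FS)


# ---------------------------------------------------------------------------
# LFP and phase coupling
# ---------------------------------------------------------------------------


def gen_lfp(
    duration: float,
    fs: float = 1000.0,
    components=((10.0, 1.0),),
    noise_sd: float = 0.2,
    channel_id: str = "lfp0",
    seed=0,
) -> LfpChannel:
    """LFP as a sum of cosines plus 1/f Gaussian noise.

    ``components`` is a sequence of ``(freq_hz, amplitude)`` pairs; each
    component gets a random phase offset unless the pair carries an explicit
    third element giving the phase in radians.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    phases = {}
    for comp in components:
        f, a = comp[0], comp[1]
        phi = comp[2] if len(comp) > 2 else float(rng.uniform(-np.pi, np.pi))
        phases[f] = phi
        x += a * np.cos(2 * np.pi * f * t + phi)
    if noise_sd > 0:
        white = rng.normal(0.0, 1.0, n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        scale = np.ones_like(freqs)
        nz = freqs > 0
        scale[nz] = 1.0 / np.sqrt(freqs[nz])
        pink = np.fft.irfft(spec * scale, n)
        pink *= noise_sd / pink.std()
        x += pink
    lfp = LfpChannel(channel_id=channel_id, fs=fs, samples=x)
    lfp.component_phases = phases  # ground-truth phase offsets
    return lfp


def _component_phase_offset(lfp: LfpChannel, f_c: float) -> float:
    """Phase offset of the stationary sinusoidal component at ``f_c``.

    Estimated by projecting the whole signal on the complex exponential;
    exact for the generator's sum-of-cosines construction.
    """
    t = np.arange(lfp.samples.size) / lfp.fs
    c = np.sum(lfp.samples * np.exp(-2j * np.pi * f_c * t))
    return float(np.angle(c))


def couple_spikes_to_lfp(
    train: SpikeTrain,
    lfp: LfpChannel,
    f_c: float,
    kappa: float,
    mu: float = 0.0,
    seed=0,
) -> SpikeTrain:
    """Move spikes so their phase at ``f_c`` is von Mises(mu, kappa).

    Each spike is shifted by less than one carrier cycle to the nearest
    time at which the instantaneous phase of the ``f_c`` component (cosine
    convention) equals a phase drawn from the target distribution.
    ``kappa = 0`` leaves phases uniform.  The mean rate is preserved to
    first order because shifts stay within one cycle.
    """
    if not (1.0 <= f_c < lfp.fs / 2):
        raise ValueError("f_c must lie in [1, fs/2)")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = _rng(seed)
    n = train.n_spikes
    if n == 0:
        return train
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, n)
    else:
        theta = rng.vonmises(mu, kappa, n)
    phi0 = _component_phase_offset(lfp, f_c)
    # instantaneous phase at time t is 2*pi*f_c*t + phi0 (cosine convention)
    current = np.mod(2 * np.pi * f_c * train.times + phi0 + np.pi, 2 * np.pi) - np.pi
    delta = np.mod(theta - current + np.pi, 2 * np.pi) - np.pi
    new_times = train.times + delta / (2 * np.pi * f_c)
    new_times = np.unique(new_times[(new_times >= 0) & (new_times < train.duration)])
    return SpikeTrain(
        unit_id=train.unit_id, times=new_times, duration=train.duration, area=train.area
    )


# ---------------------------------------------------------------------------
# Wideband multiunit activity
# ---------------------------------------------------------------------------


def gen_mua(
    train: SpikeTrain,
    smum_target: float,
    fs_wb: float = 32_000.0,
    base_gain: float = 0.5,
    seed=0,
) -> np.ndarray:
    """Wideband trace whose spike-triggered envelope asymmetry equals ``smum_target``.

    Band-limited (800-3000 Hz) Gaussian noise is amplitude-modulated in the
    12.5 ms before and after each spike of ``train``.  With pre-window gain
    ``1 + A`` (A = ``base_gain``) the post-window gain ``1 + B`` is chosen so
    that after the downstream analysis — per-segment z-scoring over +/-50 ms
    and a 5 ms sliding median that mixes the two gains within 2.5 ms of the
    spike — the (post - pre)/pre ratio over the +/-10 ms windows equals the
    target: ``B = A (0.9 + 0.825 s) / (0.9 + 0.075 s)`` for target ``s``
    (0.825/0.075 from the 25 ms modulated span inside the 100 ms segment,
    0.9 from the median-window gain mixing next to the spike).
    """
    if not (-1.0 < smum_target < 1.0):
        raise ValueError("|smum_target| must be below 1")
    if fs_wb < 8000:
        raise ValueError("wideband sampling rate must be at least 8 kHz")
    rng = _rng(seed)
    n = int(round(train.duration * fs_wb))
    noise = rng.normal(0.0, 1.0, n)
    sos = signal.butter(4, [800.0, 3000.0], btype="bandpass", fs=fs_wb, output="sos")
    band = signal.sosfiltfilt(sos, noise)

    A = base_gain
    B = A * (0.9 + 0.825 * smum_target) / (0.9 + 0.075 * smum_target)
    gain = np.ones(n)
    half = int(round(0.0125 * fs_wb))
    idx = np.round(train.times * fs_wb).astype(int)
    for i in idx:
        lo = max(0, i - half)
        hi = min(n, i + half)
        gain[lo:i] = 1.0 + A
        gain[i:hi] = 1.0 + B
    return (band * gain).astype(np.float32)


# ---------------------------------------------------------------------------
# Task behavior
# ---------------------------------------------------------------------------


def gen_session(
    params: RlParams,
    n_blocks: int = 30,
    max_block: int = 100,
    min_block: int = 30,
    criterion: float = 0.9,
    criterion_window: int = 12,
    seed=0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the color-reversal task with the Rescorla-Wagner agent.

    The rewarded color reverses once a block reaches ``max_block`` trials,
    or — after at least ``min_block`` trials — when the running accuracy
    over the last ``criterion_window`` trials reaches ``criterion``.
    Location and direction are bound to the stimuli pseudo-randomly each
    trial; reward is deterministic for the correct color.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    rng = _rng(seed)
    V = np.full(N_FEATURES, V0)
    rewarded_color = int(rng.integers(2))
    rows = []
    t_clock = 0.0
    for block in range(n_blocks):
        block_rewards: list[int] = []
        trial_in_block = 0
        while True:
            trial_in_block += 1
            # pseudo-random binding of location and direction to the colors
            loc_of_color0 = int(rng.integers(2))
            dir_of_color0 = int(rng.integers(2))
            stim_feats = [
                (0, 2 + loc_of_color0, 4 + dir_of_color0),
                (1, 2 + (1 - loc_of_color0), 4 + (1 - dir_of_color0)),
            ]
            sums = np.array([V[list(s)].sum() for s in stim_feats])
            z = params.beta * sums
            z -= z.max()
            p = np.exp(z)
            p /= p.sum()
            choice = int(rng.random() < p[1])
            reward = int(choice == rewarded_color)
            ci = list(stim_feats[choice])
            ui = list(stim_feats[1 - choice])
            V[ci] += params.eta * (reward - V[ci])
            V[ui] *= 1.0 - params.omega

            # trial event timing (seconds, cumulative session clock)
            fix = t_clock + float(rng.uniform(0.5, 0.9))
            f1 = fix + 0.4
            f2 = f1 + float(rng.uniform(0.5, 0.9))
            color_first = bool(rng.integers(2))
            color_onset, motion_onset = (f1, f2) if color_first else (f2, f1)
            outcome = f2 + float(rng.uniform(0.7, 1.6))
            t_clock = outcome + 1.0

            rows.append(
                {
                    "block_id": block,
                    "trial_in_block": trial_in_block,
                    "feature1_onset": f1,
                    "feature2_onset": f2,
                    "color_onset": color_onset,
                    "motion_onset": motion_onset,
                    "outcome_onset": outcome,
                    "color_first": color_first,
                    "rewarded_color": rewarded_color,
                    "chosen_color": choice,
                    "chosen_location": stim_feats[choice][1] - 2,
                    "chosen_direction": stim_feats[choice][2] - 4,
                    "reward": reward,
                }
            )
            block_rewards.append(reward)
            if trial_in_block >= max_block:
                break
            if (
                trial_in_block >= min_block
                and len(block_rewards) >= criterion_window
                and np.mean(block_rewards[-criterion_window:]) >= criterion
            ):
                break
        rewarded_color = 1 - rewarded_color
    trials = pd.DataFrame(rows)
    return trials, GroundTruth(agent=params)


def couple_spikes_in_windows(
    train: SpikeTrain,
    lfp: LfpChannel,
    f_c: float,
    kappa: float,
    windows,
    seed=0,
) -> SpikeTrain:
    """Phase-couple only the spikes falling inside the given time windows.

    Used to plant event- and condition-restricted synchronization (e.g. a
    class that gamma-couples only 0-500 ms after the cue on low-certainty
    trials); spikes outside the windows keep their original times.
    """
    rng = _rng(seed)
    inside = np.zeros(train.n_spikes, dtype=bool)
    for lo, hi in windows:
        inside |= (train.times >= lo) & (train.times < hi)
    if not inside.any():
        return train
    sub = SpikeTrain(
        unit_id=train.unit_id,
        times=train.times[inside],
        duration=train.duration,
        area=train.area,
    )
    moved = couple_spikes_to_lfp(sub, lfp, f_c, kappa, seed=rng)
    times = np.unique(np.concatenate([train.times[~inside], moved.times]))
    return SpikeTrain(
        unit_id=train.unit_id, times=times, duration=train.duration, area=train.area
    )


@dataclass
class UnitSpec:
    """Planted parameters of one synthetic unit."""

    unit_id: str
    class_label: str
    t2p_ms: float = 0.5
    repol_frac: float = 0.35
    rate: float = 8.0
    shape: float = 1.0  # gamma-renewal shape (controls LV/CV)
    burst_mix: float = 0.0
    kappa: float = 0.0  # spike-LFP coupling concentration
    kappa_base: float = 0.0  # weaker session-wide coupling (condition units)
    f_c: float = 40.0
    couple_condition: str = "all"  # "all", "low", "high" (variable split)
    couple_window: tuple | None = None  # (start, end) s relative to event
    rate_gain: float = 0.0  # extra post-event rate per unit of -z(variable)


def build_session(
    specs,
    trials: pd.DataFrame,
    variable: np.ndarray | None = None,
    event_column: str = "color_onset",
    lfp_components=((40.0, 1.0), (10.0, 0.8)),
    lfp_noise_sd: float = 0.3,
    seed=0,
):
    """Assemble a full synthetic session from planted unit specifications.

    For units with ``rate_gain`` > 0, extra Poisson spikes are injected in
    the 0-500 ms post-event window at a rate proportional to the negated
    z-scored ``variable`` (emulating cells that fire more when choice
    certainty is low / prediction error is high).  Units with ``kappa`` > 0
    are phase-coupled at ``f_c`` — everywhere for ``couple_condition
    'all'``, or only inside the per-trial coupling window on the low/high
    half of ``variable``.

    Returns ``(trains, waveforms, lfp, ground_truth_frame)``.
    """
    from .session import Session  # noqa: F401  (layout documented there)

    rng = _rng(seed)
    duration = float(trials["outcome_onset"].max()) + 2.0
    lfp = gen_lfp(
        duration, components=lfp_components, noise_sd=lfp_noise_sd, seed=rng.integers(2**31)
    )
    events = trials[event_column].to_numpy(dtype=float)
    if variable is not None:
        variable = np.asarray(variable, dtype=float)
        med = np.nanmedian(variable)
        low_trials = variable <= med
        z = (variable - np.nanmean(variable)) / np.nanstd(variable)
    trains = []
    waveforms = {}
    rows = []
    for spec in specs:
        train = gen_spiketrain(
            rate=spec.rate,
            duration=duration,
            shape=spec.shape,
            burst_mix=spec.burst_mix,
            seed=rng.integers(2**31),
            unit_id=spec.unit_id,
        )
        if spec.rate_gain > 0 and variable is not None:
            extra = []
            for ev, zv in zip(events, z):
                lam = spec.rate_gain * max(0.0, -zv) * 0.5
                n_extra = rng.poisson(lam)
                extra.append(ev + rng.uniform(0.0, 0.5, n_extra))
            times = np.unique(np.concatenate([train.times, *extra]))
            times = times[(times >= 0) & (times < duration)]
            train = SpikeTrain(
                unit_id=spec.unit_id, times=times, duration=duration, area=train.area
            )
        if spec.kappa > 0:
            if spec.couple_condition == "all" or variable is None:
                train = couple_spikes_to_lfp(
                    train, lfp, spec.f_c, spec.kappa, seed=rng.integers(2**31)
                )
            else:
                if spec.kappa_base > 0:  # weak session-wide locking first
                    train = couple_spikes_to_lfp(
                        train, lfp, spec.f_c, spec.kappa_base, seed=rng.integers(2**31)
                    )
                sel = low_trials if spec.couple_condition == "low" else ~low_trials
                w0, w1 = spec.couple_window or (0.0, 0.5)
                windows = [(ev + w0, ev + w1) for ev in events[sel]]
                train = couple_spikes_in_windows(
                    train, lfp, spec.f_c, spec.kappa, windows, seed=rng.integers(2**31)
                )
        trains.append(train)
        waveforms[spec.unit_id] = gen_waveform(
            spec.t2p_ms, spec.repol_frac, noise_sd=0.01, seed=rng.integers(2**31)
        ).samples
        rows.append(vars(spec).copy())
    return trains, waveforms, lfp, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted feature-space populations (for clustering recovery)
# ---------------------------------------------------------------------------


def planted_feature_matrix(
    n_classes: int = 8,
    units_per_class: int = 12,
    n_features: int = 5,
    separation: float = 3.0,
    seed=0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian class blobs in feature space with a known separation.

    Class centers are placed by rejection sampling so every pair of centers
    is at least ``separation`` standard deviations of the within-class noise
    (unit SD per feature) apart.  Returns the unit-by-feature frame and the
    true labels.
    """
    rng = _rng(seed)
    centers_list: list[np.ndarray] = []
    while len(centers_list) < n_classes:
        c = rng.uniform(-2.0 * separation, 2.0 * separation, n_features)
        if all(np.linalg.norm(c - other) >= separation for other in centers_list):
            centers_list.append(c)
    centers = np.asarray(centers_list)
    X = np.concatenate(
        [rng.normal(c, 1.0, (units_per_class, n_features)) for c in centers]
    )
    labels = np.repeat(np.arange(n_classes), units_per_class)
    cols = [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), labels
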