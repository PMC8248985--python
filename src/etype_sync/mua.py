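"""Spike-triggered multiunit activity (MUA) and the SMUM suppression statistic.

The wideband signal of a *different* electrode is bandpass filtered to
800-3000 Hz (4th-order Butterworth, forward-backward so zero phase),
rectified, and reduced to an envelope by a 5 ms sliding median evaluated
every 0.5 ms.  Around each spike a +/-50 ms envelope segment is extracted
and z-scored (its own mean and SD); the spike-triggered average of these
segments gives the MUA modulation, summarized as

    SMUM = (MUA_post - MUA_pre) / MUA_pre

with the pre/post means taken over the 10 ms before/after the spike
(excluding the zero-lag sample from both windows).  Negative SMUM marks
local suppression of surrounding activity after the unit spikes — the
signature used to corroborate putative inhibitory interneurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .datatypes import SpikeTrain

__all__ = ["StaMatrix", "SmumResult", "mua_envelope", "smum", "population_smum_test"]

ENVELOPE_STEP = 0.0005  # s (2 kHz envelope grid)
MEDIAN_WINDOW = 0.005  # s
STA_HALF = 0.050  # s
SMUM_WINDOW = 0.010  # s


@dataclass
class StaMatrix:
    """Mean z-scored spike-triggered envelope over lags +/-50 ms."""

    lags: np.ndarray  # s, symmetric about 0, 0.5 ms steps
    mean: np.ndarray
    n_spikes: int


@dataclass
class SmumResult:
    """Spike-triggered MUA modulation ratio of one unit."""

    SMUM: float
    MUA_pre: float
    MUA_post: float
    n_spikes: int
    sta: StaMatrix


def mua_envelope(wideband: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Envelope of the 800-3000 Hz band on a 2 kHz grid.

    Returns ``(envelope, fs_env)``.  Requires ``fs >= 8000`` so the band
    fits below Nyquist with margin.
    """
    if fs < 8000:
        raise ValueError("wideband sampling rate must be at least 8 kHz")
    wideband = np.asarray(wideband, dtype=float)
    sos = signal.butter(4, [800.0, 3000.0], btype="bandpass", fs=fs, output="sos")
    rect = np.abs(signal.sosfiltfilt(sos, wideband))
    # sliding 5 ms median, evaluated every 0.5 ms; reflect-padded so that
    # envelope sample k is centered on raw time k * 0.5 ms
    win = int(round(MEDIAN_WINDOW * fs))
    step = int(round(ENVELOPE_STEP * fs))
    if step < 1:
        raise ValueError("sampling rate too low for the 0.5 ms envelope grid")
    padded = np.pad(rect, win // 2, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, win)[::step]
    env = np.median(view, axis=1)
    return env, 1.0 / ENVELOPE_STEP


def _sta_segments(train: SpikeTrain, envelope: np.ndarray, fs_env: float) -> np.ndarray:
    """Per-spike z-scored envelope segments over +/-50 ms (rows)."""
    half = int(round(STA_HALF * fs_env))
    centers = np.round(train.times * fs_env).astype(int)
    ok = (centers - half >= 0) & (centers + half < envelope.size)
    centers = centers[ok]
    if centers.size == 0:
        raise ValueError("no spike has a full +/-50 ms envelope segment")
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    seg = envelope[idx]
    mu = seg.mean(axis=1, keepdims=True)
    sd = seg.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (seg - mu) / sd


def smum(train: SpikeTrain, envelope: np.ndarray, fs_env: float = 2000.0) -> SmumResult:
    """SMUM of one unit against an envelope from a different electrode."""
    if train.n_spikes < 50:
        raise ValueError("need at least 50 spikes")
    seg = _sta_segments(train, envelope, fs_env)
    mean = np.nanmean(seg, axis=0)
    half = (mean.size - 1) // 2
    lags = (np.arange(mean.size) - half) / fs_env
    nwin = int(round(SMUM_WINDOW * fs_env))
    pre = float(mean[half - nwin : half].mean())  # lag in [-10 ms, 0)
    post = float(mean[half + 1 : half + 1 + nwin].mean())  # lag in (0, +10 ms]
    if pre == 0:
        raise ZeroDivisionError("MUA_pre is zero: SMUM undefined")
    sta = StaMatrix(lags=lags, mean=mean, n_spikes=seg.shape[0])
    return SmumResult(
        SMUM=(post - pre) / pre, MUA_pre=pre, MUA_post=post, n_spikes=seg.shape[0], sta=sta
    )


def population_smum_test(smums: np.ndarray) -> float:
    """Wilcoxon signed-rank p-value of the population SMUM ratios against 0."""
    smums = np.asarray(smums, dtype=float)
    if np.allclose(smums, 0):
        return 1.0
    return float(stats.wilcoxon(smums).pvalue)
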