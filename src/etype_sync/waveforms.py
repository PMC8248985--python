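"""Action-potential waveform metrics and the narrow/broad spiking split.

Pipeline: trough-align and range-normalize the mean waveform, interpolate
10x (cubic spline, 1/32000 s -> 1/320000 s), then measure

- ``T2P`` — trough-to-peak time, with the peak the most positive sample
  after the trough;
- ``T4R`` — time for repolarization: time after the peak at which the
  voltage falls to 75% of the peak, located by linear interpolation;
- ``HR``  — hyperpolarization rate: ``1 / (t_peak - t_{0.63 x peak})``
  with the 63% crossing searched backward from the peak.

Bimodality of the metric distributions is assessed with a calibrated
Hartigan dip test (Monte-Carlo null from uniform samples), and the
narrow/broad split by 1- versus 2-component Gaussian-mixture fits compared
by AIC/BIC; the component with the larger HR (faster hyperpolarization) is
labeled narrow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .datatypes import Waveform

__all__ = [
    "WaveformMetrics",
    "normalize_align",
    "compute_metrics",
    "dip_statistic",
    "dip_test_calibrated",
    "split_narrow_broad",
]

INTERP_FACTOR = 10
MIN_SPIKES_FOR_METRICS = 50  # units with fewer spikes are excluded upstream


@dataclass
class WaveformMetrics:
    """Waveform shape metrics (seconds and 1/seconds)."""

    T2P: float
    T4R: float
    HR: float
    narrow: bool | None = None


# ---------------------------------------------------------------------------
# Alignment / normalization
# ---------------------------------------------------------------------------


def normalize_align(raw: np.ndarray, dt_raw: float = 1.0 / 32000.0) -> Waveform:
    """Trough-aligned, range-normalized, 10x cubic-spline interpolated waveform.

    Rejects waveforms with two local troughs deeper than 80% of the range
    below baseline (``ValueError``), mirroring the unit-exclusion rule for
    double-troughed mean waveforms.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size * dt_raw < 1e-3:
        raise ValueError("need at least 1 ms of samples around the trough")
    t = np.arange(raw.size) * dt_raw
    dt = dt_raw / INTERP_FACTOR
    t_fine = np.arange(0.0, t[-1] + dt / 2, dt)
    fine = CubicSpline(t, raw)(t_fine)
    lo, hi = fine.min(), fine.max()
    if hi == lo:
        raise ValueError("flat waveform")
    norm = 2.0 * (fine - lo) / (hi - lo) - 1.0
    # double-trough rejection: two prominent minima below -0.8 of the range
    # (prominence keeps noise wiggles near the trough from counting)
    from scipy.signal import find_peaks

    troughs, _ = find_peaks(-norm, height=0.8, prominence=0.3)
    if troughs.size > 1:
        raise ValueError("double-troughed waveform rejected")
    return Waveform(samples=norm, dt=dt, trough_index=int(np.argmin(norm)))


def _crossing_time(t0: float, t1: float, v0: float, v1: float, thr: float) -> float:
    """Linear-interpolated time at which the segment (v0 -> v1) crosses thr."""
    if v1 == v0:
        return t0
    return t0 + (thr - v0) / (v1 - v0) * (t1 - t0)


def compute_metrics(w: Waveform) -> WaveformMetrics:
    """T2P, T4R and HR of an aligned waveform (threshold crossings by
    linear interpolation between samples)."""
    v = w.samples
    it = w.trough_index
    if it >= v.size - 2:
        raise ValueError("no post-trough samples: metrics undefined")
    post = v[it:]
    ip_rel = int(np.argmax(post))
    if ip_rel == 0 or post[ip_rel] <= v[it]:
        raise ValueError("no post-trough peak: metrics undefined")
    ip = it + ip_rel
    vpeak = v[ip]
    t = np.arange(v.size) * w.dt
    t2p = t[ip] - t[it]

    # T4R: first fall to 0.75*peak after the peak
    thr = 0.75 * vpeak
    after = v[ip:]
    below = np.nonzero(after <= thr)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError("waveform never repolarizes to 75% of peak")
    j = ip + below[0]
    t4r = _crossing_time(t[j - 1], t[j], v[j - 1], v[j], thr) - t[ip]

    # HR: 0.63*peak crossing searched backward from the peak
    thr = 0.63 * vpeak
    before = v[it : ip + 1]
    under = np.nonzero(before <= thr)[0]
    if under.size == 0:
        raise ValueError("no 63%-of-peak crossing before the peak")
    j = it + under[-1]  # last sample at/below threshold before the peak
    tc = _crossing_time(t[j], t[j + 1], v[j], v[j + 1], thr)
    hr = 1.0 / (t[ip] - tc)
    return WaveformMetrics(T2P=float(t2p), T4R=float(t4r), HR=float(hr))


# ---------------------------------------------------------------------------
# Hartigan dip statistic and calibrated test
# ---------------------------------------------------------------------------


def _collapse_ties(x: np.ndarray):
    """Unique sorted values with the ecdf corridor of each tied group.

    At a value covering sorted ranks i..j (0-based) the fitted cdf must pass
    within d of both ecdf limits, i.e. inside
    ``[(j+1)/n - d, i/n + d]``: ``upper0`` holds i/n, ``lower0`` (j+1)/n.
    """
    n = x.size
    ux, first = np.unique(x, return_index=True)
    last = np.r_[first[1:], n] - 1
    upper0 = first / n
    lower0 = (last + 1) / n
    return ux, upper0, lower0


def _gcm(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Indices of the greatest convex minorant vertices of (xs, ys)."""
    hull = [0]
    for i in range(1, xs.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (ys[b] - ys[a]) * (xs[i] - xs[b]) <= (ys[i] - ys[b]) * (xs[b] - xs[a]):
                break
            hull.pop()
        hull.append(i)
    return np.asarray(hull)


def _convex_dev(xs, hi0, lo0) -> float:
    """Half the worst shortfall of a convex cdf fit inside the ecdf corridor.

    The corridor at each unique value is ``[lo0 - d, hi0 + d]``; the best
    convex fit is the greatest convex minorant of ``hi0 + d``, so the
    minimal feasible d is ``max(lo0 - GCM(hi0)) / 2``.
    """
    if xs.size == 0:
        return 0.0
    g = _gcm(xs, hi0)
    fit = np.interp(xs, xs[g], hi0[g])
    return float(max(0.0, np.max(lo0 - fit) / 2.0))


def _concave_dev(xs, hi0, lo0) -> float:
    """Concave counterpart: least concave majorant of ``lo0`` against ``hi0``."""
    if xs.size == 0:
        return 0.0
    g = _gcm(xs, -lo0)
    fit = -np.interp(xs, xs[g], -lo0[g])
    return float(max(0.0, np.max(fit - hi0) / 2.0))


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip: sup-norm distance of the ecdf to the nearest unimodal cdf.

    The sorted sample is split at every candidate mode position into a
    convex (left) and concave (right) region; the deviation of each side is
    half the worst violation between the ecdf corridor (both ecdf limits at
    each value) and the greatest convex minorant (resp. least concave
    majorant) of the corridor.  The left deviation is nondecreasing and the
    right deviation nonincreasing in the split position, so the minimax
    between-point split is located by bisection.  A unimodal cdf may itself
    jump at its mode, so splits *at* a data value — where the fitted cdf
    only has to meet each one-sided ecdf limit — are also scanned; they
    matter when the data contain ties.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 2 or x[0] == x[-1]:
        return 0.0
    xs, upper0, lower0 = _collapse_ties(x)
    m = xs.size
    if m == 1:
        return 0.0

    def d_left(k: int) -> float:
        # convex fit on the first k unique points
        return _convex_dev(xs[:k], upper0[:k], lower0[:k])

    def d_right(k: int) -> float:
        # concave fit on points k..m-1
        return _concave_dev(xs[k:], upper0[k:], lower0[k:])

    lo, hi = 0, m  # smallest k with d_left(k) >= d_right(k) (monotone predicate)
    while lo < hi:
        mid = (lo + hi) // 2
        if d_left(mid) >= d_right(mid):
            hi = mid
        else:
            lo = mid + 1
    best = np.inf
    for k in range(max(0, lo - 2), min(m, lo + 2) + 1):
        best = min(best, max(d_left(k), d_right(k)))

    def d_at_point(j: int) -> float:
        # mode at xs[j]: the cdf may jump there, so the left chain only has
        # to meet the left ecdf limit and the right chain the right limit
        hi_l, lo_l = upper0[: j + 1].copy(), lower0[: j + 1].copy()
        lo_l[j] = hi_l[j]
        hi_r, lo_r = upper0[j:].copy(), lower0[j:].copy()
        hi_r[0] = lo_r[0]
        return max(
            _convex_dev(xs[: j + 1], hi_l, lo_l),
            _concave_dev(xs[j:], hi_r, lo_r),
        )

    n = x.size
    tie_jump = (lower0 - upper0) * n > 1.5  # values with multiplicity > 1
    candidates = set(np.nonzero(tie_jump)[0].tolist())
    candidates.update(range(max(0, lo - 2), min(m, lo + 2)))
    for j in candidates:
        best = min(best, d_at_point(j))
    return float(best)


def dip_test_calibrated(values: np.ndarray, n_boot: int = 500, seed=0) -> tuple[float, float]:
    """Dip statistic with a Monte-Carlo p-value from uniform nulls of the same n.

    Returns ``(dip, p)`` with ``p = (1 + #{null >= dip}) / (1 + n_boot)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 observations")
    obs = dip_statistic(values)
    rng = np.random.default_rng(seed)
    null = np.array([dip_statistic(rng.uniform(size=values.size)) for _ in range(n_boot)])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_boot)
    return obs, float(p)


# ---------------------------------------------------------------------------
# Narrow/broad split
# ---------------------------------------------------------------------------


def split_narrow_broad(
    metrics: pd.DataFrame, seed=0, n_init: int = 20, tol: float = 1e-8
) -> tuple[np.ndarray, dict]:
    """Gaussian-mixture narrow/broad labeling on the (HR, T4R) plane.

    Fits 1- and 2-component mixtures on the standardized 2-D metrics and on
    each 1-D marginal, reporting AIC/BIC per model.  When BIC prefers two
    components, units are labeled by maximum posterior responsibility; the
    component with the larger mean HR is "narrow".  Returns the boolean
    narrow flags and a fit report (AIC/BIC tables, mixture weights, the
    first PCA component of (HR, T4R) — reported only, never clustered on).
    """
    if len(metrics) < 30:
        raise ValueError("need at least 30 units")
    X = metrics[["HR", "T4R"]].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) waveform feature")
    Z = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)

    def gmm_fit(data, k):
        g = GaussianMixture(
            n_components=k,
            n_init=n_init,
            tol=tol,
            random_state=int(rng.integers(2**31)),
        ).fit(data)
        return g

    report: dict = {"aic": {}, "bic": {}}
    fits = {}
    for name, data in [("HR_T4R", Z), ("HR", Z[:, [0]]), ("T4R", Z[:, [1]])]:
        for k in (1, 2):
            g = gmm_fit(data, k)
            report["aic"][(name, k)] = float(g.aic(data))
            report["bic"][(name, k)] = float(g.bic(data))
            fits[(name, k)] = g
    report["two_components_preferred"] = (
        report["bic"][("HR_T4R", 2)] < report["bic"][("HR_T4R", 1)]
    )
    report["pca1"] = PCA(n_components=1).fit_transform(Z).ravel()

    g2 = fits[("HR_T4R", 2)]
    report["weights"] = g2.weights_.copy()
    if report["two_components_preferred"]:
        resp = g2.predict(Z)
        narrow_comp = int(np.argmax(g2.means_[:, 0]))  # larger HR -> narrow
        narrow = resp == narrow_comp
    else:
        narrow = np.zeros(len(metrics), dtype=bool)
    return narrow, report
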