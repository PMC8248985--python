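"""Firing-rate circuit motifs for the gamma/beta and gamma/theta switches.

Two delayed Wilson-Cowan-type motifs reproduce the interneuron-specific
synchronization switches observed in prefrontal and cingulate cortex:

- **E-E-I**: one inhibitory population receives input from two excitatory
  populations (value-coding pyramidal pools) and inhibits both.  With
  balanced, high drive to both E pools (similar stimulus values, i.e. low
  choice certainty) the loop synchronizes in the gamma band (35-45 Hz);
  when one drive dominates, the lower total effective drive moves the
  network into the beta band (20-35 Hz).
- **E-I-I**: one excitatory population is reciprocally coupled to a fast
  (I1, putative PV+ basket cells) and a slow (I2) inhibitory population.
  Stronger drive to I1 yields gamma; stronger drive to I2 imposes slow
  theta/alpha (6-14 Hz) synchrony.  The "disinhibition" preset realizes
  the high-prediction-error state by lowering the drive to I2.

Each population obeys ``tau_p dr/dt = -r + F(sum_q W_pq r_q(t - D) + d_p +
noise)`` with a sigmoidal transfer ``F(x) = rmax / (1 + exp(-(x - theta)/s))``
integrated by Euler steps of 0.05 ms with a common synaptic delay D.
Dominant frequency is the argmax above 3 Hz of the Welch spectrum (2 s
windows, 50% overlap) of the summed excitatory rate.  The default
parameterization is pinned and versioned as the regression oracle; the
contract is the qualitative regime structure (band membership), not exact
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "MotifParams",
    "MotifTrace",
    "EEI_DEFAULTS",
    "EII_DEFAULTS",
    "EEI_BALANCED",
    "EEI_ASYMMETRIC",
    "EII_GAMMA",
    "EII_THETA",
    "simulate_motif",
    "simulate_eei",
    "simulate_eii",
    "dominant_frequency",
    "drive_sweep",
    "acc_disinhibition_preset",
]

BANDS = {"theta": (6.0, 14.0), "beta": (20.0, 35.0), "gamma": (35.0, 45.0)}


@dataclass
class MotifParams:
    """Parameters of a delayed rate-model motif."""

    tau: tuple  # population time constants (ms)
    W: tuple  # rows: target population; columns: source (signed weights)
    drives: tuple  # tonic external drives per population
    delay: float = 1.5  # synaptic delay (ms)
    dt: float = 0.05  # integration step (ms)
    noise_sd: float = 0.5
    rmax: float = 100.0  # transfer ceiling (arbitrary rate units)
    gain: float | tuple = 0.08  # sigmoid slope (scalar or per population)
    theta: float | tuple = 20.0  # sigmoid midpoint (scalar or per population)

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.tau):
            raise ValueError("time constants must be positive")
        if self.dt >= min(self.tau) / 10:
            raise ValueError("integration step must be below min(tau)/10")
        n = len(self.tau)
        self.gain = tuple(np.broadcast_to(self.gain, n).astype(float))
        self.theta = tuple(np.broadcast_to(self.theta, n).astype(float))


@dataclass
class MotifTrace:
    """Simulated population rates with spectral summary."""

    time: np.ndarray  # s
    rates: np.ndarray  # (n_steps, n_pop)
    freqs: np.ndarray
    power: np.ndarray
    dominant_freq: float
    band: str | None = field(default=None)


def _transfer(x, rmax, gain, theta):
    return rmax / (1.0 + np.exp(-gain * (x - theta)))


def simulate_motif(
    params: MotifParams,
    duration: float = 6.0,
    seed=0,
    excitatory: tuple = (0,),
    discard: float = 1.0,
) -> MotifTrace:
    """Integrate the motif and summarize its rhythm.

    ``excitatory`` indexes the populations whose summed rate is used for
    the spectrum.  The first ``discard`` seconds are dropped as transient.
    Raises on divergent (non-finite) trajectories.
    """
    rng = np.random.default_rng(seed)
    tau = np.asarray(params.tau, dtype=float)
    W = np.asarray(params.W, dtype=float)
    d = np.asarray(params.drives, dtype=float)
    gain = np.asarray(params.gain, dtype=float)
    theta = np.asarray(params.theta, dtype=float)
    n_pop = tau.size
    dt = params.dt
    n_steps = int(round(duration * 1000.0 / dt))
    n_delay = max(1, int(round(params.delay / dt)))
    r = np.zeros((n_steps, n_pop))
    r[0] = _transfer(d, params.rmax, gain, theta) * 0.5
    sq = np.sqrt(dt)
    noise = params.noise_sd * rng.standard_normal((n_steps, n_pop)) * sq
    for t in range(1, n_steps):
        rd = r[max(0, t - n_delay)]
        inp = W @ rd + d + noise[t]
        drdt = (-r[t - 1] + _transfer(inp, params.rmax, gain, theta)) / tau
        r[t] = r[t - 1] + dt * drdt
        if not np.all(np.isfinite(r[t])):
            raise FloatingPointError(
                f"divergent trajectory at step {t}; max rate {np.nanmax(r[: t + 1])}"
            )
    fs = 1000.0 / dt
    keep = r[int(discard * 1000.0 / dt) :]
    drive_sig = keep[:, list(excitatory)].sum(axis=1)
    nperseg = min(int(2.0 * fs), drive_sig.size)
    freqs, power = signal.welch(
        drive_sig - drive_sig.mean(), fs=fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    # smooth over ~4 Hz before the argmax: noise-driven resonances are broad
    df = freqs[1] - freqs[0]
    k = max(1, int(round(4.0 / df)))
    smoothed = np.convolve(power, np.ones(k) / k, mode="same")
    sel = freqs >= 3.0
    fdom = float(freqs[sel][np.argmax(smoothed[sel])])
    band = next((name for name, (lo, hi) in BANDS.items() if lo <= fdom <= hi), None)
    time = np.arange(n_steps) * dt / 1000.0
    return MotifTrace(
        time=time, rates=r, freqs=freqs, power=power, dominant_freq=fdom, band=band
    )


def dominant_frequency(trace: MotifTrace) -> float:
    return trace.dominant_freq


# ---------------------------------------------------------------------------
# Pinned default motifs
# ---------------------------------------------------------------------------

# E-E-I: populations (E1, E2, I).  Pinned once: with balanced high drive
# the E-I loop runs a weak limit cycle whose frequency (~40 Hz) is set by
# the time constants and delay, hence robust to weight perturbations; with
# one dominant drive the loop is subcritical and the noise-driven resonance
# sits in the beta band.  The I population has a high sigmoid midpoint so
# its operating-point gain tracks the *total* excitatory drive.
EEI_DEFAULTS = MotifParams(
    tau=(9.0, 9.0, 21.0),
    W=(
        (0.0, 0.0, -4.5),
        (0.0, 0.0, -4.5),
        (1.0, 1.0, 0.0),
    ),
    drives=(240.0, 240.0, 0.0),
    delay=1.2,
    noise_sd=1.0,
    gain=(0.04, 0.04, 0.08),
    theta=(50.0, 50.0, 85.0),
)

#: Pinned drive conditions: balanced high drive (similar stimulus values,
#: low choice certainty) vs one dominant drive with lower total drive.
EEI_BALANCED = (240.0, 240.0)
EEI_ASYMMETRIC = (140.0, 30.0)

# E-I-I: populations (E, I1 fast, I2 slow).  Recurrent excitation makes the
# fast subsystem bistable; the slow I2 then sweeps it through a theta-band
# relaxation cycle when driven, while drive to I1 instead engages the fast
# delayed E-I1 loop at gamma.
EII_DEFAULTS = MotifParams(
    tau=(9.0, 7.5, 130.0),
    W=(
        (2.0, -4.5, -4.5),
        (2.0, 0.0, 0.0),
        (1.5, 0.0, 0.0),
    ),
    drives=(80.0, 40.0, -60.0),
    delay=1.0,
    noise_sd=1.0,
    gain=(0.04, 0.08, 0.08),
    theta=(50.0, 85.0, 85.0),
)

#: Pinned drive conditions: fast-interneuron dominant (high prediction
#: error, gamma) vs slow-interneuron dominant (expected outcome, theta).
EII_GAMMA = (40.0, -60.0)
EII_THETA = (-100.0, 20.0)


def simulate_eei(
    d_E1: float,
    d_E2: float,
    params: MotifParams = EEI_DEFAULTS,
    duration: float = 6.0,
    seed=0,
) -> MotifTrace:
    """E-E-I motif with the two excitatory drives set explicitly."""
    p = replace(params, drives=(d_E1, d_E2, params.drives[2]))
    return simulate_motif(p, duration=duration, seed=seed, excitatory=(0, 1))


def simulate_eii(
    d_I1: float,
    d_I2: float,
    params: MotifParams = EII_DEFAULTS,
    duration: float = 6.0,
    seed=0,
) -> MotifTrace:
    """E-I-I motif with the two inhibitory drives set explicitly."""
    if not params.tau[1] < params.tau[2]:
        raise ValueError("I1 must be the faster population (tau_I1 < tau_I2)")
    p = replace(params, drives=(params.drives[0], d_I1, d_I2))
    return simulate_motif(p, duration=duration, seed=seed, excitatory=(0,))


def acc_disinhibition_preset(
    level: float = 100.0, params: MotifParams = EII_DEFAULTS
) -> MotifParams:
    """High-prediction-error state by disinhibition.

    Lowering the drive to the slow I2 population releases the fast I1
    population (its effective drive rises by the same amount), switching
    the network from theta to gamma.
    """
    return replace(
        params,
        drives=(params.drives[0], params.drives[1] + level, params.drives[2] - level),
    )


def drive_sweep(
    motif: str,
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    duration: float = 4.0,
    seed=0,
) -> dict:
    """Phase diagram of dominant frequency over a drive grid.

    ``motif`` is "eei" (grids = d_E1, d_E2) or "eii" (grids = d_I1, d_I2).
    """
    if motif not in ("eei", "eii"):
        raise ValueError("motif must be 'eei' or 'eii'")
    sim = simulate_eei if motif == "eei" else simulate_eii
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    freq = np.empty((grid_a.size, grid_b.size))
    band = np.empty((grid_a.size, grid_b.size), dtype=object)
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            tr = sim(a, b, duration=duration, seed=seed)
            freq[i, j] = tr.dominant_freq
            band[i, j] = tr.band
    return {"a": grid_a, "b": grid_b, "freq": freq, "band": band}
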