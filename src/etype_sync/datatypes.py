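"""Core containers shared across the analysis stages.

All times are in seconds; intervals are half-open ``[t0, t0 + duration)``.
Trial tables are plain :class:`pandas.DataFrame` objects with the column
contract documented in :data:`TRIAL_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Required columns of a trial table.
TRIAL_COLUMNS = (
    "block_id",
    "trial_in_block",
    "feature1_onset",
    "feature2_onset",
    "color_onset",
    "motion_onset",
    "outcome_onset",
    "color_first",
    "rewarded_color",
    "chosen_color",
    "chosen_location",
    "chosen_direction",
    "reward",
)


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit.

    Parameters
    ----------
    unit_id:
        Unit identifier.
    times:
        Strictly increasing spike times in seconds, within
        ``[0, duration)``.
    duration:
        Recording length in seconds.
    area:
        Brain-area label (``"LPFC"``, ``"ACC"`` or ``"synthetic"``).
    """

    unit_id: str
    times: np.ndarray
    duration: float
    area: str = "synthetic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D array")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)


@dataclass
class LfpChannel:
    """One LFP channel: regularly sampled voltages starting at ``t0``."""

    channel_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class Waveform:
    """Trough-aligned, amplitude-normalized mean action potential.

    ``samples`` span ``[-1, 1]`` after normalization (trough at -1, peak
    at +1 only when the peak equals the range maximum; in general the
    global extrema are mapped onto the interval edges).  ``dt`` is the
    sampling step in seconds (1/32000 raw; 1/320000 after 10x
    interpolation).
    """

    samples: np.ndarray
    dt: float
    trough_index: int = field(default=-1)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.trough_index < 0:
            self.trough_index = int(np.argmin(self.samples))

    def time(self) -> np.ndarray:
        """Sample times in seconds relative to the trough."""
        return (np.arange(self.samples.size) - self.trough_index) * self.dt
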