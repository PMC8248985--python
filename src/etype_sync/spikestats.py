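"""Per-unit firing statistics: rate, CV, LV, Fano factor and burst index.

Conventions
-----------
- LV uses the Shinomoto normalization with the factor 3, so a Poisson
  (exponential-ISI) train has expectation 1 and a constant-ISI train 0:

  .. math:: LV = \\frac{3}{n-1} \\sum_{i=1}^{n-1}
            \\left( \\frac{I_i - I_{i+1}}{I_i + I_{i+1}} \\right)^2

- CV uses the population (n-denominator) standard deviation by default;
  pass ``ddof=1`` for the sample convention.
- The Fano factor tiles the whole recording with non-overlapping windows;
  a partial last window is dropped.
- The burst index is the proportion of ISIs below 5 ms among ISIs below
  100 ms, normalized by the same ratio expected for a Poisson process of
  the unit's rate, so BI > 1 means more bursting than Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import SpikeTrain

__all__ = [
    "UnitFeatures",
    "compute_cv",
    "compute_lv",
    "compute_ff",
    "compute_burst_index",
    "unit_features",
]


@dataclass
class UnitFeatures:
    """Firing-statistic feature vector of one unit."""

    rate: float
    CV: float
    LV: float
    FF: float
    BI: float
    n_spikes: int


def _check_isis(isis: np.ndarray, min_n: int = 2) -> np.ndarray:
    isis = np.asarray(isis, dtype=float)
    if isis.size < min_n:
        raise ValueError(f"need at least {min_n} inter-spike intervals, got {isis.size}")
    return isis


def compute_cv(isis: np.ndarray, ddof: int = 0) -> float:
    """Coefficient of variation: SD over mean of the inter-spike intervals."""
    isis = _check_isis(isis)
    mean = isis.mean()
    if mean <= 0:
        raise ValueError("mean ISI must be positive")
    return float(isis.std(ddof=ddof) / mean)


def compute_lv(isis: np.ndarray) -> float:
    """Local variation of consecutive inter-spike intervals."""
    isis = _check_isis(isis)
    if np.any(isis <= 0):
        raise ValueError("all ISIs must be positive")
    a, b = isis[:-1], isis[1:]
    terms = ((a - b) / (a + b)) ** 2
    return float(3.0 * terms.mean())


def compute_ff(train: SpikeTrain, window: float = 0.1) -> float:
    """Fano factor of spike counts in non-overlapping windows (default 100 ms).

    Returns NaN (flagged missing) when the mean count is zero.
    """
    n_win = int(train.duration / window)
    if n_win < 10:
        raise ValueError("recording must span at least 10 windows")
    edges = np.arange(n_win + 1) * window
    counts, _ = np.histogram(train.times, bins=edges)
    mean = counts.mean()
    if mean == 0:
        return float("nan")
    return float(counts.var() / mean)


def compute_burst_index(isis: np.ndarray, rate: float) -> float:
    """Poisson-normalized burst index.

    Raw ratio = #(ISI < 5 ms) / #(ISI < 100 ms), divided by the Poisson
    expectation ``(1 - exp(-0.005 rate)) / (1 - exp(-0.1 rate))``.
    Returns NaN when no ISI falls below 100 ms.
    """
    isis = np.asarray(isis, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_100 = int(np.sum(isis < 0.100))
    if n_100 == 0:
        return float("nan")
    raw = np.sum(isis < 0.005) / n_100
    expected = (1.0 - math.exp(-0.005 * rate)) / (1.0 - math.exp(-0.1 * rate))
    return float(raw / expected)


def unit_features(train: SpikeTrain, ff_window: float = 0.1) -> UnitFeatures:
    """All firing statistics of one unit in a single pass."""
    isis = train.isis()
    return UnitFeatures(
        rate=train.rate,
        CV=compute_cv(isis),
        LV=compute_lv(isis),
        FF=compute_ff(train, ff_window),
        BI=compute_burst_index(isis, train.rate),
        n_spikes=train.n_spikes,
    )
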