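"""Smoothed-moving-average filtering and saturation normalization.

The SMMA is an online (causal) windowed mean of width ``K`` samples: at
each time step the oldest sample leaves the window and the newest enters,
so the filter output is the mean of the most recent ``K`` readings.  At
the start of the series, where fewer than ``K`` samples exist, the mean
is taken over the samples available so far, which keeps the output the
same length as the input without needing future data.

Normalization maps voltages into the unit interval by dividing by the
channel's saturation value, so all downstream features are unitless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SmoothedSeries:
    """A filtered series together with the window it was filtered with."""

    values: np.ndarray
    window: int
    source_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.values.size != self.source_length:
            raise ValueError("smoothed series must preserve length")


@dataclass
class NormalizedSeries:
    """A unitless series in [0, 1] plus the saturation used to scale it."""

    values: np.ndarray
    saturation: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.saturation <= 0:
            raise ValueError("saturation must be positive")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("normalized values must lie in [0, 1]")

    def denormalize(self) -> np.ndarray:
        return self.values * self.saturation


def smma(series, window: int) -> SmoothedSeries:
    """Causal moving mean: ``out[t] = mean(series[max(0, t-K+1) .. t])``.

    Implemented with a cumulative sum so the cost is O(n) regardless of
    the window size.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("smma expects a 1-D series")
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return SmoothedSeries(values=x.copy(), window=1, source_length=x.size)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - window + 1)
    out = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    return SmoothedSeries(values=out, window=window, source_length=x.size)


def normalize(series, saturation: float) -> NormalizedSeries:
    """Divide by the channel saturation, mapping [0, s] onto [0, 1].

    A reading above the saturation signals a mis-configured saturation
    and raises rather than silently clipping.
    """
    x = np.asarray(series, dtype=float)
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    if np.any(x < 0):
        raise ValueError("series contains negative values")
    if np.any(x > saturation):
        raise ValueError("series exceeds the configured saturation value")
    return NormalizedSeries(values=x / saturation, saturation=float(saturation))
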