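"""Windowed gradient features of smoothed, normalized sensor series.

The gradient signature of a series S is its rate of change evaluated
whenever t is a multiple of the smoothing window K:

    T(t) = (S(t) - S(0)) / t        for t <= K
    T(t) = (S(t) - S(t - K)) / K    for t >  K

The first branch fires exactly once, at t = K, where the two branches
coincide.  The grid therefore starts at t = K (t = 0 would divide by
zero) and steps by K up to the series length.  Profiles carry a role
flag distinguishing query (test) data from reference (input) data; the
formula is identical for both and the flag is bookkeeping only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import SmoothedSeries, normalize, smma
from .sim import CHANNELS, N_CHANNELS, SensorFrame


@dataclass
class GradientProfile:
    """Per-channel gradient values on the common grid t = K, 2K, ...

    ``values`` has shape ``(n_channels, n_epochs)``; ``epochs`` holds the
    evaluation times in seconds (multiples of the window).
    """

    channels: tuple[str, ...]
    epochs: np.ndarray
    values: np.ndarray
    window: int
    role: str = "query"
    label: str | None = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channels), self.epochs.size):
            raise ValueError("values must have shape (n_channels, n_epochs)")
        if np.any(self.epochs % self.window != 0) or np.any(self.epochs < self.window):
            raise ValueError("epochs must be positive multiples of the window")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gradient values must be finite")

    @property
    def n_epochs(self) -> int:
        return self.epochs.size

    def to_dict(self) -> dict:
        return {
            "window": int(self.window),
            "role": self.role,
            "label": self.label,
            "epochs": self.epochs.tolist(),
            "channel_order": list(self.channels),
            "channels": {
                name: self.values[i].tolist() for i, name in enumerate(self.channels)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradientProfile":
        channels = tuple(d.get("channel_order", d["channels"]))
        values = np.array([d["channels"][name] for name in channels], dtype=float)
        return cls(channels=channels, epochs=np.asarray(d["epochs"]), values=values,
                   window=int(d["window"]), role=d.get("role", "query"),
                   label=d.get("label"))


def gradient_series(smoothed: SmoothedSeries | Sequence[float], window: int | None = None):
    """Two-branch windowed gradient of one smoothed channel.

    Returns ``(epochs, values)`` with epochs K, 2K, ... up to the last
    sample index.  Needs at least ``K + 1`` samples so that S(K) exists.
    """
    if isinstance(smoothed, SmoothedSeries):
        s = smoothed.values
        window = smoothed.window if window is None else int(window)
    else:
        s = np.asarray(smoothed, dtype=float)
        if window is None:
            raise ValueError("window is required for a bare array")
        window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if s.size <= window:
        raise ValueError(f"series must be longer than the window ({window} samples)")
    epochs = np.arange(window, s.size, window)
    values = np.empty(epochs.size)
    for i, t in enumerate(epochs):
        if t <= window:
            values[i] = (s[t] - s[0]) / t
        else:
            values[i] = (s[t] - s[t - window]) / window
    return epochs, values


def profile_of_frame(frame: SensorFrame, window: int,
                     saturations: Sequence[float] | float,
                     role: str = "query") -> GradientProfile:
    """Full per-channel pipeline: SMMA -> normalize -> windowed gradient.

    All 8 channels land on the same epoch grid.
    """
    sats = np.asarray(saturations, dtype=float)
    if sats.ndim == 0:
        sats = np.full(N_CHANNELS, float(sats))
    if sats.shape != (N_CHANNELS,):
        raise ValueError("saturations must be scalar or one per channel")
    rows = []
    epochs = None
    for c in range(N_CHANNELS):
        smoothed = smma(frame.values[c], window)
        norm = normalize(smoothed.values, sats[c])
        ep, grad = gradient_series(norm.values, window)
        epochs = ep if epochs is None else epochs
        rows.append(grad)
    return GradientProfile(channels=tuple(frame.channels), epochs=epochs,
                           values=np.vstack(rows), window=window, role=role,
                           label=frame.label)


def steady_state_features(frame: SensorFrame, window: int,
                          saturations: Sequence[float] | float) -> np.ndarray:
    """Per-channel smoothed, normalized end-of-event response (8-vector in [0,1]).

    This is the compact feature vector consumed by the genetic stage: the
    late-time window mean of each channel divided by its saturation, i.e.
    the normalized plateau level the sensor settled at.
    """
    sats = np.asarray(saturations, dtype=float)
    if sats.ndim == 0:
        sats = np.full(N_CHANNELS, float(sats))
    out = np.empty(N_CHANNELS)
    for c in range(N_CHANNELS):
        smoothed = smma(frame.values[c], window)
        out[c] = normalize(smoothed.values, sats[c]).values[-1]
    return out
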