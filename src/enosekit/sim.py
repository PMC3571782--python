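"""Synthetic gas-sensor-array event generator.

Emulates the response of an 8-channel metal-oxide-semiconductor (MOS)
sensor array exposed to a decaying food sample: each channel shows a
saturating exponential rise from its baseline toward a class-dependent
plateau, superimposed with a slow linear drift of the semiconductor and
additive Gaussian read noise, all sampled at 1 Hz as voltages.

The generator is first-class code: every downstream stage (smoothing,
gradient features, the genetic/neural classifier, database matching) is
exercised against events drawn from it, since no public recordings of
this kind of experiment exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Channel order of the 8-gas sensor array.
CHANNELS: tuple[str, ...] = (
    "O3", "LPG_LNG", "NOx", "alcohol", "smoke", "VOC", "CO", "NH3",
)

N_CHANNELS = len(CHANNELS)

#: Default event length in samples (1 Hz, so also seconds).
DEFAULT_DURATION = 1000


def _as_channel_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N_CHANNELS, float(arr))
    if arr.shape != (N_CHANNELS,):
        raise ValueError(f"{name} must be a scalar or length-{N_CHANNELS} sequence")
    return arr


@dataclass(frozen=True)
class ClassSpec:
    """Response model of one substance class (e.g. one decay day of one food).

    Channel ``c`` of an event follows

        v_c(t) = b_c + A_c * (1 - exp(-t / tau_c)) + drift * t + eps(t)

    with ``eps ~ N(0, noise_sd^2)`` i.i.d. per sample, clipped to
    ``[0, s_c]`` where ``s_c`` is the channel's saturation voltage.

    Parameters
    ----------
    label : substance class name, e.g. ``"decayed_fish_day2"``.
    amplitude : per-channel plateau rise ``A_c`` above baseline [V].
    rise_time : per-channel time constant ``tau_c`` [s]; must be > 0.
    baseline : per-channel clean-air offset ``b_c`` [V].
    saturation : per-channel sensor ceiling ``s_c`` [V]; also the value
        used downstream to normalize readings into [0, 1].
    drift : slow linear baseline drift shared by all channels [V/s].
    noise_sd : additive Gaussian noise standard deviation [V].
    """

    label: str
    amplitude: Sequence[float]
    rise_time: Sequence[float]
    baseline: Sequence[float]
    saturation: Sequence[float] = field(default=5.0)
    drift: float = 0.002
    noise_sd: float = 0.002

    def __post_init__(self):
        a = _as_channel_array(self.amplitude, "amplitude")
        tau = _as_channel_array(self.rise_time, "rise_time")
        b = _as_channel_array(self.baseline, "baseline")
        s = _as_channel_array(self.saturation, "saturation")
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "rise_time", tau)
        object.__setattr__(self, "baseline", b)
        object.__setattr__(self, "saturation", s)
        if not self.label:
            raise ValueError("label must be non-empty")
        if np.any(s <= 0):
            raise ValueError("saturation must be positive on every channel")
        if np.any(tau <= 0):
            raise ValueError("rise_time must be positive on every channel")
        if np.any(b < 0) or np.any(b + a > s):
            raise ValueError("need 0 <= baseline <= baseline + amplitude <= saturation")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def noiseless_curve(self, duration: int) -> np.ndarray:
        """Deterministic mean response, shape (8, duration), pre-clipping."""
        t = np.arange(int(duration), dtype=float)
        rise = self.amplitude[:, None] * (1.0 - np.exp(-t[None, :] / self.rise_time[:, None]))
        return self.baseline[:, None] + rise + self.drift * t[None, :]

    def with_noise(self, noise_sd: float) -> "ClassSpec":
        return replace(self, noise_sd=noise_sd)


@dataclass
class SensorFrame:
    """One recorded event: 8 voltage series on a uniform 1 Hz grid.

    ``values`` has shape ``(8, n_samples)`` in channel order ``channels``;
    ``times`` is the 0-based second index.
    """

    times: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.channels) != N_CHANNELS:
            raise ValueError(f"expected exactly {N_CHANNELS} channels")
        if self.values.shape != (N_CHANNELS, self.times.size):
            raise ValueError("values must have shape (8, len(times))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensor values must be finite")
        if np.any(self.values < 0):
            raise ValueError("sensor voltages must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.times.size


def generate_event(spec: ClassSpec, duration: int = DEFAULT_DURATION,
                   seed: int | np.random.SeedSequence | None = None) -> SensorFrame:
    """Draw one seeded synthetic event for ``spec``.

    The channel value at second ``t`` is the saturating rise plus drift
    plus Gaussian noise, clipped to ``[0, s_c]``. Identical seeds give
    bitwise-identical frames.
    """
    duration = int(duration)
    if duration < 1:
        raise ValueError("duration must be at least 1 sample")
    rng = np.random.default_rng(seed)
    clean = spec.noiseless_curve(duration)
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    values = np.clip(clean, 0.0, spec.saturation[:, None])
    return SensorFrame(times=np.arange(duration, dtype=float), values=values,
                       label=spec.label)


def average_event(frames: Sequence[SensorFrame]) -> SensorFrame:
    """Per-time, per-channel mean of several frames.

    The label is preserved when all inputs agree on it, otherwise dropped.
    """
    if len(frames) == 0:
        raise ValueError("cannot average an empty list of frames")
    first = frames[0]
    for f in frames[1:]:
        if f.values.shape != first.values.shape or f.channels != first.channels:
            raise ValueError("all frames must share length and channels")
    labels = {f.label for f in frames}
    label = labels.pop() if len(labels) == 1 else None
    mean = np.mean([f.values for f in frames], axis=0)
    return SensorFrame(times=first.times.copy(), values=mean,
                       channels=first.channels, label=label)


@dataclass
class Study:
    """A labelled train/test split of generated events."""

    train: list[SensorFrame]
    test: list[SensorFrame]

    def by_class(self, which: str = "train") -> dict[str, list[SensorFrame]]:
        out: dict[str, list[SensorFrame]] = {}
        for frame in getattr(self, which):
            out.setdefault(frame.label, []).append(frame)
        return out


def generate_study(specs: Sequence[ClassSpec], n_events: int = 50,
                   train_fraction: float = 0.6,
                   duration: int = DEFAULT_DURATION,
                   seed: int | np.random.SeedSequence | None = None) -> Study:
    """Generate the repeated-measurement study: ``n_events`` seeded events
    per class, split deterministically into train/test (defaults 30/20).
    """
    if len(specs) == 0:
        raise ValueError("need at least one ClassSpec")
    if n_events < 2:
        raise ValueError("need at least 2 events per class to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n_events))
    n_train = min(max(n_train, 1), n_events - 1)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    train: list[SensorFrame] = []
    test: list[SensorFrame] = []
    for spec, class_seed in zip(specs, root.spawn(len(specs))):
        event_seeds = class_seed.spawn(n_events + 1)
        frames = [generate_event(spec, duration, s) for s in event_seeds[:n_events]]
        order = np.random.default_rng(event_seeds[-1]).permutation(n_events)
        train.extend(frames[i] for i in order[:n_train])
        test.extend(frames[i] for i in order[n_train:])
    return Study(train=train, test=test)


def _spec(label, amplitude, rise_time):
    # Shared geometry of the built-in library: 5 V ceiling, 0.3 V baseline,
    # 2 mV/s drift and 2 mV noise.  Amplitudes stay <= 2.5 V so that
    # baseline + amplitude + 1000 s of drift never reaches the ceiling.
    return ClassSpec(label=label, amplitude=amplitude, rise_time=rise_time,
                     baseline=0.3, saturation=5.0, drift=0.002, noise_sd=0.002)


#: Illustrative built-in classes named after food-decay conditions.  The
#: parameters are hand-chosen to reproduce the qualitative structure of
#: such experiments (response growing with decay day; fish and meat
#: exciting different channel subsets); they are not fits to real sensors.
BUILTIN_SPECS: Mapping[str, ClassSpec] = {
    s.label: s for s in [
        #                 O3    LPG   NOx   alc   smk   VOC   CO    NH3
        _spec("fresh_fish",
              [0.40, 0.50, 0.30, 0.60, 0.50, 0.80, 0.40, 0.70],
              [150., 220., 180., 130., 260., 170., 300., 140.]),
        _spec("decayed_fish_day1",
              [0.90, 1.10, 0.70, 1.50, 1.20, 1.70, 0.90, 1.60],
              [140., 210., 170., 120., 240., 160., 280., 130.]),
        _spec("decayed_fish_day2",
              [1.40, 1.80, 1.10, 2.30, 1.90, 2.40, 1.30, 2.40],
              [130., 200., 160., 110., 220., 150., 260., 120.]),
        _spec("fresh_meat",
              [0.50, 0.40, 0.40, 0.50, 0.70, 0.90, 0.50, 0.40],
              [200., 160., 240., 180., 140., 210., 160., 320.]),
        _spec("decayed_meat_day1",
              [1.00, 0.80, 0.90, 1.20, 1.50, 1.80, 1.10, 0.80],
              [190., 150., 230., 170., 130., 200., 150., 300.]),
        _spec("decayed_meat_day2",
              [1.60, 1.20, 1.50, 1.90, 2.20, 2.50, 1.70, 1.20],
              [180., 140., 220., 160., 120., 190., 140., 280.]),
    ]
}
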