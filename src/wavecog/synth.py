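"""Synthetic two-class multichannel EEG epochs with dyadic-band structure.

The generator emulates a cognitive-task vs baseline contrast: each channel
of an epoch is a sum of unit-variance band-limited processes — one per
dyadic wavelet sub-band (A5, D5..D1 for a 5-level pyramid) — weighted by
class-dependent amplitudes, plus 1/f-shaped pink noise.  The class
difference is therefore a controllable shift of spectral power between
sub-bands, the feature family the downstream pipeline extracts.

Each band process is a mixture of K random-phase sinusoids whose
frequencies are drawn strictly inside the band (kept away from the dyadic
edges by a 2%-of-bandwidth margin to limit cross-band leakage through the
finite filter transition bands), normalized to unit sample variance.
Sinusoid mixtures give exact spectral confinement without any filter
design, at the cost of being far more stationary than real EEG.

The default configuration is the study condition used throughout the test
suite: 280 epochs per class at 250 Hz, the task class carrying extra power
in the two lowest bands (A5: 0–3.9 Hz and D5: 3.9–7.8 Hz, where slow
cognitive-task activity dominates), over a common pink-noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dwt import band_labels, subband_ranges

__all__ = [
    "SynthConfig",
    "Epoch",
    "EpochSet",
    "generate_epoch",
    "generate_dataset",
    "expected_relative_energy",
]

BAND_SET = frozenset(band_labels(5))  # {A5, D5, D4, D3, D2, D1}

_DEFAULT_W1 = {"A5": 1.6, "D5": 1.3, "D4": 1.0, "D3": 1.0, "D2": 1.0, "D1": 1.0}
_DEFAULT_W2 = {"A5": 1.0, "D5": 1.0, "D4": 1.0, "D3": 1.0, "D2": 1.0, "D1": 1.0}

# fraction of band width kept clear of each dyadic edge
_EDGE_MARGIN = 0.02


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the two-class synthetic EEG generator.

    Parameters
    ----------
    n_epochs_per_class : epochs generated for each of the two classes.
    n_channels : channels per epoch (128 emulates a high-density montage,
        6 a small clinical one).
    fs : sampling rate in Hz.
    epoch_len : samples per epoch; must be a positive multiple of 32 so a
        5-level periodic pyramid needs no padding.
    band_weights_class1/2 : amplitude weight of each sub-band's
        unit-variance process, keyed by {A5, D5, D4, D3, D2, D1}.
    pink_noise_level : amplitude of the unit-variance 1/f noise floor.
    sinusoids_per_band : K, sinusoids mixed per band process.
    channel_gain_jitter : per-channel gain drawn uniformly in
        [1 - jitter, 1 + jitter].
    seed : master seed; every epoch derives its own substream from it.
    """

    n_epochs_per_class: int = 280
    n_channels: int = 8
    fs: float = 250.0
    epoch_len: int = 2048
    band_weights_class1: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_W1)
    )
    band_weights_class2: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_W2)
    )
    pink_noise_level: float = 0.5
    sinusoids_per_band: int = 40
    channel_gain_jitter: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.epoch_len <= 0 or self.epoch_len % 32:
            raise ValueError("epoch_len must be a positive multiple of 32")
        if self.n_epochs_per_class < 1 or self.n_channels < 1:
            raise ValueError("n_epochs_per_class and n_channels must be >= 1")
        if self.sinusoids_per_band < 1:
            raise ValueError("sinusoids_per_band must be >= 1")
        if self.channel_gain_jitter < 0 or self.pink_noise_level < 0:
            raise ValueError("noise/jitter levels must be non-negative")
        for weights in (self.band_weights_class1, self.band_weights_class2):
            unknown = set(weights) - BAND_SET
            if unknown:
                raise ValueError(f"unknown sub-band labels: {sorted(unknown)}")
            if any(w < 0 for w in weights.values()):
                raise ValueError("band weights must be non-negative")

    def weights_for(self, label: int) -> dict[str, float]:
        if label == 1:
            return self.band_weights_class1
        if label == 2:
            return self.band_weights_class2
        raise ValueError(f"label must be 1 or 2, got {label!r}")


@dataclass
class Epoch:
    """One fixed-length multichannel segment: channels x time, with a label."""

    samples: np.ndarray
    fs: float
    label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")
        if self.label not in (1, 2):
            raise ValueError(f"label must be 1 or 2, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """An ordered, labelled collection of same-shape epochs."""

    epochs: list[Epoch]
    channel_names: list[str]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("EpochSet must contain at least one epoch")
        e0 = self.epochs[0]
        for e in self.epochs:
            if e.samples.shape != e0.samples.shape or e.fs != e0.fs:
                raise ValueError("all epochs must share fs and shape")
        if len(self.channel_names) != e0.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def n_channels(self) -> int:
        return self.epochs[0].n_channels

    @property
    def epoch_len(self) -> int:
        return self.epochs[0].n_samples

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs], dtype=int)

    @property
    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _band_edges(fs: float) -> dict[str, tuple[float, float]]:
    return {label: (lo, hi) for label, lo, hi, _ in subband_ranges(fs, 5)}


def _band_process(
    lo: float, hi: float, k: int, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    margin = _EDGE_MARGIN * (hi - lo)
    freqs = rng.uniform(lo + margin, hi - margin, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    sig = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(
        axis=0
    )
    sd = sig.std()
    if sd == 0.0:  # pathological draw; cannot normalize
        return sig
    return sig / sd


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise: shape a white spectrum by 1/sqrt(f), DC zeroed."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    sig = np.fft.irfft(spec * scale, n)
    return sig / sig.std()


def generate_epoch(
    config: SynthConfig, label: int, stream: np.random.Generator
) -> Epoch:
    """Generate one epoch of the given class from a seeded random stream."""
    weights = config.weights_for(label)
    edges = _band_edges(config.fs)
    t = np.arange(config.epoch_len) / config.fs
    samples = np.zeros((config.n_channels, config.epoch_len))
    for ch in range(config.n_channels):
        sig = np.zeros(config.epoch_len)
        for band in band_labels(5):  # fixed order: A5, D5..D1
            w = weights.get(band, 0.0)
            if w == 0.0:
                continue
            lo, hi = edges[band]
            sig += w * _band_process(
                lo, hi, config.sinusoids_per_band, t, stream
            )
        if config.pink_noise_level > 0.0:
            sig = sig + config.pink_noise_level * _pink_noise(
                config.epoch_len, stream
            )
        gain = 1.0
        if config.channel_gain_jitter > 0.0:
            gain = stream.uniform(
                1.0 - config.channel_gain_jitter, 1.0 + config.channel_gain_jitter
            )
        samples[ch] = gain * sig
    return Epoch(samples=samples, fs=config.fs, label=label)


def _epoch_stream(config: SynthConfig, label: int, index: int) -> np.random.Generator:
    # substream keyed by (seed, label, index): insertion order cannot change
    # any epoch's content
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, label, index))
    )


def generate_dataset(config: SynthConfig) -> EpochSet:
    """Generate the full two-class EpochSet, class-interleaved.

    Epoch ``2*i`` is the ``i``-th class-1 epoch and ``2*i + 1`` the ``i``-th
    class-2 epoch.  Every epoch is generated from its own substream of the
    master seed, so the set is reproducible element-wise.
    """
    epochs: list[Epoch] = []
    for i in range(config.n_epochs_per_class):
        for label in (1, 2):
            epochs.append(generate_epoch(config, label, _epoch_stream(config, label, i)))
    names = [f"ch{c + 1}" for c in range(config.n_channels)]
    return EpochSet(epochs=epochs, channel_names=names)


def expected_relative_energy(config: SynthConfig, label: int) -> dict[str, float]:
    """Analytic expected relative energy per band, ignoring pink noise.

    Band processes have unit variance, so a band's expected energy share is
    ``w**2 / sum(w**2)``.  Only valid as stated when ``pink_noise_level`` is
    0; with pink noise the true shares shift toward low frequencies.
    """
    weights = config.weights_for(label)
    total = sum(w**2 for w in weights.values())
    if total == 0.0:
        raise ValueError("all band weights are zero: relative energy undefined")
    return {band: weights.get(band, 0.0) ** 2 / total for band in band_labels(5)}
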