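"""Synthetic stimulus-locked EEG with a controllable P300-like deflection.

The generator emulates parietal oddball recordings: each epoch is 1/f
("pink") background noise, and target-class epochs additionally carry a
positive Gaussian-shaped deflection whose latency is drawn per epoch around
300-500 ms post-stimulus.  A fixed parietal weight vector (1.0 on the
Pz-like channel, 0.6 on its neighbours) spreads the component across
channels.  Everything is reproducible from a single root seed, and epoch i
is invariant to the total number of epochs requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochedEEG

__all__ = ["ClassSpec", "SynthConfig", "pink_noise", "generate_oddball",
           "parietal_weights", "erp_template"]

_PARIETAL_NAMES = ["Pz", "P3", "P4", "PO7", "PO8"]


@dataclass(frozen=True)
class ClassSpec:
    """One stimulus class: label, epoch count, and ERP shape parameters (µV/ms)."""

    label: int
    n_epochs: int
    erp_amplitude: float = 0.0     # µV; 0 disables the component
    erp_latency_mean: float = 400.0  # ms post-stimulus
    erp_latency_sd: float = 30.0     # ms
    erp_width: float = 80.0          # ms, Gaussian sigma


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 256.0
    epoch_ms: float = 1000.0
    n_channels: int = 5
    class_spec: tuple[ClassSpec, ...] = (
        ClassSpec(label=0, n_epochs=200, erp_amplitude=0.0),
        ClassSpec(label=1, n_epochs=200, erp_amplitude=5.0),
    )
    noise_sd: float = 2.5          # µV, background scale
    pink_exponent: float = 1.0     # power ~ 1/f^alpha
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.epoch_ms <= 0:
            raise ValueError("fs and epoch_ms must be positive")
        for cs in self.class_spec:
            if cs.n_epochs < 1:
                raise ValueError("every class needs n_epochs >= 1")
            if cs.erp_width <= 0:
                raise ValueError("erp_width must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_ms / 1000.0))


def parietal_weights(n_channels: int) -> np.ndarray:
    """Fixed topography: 1.0 on the Pz-like channel, 0.6 elsewhere."""
    w = np.full(n_channels, 0.6)
    w[0] = 1.0
    return w


def pink_noise(n_samples: int, exponent: float,
               seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean noise with amplitude spectrum shaped by 1/f^(exponent/2).

    White Gaussian noise is shaped in the frequency domain; the DC bin is
    zeroed so the series is exactly zero-mean, and the result is rescaled
    to unit standard deviation.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = spec * shape
    series = np.fft.irfft(spec, n=n_samples)
    sd = series.std()
    if sd > 0:
        series = series / sd
    return series


def erp_template(times_ms: np.ndarray, amplitude: float, latency_ms: float,
                 width_ms: float) -> np.ndarray:
    """Gaussian bump used as the ground-truth ERP shape."""
    return amplitude * np.exp(-0.5 * ((times_ms - latency_ms) / width_ms) ** 2)


def generate_oddball(config: SynthConfig) -> EpochedEEG:
    """Draw stimulus-locked epochs per the class specification.

    Each epoch uses an independent RNG stream keyed by (root seed, class
    index, epoch index), so regenerating with more epochs leaves earlier
    epochs bit-identical.
    """
    n = config.n_samples
    times = 1000.0 * np.arange(n) / config.fs  # time0 = 0, ms
    weights = parietal_weights(config.n_channels)

    chunks, labels = [], []
    for ci, cs in enumerate(config.class_spec):
        block = np.empty((cs.n_epochs, config.n_channels, n), dtype=np.float64)
        for ei in range(cs.n_epochs):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, ci, ei)))
            for ch in range(config.n_channels):
                block[ei, ch] = config.noise_sd * pink_noise(
                    n, config.pink_exponent, rng)
            if cs.erp_amplitude != 0.0:
                latency = rng.normal(cs.erp_latency_mean, cs.erp_latency_sd)
                lo, hi = times[0], times[-1]
                if latency < lo or latency > hi:
                    warnings.warn(
                        f"ERP latency {latency:.1f} ms outside epoch window "
                        f"[{lo:.0f}, {hi:.0f}] ms; clamped", stacklevel=2)
                    latency = min(max(latency, lo), hi)
                bump = erp_template(times, cs.erp_amplitude, latency, cs.erp_width)
                block[ei] += weights[:, None] * bump[None, :]
        chunks.append(block)
        labels.append(np.full(cs.n_epochs, cs.label, dtype=np.int32))

    names = (_PARIETAL_NAMES[:config.n_channels]
             if config.n_channels <= len(_PARIETAL_NAMES)
             else _PARIETAL_NAMES + [f"P{i}" for i in
                                     range(5, config.n_channels)])
    return EpochedEEG(
        data=np.concatenate(chunks, axis=0),
        labels=np.concatenate(labels),
        fs=config.fs,
        channel_names=names,
        time0_ms=0.0,
    )
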