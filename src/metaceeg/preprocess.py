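"""Preprocessing for epoched EEG: FIR band-limiting, MaxAbs scaling,
channel selection, and ERP averaging.

The nominal band is 0.01-40 Hz.  On ~1 s epochs a 0.01 Hz FIR high-pass is
longer than the epoch itself, so whenever the low edge spans less than one
cycle per epoch the high-pass is realized as per-epoch mean removal followed
by the FIR low-pass.  Filtering is zero-phase (forward-backward), which
preserves ERP latencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochedEEG

__all__ = ["FilterSpec", "bandpass_fir", "maxabs_scale", "select_channels",
           "erp_average"]


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 0.01
    high_hz: float = 40.0
    fir_order: int | None = None   # taps; None -> 129 scaled with fs/256
    window: str = "hamming"

    def taps(self, fs: float) -> int:
        if self.fir_order is not None:
            n = self.fir_order
        else:
            n = int(round(129 * fs / 256.0))
        if n % 2 == 0:
            n += 1
        if n < 3:
            raise ValueError("fir_order must be >= 3")
        return n


def bandpass_fir(epochs: EpochedEEG, spec: FilterSpec = FilterSpec()) -> EpochedEEG:
    """Zero-phase FIR band-pass of every channel of every epoch."""
    fs = epochs.fs
    if not (0 <= spec.low_hz < spec.high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if spec.high_hz >= fs / 2:
        raise ValueError(f"high edge {spec.high_hz} Hz >= Nyquist {fs / 2} Hz")
    ntaps = spec.taps(fs)
    if epochs.n_samples <= ntaps:
        raise ValueError("epoch length must exceed the FIR order")

    epoch_s = epochs.n_samples / fs
    data = epochs.data.astype(np.float64)
    if spec.low_hz * epoch_s < 1.0:
        # low edge below one cycle per epoch: mean removal + low-pass
        data = data - data.mean(axis=-1, keepdims=True)
        taps = signal.firwin(ntaps, spec.high_hz, window=spec.window, fs=fs)
    else:
        taps = signal.firwin(ntaps, [spec.low_hz, spec.high_hz],
                             window=spec.window, pass_zero=False, fs=fs)
    padlen = min(epochs.n_samples - 1, 3 * ntaps)
    out = signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)
    return epochs.with_data(out)


def maxabs_scale(epochs: EpochedEEG) -> EpochedEEG:
    """Divide each channel of each epoch by its peak absolute value.

    All-zero traces are left untouched.  Keeps every trace in [-1, 1] as the
    tanh-headed generators require.
    """
    peak = np.abs(epochs.data).max(axis=-1, keepdims=True)
    peak = np.where(peak == 0, 1.0, peak)
    return epochs.with_data(epochs.data / peak)


def select_channels(epochs: EpochedEEG, names: list[str]) -> EpochedEEG:
    """Channel subset in the requested order."""
    missing = [n for n in names if n not in epochs.channel_names]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {epochs.channel_names}")
    idx = [epochs.channel_names.index(n) for n in names]
    return EpochedEEG(epochs.data[:, idx, :], epochs.labels, fs=epochs.fs,
                      channel_names=list(names), time0_ms=epochs.time0_ms)


def erp_average(epochs: EpochedEEG, label: int,
                normalize: bool = True) -> np.ndarray:
    """Per-channel mean over all epochs of one label.

    With ``normalize`` (default) each channel is min-max scaled to [0, 1];
    a flat channel maps to zeros.  Returns [n_channels, n_samples].
    """
    mask = epochs.labels == label
    if not mask.any():
        raise ValueError(f"no epochs with label {label}")
    avg = epochs.data[mask].mean(axis=0)
    if not normalize:
        return avg
    lo = avg.min(axis=-1, keepdims=True)
    hi = avg.max(axis=-1, keepdims=True)
    rng = hi - lo
    flat = rng.squeeze(-1) == 0
    rng = np.where(rng == 0, 1.0, rng)
    out = (avg - lo) / rng
    out[flat] = 0.0
    return out
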