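"""Epoched EEG container and its HDF5 round-trip.

Layout: datasets ``/data`` (float32, [n_epochs, n_channels, n_samples]) and
``/labels`` (int32); root attributes ``fs``, ``time0_ms``, ``channel_names``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["EpochedEEG", "FormatError", "read_epochs", "write_epochs"]


class FormatError(ValueError):
    """The epochs container is missing a required dataset or attribute."""


@dataclass
class EpochedEEG:
    """Stimulus-locked EEG epochs: [n_epochs, n_channels, n_samples] + labels.

    `fs` is the sampling rate in Hz and `time0_ms` the epoch start relative
    to the stimulus (0 = stimulus onset).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    time0_ms: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_epochs, n_channels, n_samples]")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal n_epochs")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.time0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray) -> "EpochedEEG":
        return replace(self, data=np.asarray(data))

    def subset(self, idx) -> "EpochedEEG":
        return replace(self, data=self.data[idx], labels=self.labels[idx])


def write_epochs(epochs: EpochedEEG, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int32))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["time0_ms"] = float(epochs.time0_ms)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]


def read_epochs(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        for ds in ("data", "labels"):
            if ds not in f:
                raise FormatError(f"missing required dataset '/{ds}'")
        for at in ("fs", "time0_ms", "channel_names"):
            if at not in f.attrs:
                raise FormatError(f"missing required root attribute '{at}'")
        names = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in f.attrs["channel_names"]]
        return EpochedEEG(
            data=f["data"][...].astype(np.float32),
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            channel_names=names,
            time0_ms=float(f.attrs["time0_ms"]),
        )
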