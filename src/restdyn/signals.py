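"""Time-series containers: epoched signals, sensor recordings, leadfields."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EpochedSignal", "SensorRecording", "Leadfield"]


@dataclass(frozen=True)
class EpochedSignal:
    """Epochs x samples array with its sampling rate (Hz).

    Carrier of all source-space (virtual channel) measures: power spectra,
    relative band power and multiscale entropy are computed per epoch and
    averaged across epochs.
    """

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if data.ndim != 2:
            raise ValueError("epoched data must be 2-D (epochs x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SensorRecording:
    """Epoched multichannel sensor data: (epochs, channels, samples)."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:  # single continuous segment -> one epoch
            data = data[None, :, :]
        if data.ndim != 3:
            raise ValueError(
                "sensor data must be (epochs, channels, samples) or (channels, samples)"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def concatenated(self) -> np.ndarray:
        """Channels x (epochs*samples) view of all epochs joined in time."""
        return np.concatenate(list(self.data), axis=1)


@dataclass(frozen=True)
class Leadfield:
    """Forward-model gains: (voxels, channels, 3 dipole orientations)."""

    gains: np.ndarray

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        if gains.ndim != 3 or gains.shape[2] != 3:
            raise ValueError("leadfield must have shape (voxels, channels, 3)")
        if not np.isfinite(gains).all():
            raise ValueError("leadfield entries must be finite")
        # every voxel must be visible to the array through some orientation
        if (np.abs(gains).sum(axis=(1, 2)) == 0).any():
            raise ValueError("leadfield has a voxel with all-zero gains")
        object.__setattr__(self, "gains", gains)

    @property
    def n_voxels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]
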