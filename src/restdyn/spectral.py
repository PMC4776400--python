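"""Welch power spectra and relative band power of virtual-channel signals.

Relative power of a band is its integrated power divided by the total
power over the full analysis band (0-80 Hz).  Basing group comparisons on
relative rather than absolute power makes the analysis a function of
spectral *shape*, which is robust to the SNR normalization of beamformer
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .signals import EpochedSignal

__all__ = [
    "SpectralParams",
    "BandScheme",
    "PowerSpectrum",
    "welch_psd",
    "epoch_psd",
    "relative_band_power",
]


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimator settings: 500 ms Hamming windows, 50% overlap,
    analysis band 0-80 Hz.  ``include_dc`` controls whether the 0 Hz bin
    enters the total-power denominator."""

    window_len_s: float = 0.5
    overlap: float = 0.5
    taper: str = "hamming"
    total_band: tuple[float, float] = (0.0, 80.0)
    include_dc: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.window_len_s <= 0:
            raise ValueError("window length must be positive")

    def nperseg(self, fs: float) -> int:
        return int(np.floor(self.window_len_s * fs))


# Canonical band edges, half-open [low, high) on bin centers.  The gaps
# 7-8 Hz and 12-15 Hz are intentional, so the four-band sum is <= 1.
DEFAULT_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
}


@dataclass(frozen=True)
class BandScheme:
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r} has low >= high")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided PSD (power density per Hz) on frequency bins 0..fs/2."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.shape != self.power.shape[-1:]:
            raise ValueError("frequency axis does not match power array")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    epoch: np.ndarray, fs: float, params: SpectralParams = SpectralParams()
) -> PowerSpectrum:
    """Welch PSD of one epoch: mean of Hamming-tapered, 50%-overlapped
    periodograms.  FFT length equals the window length (no zero padding);
    sum(PSD) * df approximates the signal variance (Parseval)."""
    epoch = np.asarray(epoch, dtype=float)
    nperseg = params.nperseg(fs)
    if epoch.shape[-1] < nperseg:
        raise ValueError(
            f"epoch of {epoch.shape[-1]} samples shorter than the "
            f"{nperseg}-sample analysis window"
        )
    freqs, power = sps.welch(
        epoch,
        fs=fs,
        window=params.taper,
        nperseg=nperseg,
        noverlap=int(nperseg * params.overlap),
        nfft=nperseg,
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(freqs=freqs, power=power)


def epoch_psd(signal: EpochedSignal, params: SpectralParams = SpectralParams()) -> PowerSpectrum:
    """Welch PSD per epoch, averaged across epochs."""
    spec = welch_psd(signal.data, signal.fs, params)
    return PowerSpectrum(freqs=spec.freqs, power=spec.power.mean(axis=0))


def _band_bins(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


def relative_band_power(
    spectrum: PowerSpectrum,
    band: str | tuple[float, float],
    scheme: BandScheme = BandScheme(),
    params: SpectralParams = SpectralParams(),
) -> float:
    """Integrated band power divided by total power over the analysis band.

    Band membership is decided on bin centers with half-open [low, high)
    edges; the total band is closed, [0, 80] Hz, with the DC bin included
    unless ``params.include_dc`` is false.  Result lies in [0, 1].
    """
    if isinstance(band, str):
        lo, hi = scheme.bands[band]
    else:
        lo, hi = band
    freqs = spectrum.freqs
    band_sel = _band_bins(freqs, lo, hi)
    # closed upper edge so a bin exactly at 80 Hz (or hi == total high) counts
    if hi >= params.total_band[1]:
        band_sel |= np.isclose(freqs, hi) & (freqs <= params.total_band[1])
    t_lo, t_hi = params.total_band
    total_sel = (freqs >= t_lo) & (freqs <= t_hi)
    if not params.include_dc:
        total_sel &= freqs > 0
        band_sel &= freqs > 0
    if not band_sel.any():
        raise ValueError(
            f"band [{lo}, {hi}) contains no frequency bin at resolution "
            f"{spectrum.df:.3g} Hz; use longer windows"
        )
    total = spectrum.power[total_sel].sum()
    if total == 0:
        return float("nan")
    return float(spectrum.power[band_sel & total_sel].sum() / total)
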