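"""Per-voxel MEG measure maps and ROI-averaged spectra / MSE curves.

Six whole-brain maps are produced per subject from the virtual-channel
signals: relative delta, theta, alpha and beta power, and the MSE means
over the short (1-5) and long (7-20) scale ranges.  ROI summaries average
the per-voxel quantities over the voxels of a mask; spectra entering ROI
curves are normalized to unit total power over the analysis band, so they
describe spectral shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import (
    LONG_SCALES,
    SHORT_SCALES,
    EntropyParams,
    MSECurve,
    mse_curve,
    scale_band_summary,
)
from .geometry import BinaryMask, VolumeMap
from .signals import EpochedSignal
from .spectral import BandScheme, SpectralParams, epoch_psd, relative_band_power
from .synthetic import SubjectRecord

__all__ = [
    "MEGMeasureParams",
    "VoxelMeasures",
    "voxel_measures",
    "meg_maps",
    "roi_measures",
    "MAP_NAMES",
]

MAP_NAMES = ("delta", "theta", "alpha", "beta", "mse_short", "mse_long")


@dataclass(frozen=True)
class MEGMeasureParams:
    spectral: SpectralParams = field(default_factory=SpectralParams)
    bands: BandScheme = field(default_factory=BandScheme)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    short_scales: tuple[int, int] = SHORT_SCALES
    long_scales: tuple[int, int] = LONG_SCALES


@dataclass(frozen=True)
class VoxelMeasures:
    """All measures of one virtual channel."""

    band_power: dict[str, float]
    mse_short: float
    mse_long: float
    psd_shape: np.ndarray  # PSD normalized to unit total-band power
    freqs: np.ndarray
    mse: MSECurve


def voxel_measures(
    signal: EpochedSignal, params: MEGMeasureParams = MEGMeasureParams()
) -> VoxelMeasures:
    spec = epoch_psd(signal, params.spectral)
    bands = {
        name: relative_band_power(spec, name, params.bands, params.spectral)
        for name in params.bands.names
    }
    t_lo, t_hi = params.spectral.total_band
    total_sel = (spec.freqs >= t_lo) & (spec.freqs <= t_hi)
    total = spec.power[total_sel].sum()
    shape = spec.power / total if total > 0 else np.full_like(spec.power, np.nan)
    curve = mse_curve(signal, params.entropy)
    return VoxelMeasures(
        band_power=bands,
        mse_short=scale_band_summary(curve, params.short_scales),
        mse_long=scale_band_summary(curve, params.long_scales),
        psd_shape=shape,
        freqs=spec.freqs,
        mse=curve,
    )


def meg_maps(
    subject: SubjectRecord,
    mask: BinaryMask = None,
    params: MEGMeasureParams = MEGMeasureParams(),
) -> dict[str, VolumeMap]:
    """The six measure maps of one subject, NaN outside the mask
    (default: the subject's gray matter excluding the lesion)."""
    geom = subject.geometry
    if mask is None:
        mask = subject.gm_mask - subject.lesion_mask
    if mask.geometry != geom:
        raise ValueError("mask geometry does not match the subject")
    flats = np.flatnonzero(mask.data.reshape(-1))
    out = {name: np.full(geom.n_voxels, np.nan) for name in MAP_NAMES}
    for v in flats:
        m = voxel_measures(subject.meg_signal(int(v)), params)
        for name in ("delta", "theta", "alpha", "beta"):
            out[name][v] = m.band_power[name]
        out["mse_short"][v] = m.mse_short
        out["mse_long"][v] = m.mse_long
    return {
        name: VolumeMap(arr.reshape(geom.shape), geom)
        for name, arr in out.items()
    }


def roi_measures(
    subject: SubjectRecord,
    roi: BinaryMask,
    params: MEGMeasureParams = MEGMeasureParams(),
) -> dict:
    """Voxel-mean measures over an ROI for one subject.

    Returns the scalar ROI means of the six measures plus the ROI-mean
    normalized spectrum and MSE curve (for group curve tables).  Raises on
    an empty ROI — callers exclude such subjects explicitly.
    """
    flats = np.flatnonzero(roi.data.reshape(-1))
    if flats.size == 0:
        raise ValueError("empty ROI")
    per_voxel = [voxel_measures(subject.meg_signal(int(v)), params) for v in flats]
    out: dict = {
        name: float(np.nanmean([m.band_power[name] for m in per_voxel]))
        for name in ("delta", "theta", "alpha", "beta")
    }
    out["mse_short"] = float(np.nanmean([m.mse_short for m in per_voxel]))
    out["mse_long"] = float(np.nanmean([m.mse_long for m in per_voxel]))
    out["freqs"] = per_voxel[0].freqs
    out["spectrum"] = np.nanmean([m.psd_shape for m in per_voxel], axis=0)
    out["scales"] = per_voxel[0].mse.scales
    out["mse_curve"] = np.nanmean([m.mse.values for m in per_voxel], axis=0)
    out["n_voxels"] = int(flats.size)
    return out
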