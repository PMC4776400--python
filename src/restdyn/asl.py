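"""Pulsed-ASL perfusion: surround subtraction and one-compartment CBF
quantification.

Tag/control frames alternate; surround subtraction differences each frame
against the average of its temporally adjacent opposite-condition frames,
which cancels any signal component linear in frame index (BOLD drift).
The mean perfusion-weighted signal is converted to cerebral blood flow in
ml/100g/min with the one-compartment kinetic model for a QUIPSS-II style
pulsed sequence:

    f = 6e6 * lambda * dM / (2 * alpha * M0 * TI1 * exp(-TI2 / T1_blood))

with TI in ms; the constant 6e6 converts ml/g/ms to ml/100g/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bold import smooth_volume
from .geometry import VolumeGeometry, VolumeMap

__all__ = [
    "ASLParams",
    "ASLSeries",
    "surround_subtract",
    "quantify_cbf",
    "perfusion_signal",
    "cbf_map",
]


@dataclass(frozen=True)
class ASLParams:
    """Sequence timing and kinetic-model constants.

    TI values (ms) follow the acquisition (TI1 700, TIs 1600, TI2 1800);
    lambda (blood-tissue partition, ml/g), alpha (labeling efficiency) and
    T1 of arterial blood (ms) are standard 3 T gray-matter values.
    """

    ti1_ms: float = 700.0
    tis_ms: float = 1600.0
    ti2_ms: float = 1800.0
    partition_ml_g: float = 0.9
    labeling_efficiency: float = 0.95
    t1_blood_ms: float = 1650.0

    def __post_init__(self) -> None:
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if not self.ti1_ms < self.ti2_ms:
            raise ValueError("TI1 must precede TI2")
        if min(self.ti1_ms, self.ti2_ms, self.partition_ml_g, self.t1_blood_ms) <= 0:
            raise ValueError("all kinetic parameters must be positive")


@dataclass(frozen=True)
class ASLSeries:
    """Interleaved tag/control frame series: (nx, ny, nz, frames).

    ``first_label`` says whether frame 0 is a tag or a control; labels
    strictly alternate and the frame count is even (here 150 = 75 + 75).
    ``m0`` is the equilibrium-magnetization map from a separate scan.
    """

    data: np.ndarray
    geometry: VolumeGeometry
    m0: VolumeMap
    tr_s: float = 3.0
    first_label: str = "tag"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[:3] != tuple(self.geometry.shape):
            raise ValueError("ASL data must be (nx, ny, nz, frames) on its geometry")
        if data.shape[3] % 2:
            raise ValueError("frame count must be even (tag/control pairs)")
        if self.first_label not in ("tag", "control"):
            raise ValueError("first_label must be 'tag' or 'control'")
        if self.m0.geometry != self.geometry:
            raise ValueError("M0 map must share the series geometry")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def is_control(self) -> np.ndarray:
        """Boolean per frame, True where the frame is a control frame."""
        start = self.first_label == "control"
        return (np.arange(self.n_frames) % 2 == 0) == start


def surround_subtract(series: ASLSeries) -> np.ndarray:
    """Perfusion-weighted series, one frame per tag/control pair.

    For each frame the opposite condition is interpolated from the
    neighboring frames (single neighbor at the boundaries), signed so that
    control-minus-tag is positive for a perfused voxel; the two per-frame
    differences of each original pair are then averaged, giving
    frames/2 difference images.
    """
    x = series.data
    n = series.n_frames
    if n < 3:
        raise ValueError("surround subtraction needs at least 3 frames")
    ctrl = series.is_control()
    if np.any(ctrl[1:] == ctrl[:-1]):
        raise ValueError("tag/control labels must strictly alternate")
    neighbor = np.empty_like(x)
    neighbor[..., 1:-1] = 0.5 * (x[..., :-2] + x[..., 2:])
    neighbor[..., 0] = x[..., 1]
    neighbor[..., -1] = x[..., -2]
    sign = np.where(ctrl, 1.0, -1.0)
    dm = sign * (x - neighbor)
    return 0.5 * (dm[..., 0::2] + dm[..., 1::2])


def quantify_cbf(
    dm_mean: np.ndarray | float,
    m0: np.ndarray | float,
    params: ASLParams = ASLParams(),
) -> np.ndarray | float:
    """One-compartment CBF (ml/100g/min) from the mean perfusion-weighted
    signal; linear in dM, voxels with M0 <= 0 are flagged NaN."""
    dm_mean = np.asarray(dm_mean, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    bad = m0 <= 0
    if np.any(bad):
        warnings.warn("voxels with M0 <= 0 flagged NaN in CBF quantification")
    denom = (
        2.0
        * params.labeling_efficiency
        * np.where(bad, np.nan, m0)
        * params.ti1_ms
        * np.exp(-params.ti2_ms / params.t1_blood_ms)
    )
    f = 6.0e6 * params.partition_ml_g * dm_mean / denom
    return float(f) if f.ndim == 0 else f


def perfusion_signal(
    cbf: np.ndarray | float, m0: np.ndarray | float, params: ASLParams = ASLParams()
) -> np.ndarray | float:
    """Forward model: the mean control-tag difference produced by a given
    CBF — the exact inverse of :func:`quantify_cbf`."""
    cbf = np.asarray(cbf, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    dm = (
        cbf
        * 2.0
        * params.labeling_efficiency
        * m0
        * params.ti1_ms
        * np.exp(-params.ti2_ms / params.t1_blood_ms)
        / (6.0e6 * params.partition_ml_g)
    )
    return float(dm) if dm.ndim == 0 else dm


def cbf_map(
    series: ASLSeries,
    params: ASLParams = ASLParams(),
    fwhm_mm: float = 6.0,
) -> VolumeMap:
    """Smooth -> surround subtraction -> average over frames -> quantify."""
    geom = series.geometry
    smoothed = ASLSeries(
        data=smooth_volume(series.data, geom, fwhm_mm),
        geometry=geom,
        m0=VolumeMap(smooth_volume(series.m0.data, geom, fwhm_mm), geom),
        tr_s=series.tr_s,
        first_label=series.first_label,
    )
    dm = surround_subtract(smoothed).mean(axis=-1)
    return VolumeMap(quantify_cbf(dm, smoothed.m0.data, params), geom)
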