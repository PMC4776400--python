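"""Scalar (SAM-style) beamformer: noise-normalized virtual channels.

For each voxel a single dipole orientation u is chosen to maximize source
power, the weight vector ``w = C^-1 l / (l^T C^-1 l)`` passes unit gain to
a dipole at the target voxel while minimizing power from everywhere else,
and the virtual signal is rendered in dimensionless SNR units

    s(t) = w^T x(t) / sqrt(sigma2_noise * w^T w),

with the noise power estimated as the lowest singular value of the sensor
covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import EpochedSignal, Leadfield, SensorRecording

__all__ = [
    "SensorCovariance",
    "BeamformerWeights",
    "preprocess_sensors",
    "sensor_covariance",
    "optimal_orientation",
    "sam_weights",
    "virtual_channel",
    "compute_weights",
]


@dataclass(frozen=True)
class SensorCovariance:
    """Epoch-concatenated sensor covariance with diagonal-loading info.

    ``sigma2_noise`` is the smallest singular value of the *unregularized*
    covariance; the regularized inverse uses
    ``(C + reg_fraction * mean(diag(C)) * I)^-1``.
    """

    matrix: np.ndarray
    reg_fraction: float
    sigma2_noise: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance must be symmetric")
        if self.sigma2_noise < 0:
            raise ValueError("noise power must be >= 0")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def inverse(self) -> np.ndarray:
        c = self.matrix
        if self.reg_fraction > 0:
            c = c + self.reg_fraction * np.mean(np.diag(c)) * np.eye(len(c))
        return np.linalg.inv(c)


@dataclass(frozen=True)
class BeamformerWeights:
    """Per-voxel sensor weights and chosen dipole orientations."""

    weights: np.ndarray      # (voxels, channels)
    orientations: np.ndarray  # (voxels, 3), unit norm

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        u = np.asarray(self.orientations, dtype=float)
        if w.ndim != 2 or u.shape != (w.shape[0], 3):
            raise ValueError("weights (voxels, channels) and orientations (voxels, 3)")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "orientations", u)


def preprocess_sensors(
    recording: SensorRecording, lowpass: float, decim: int
) -> SensorRecording:
    """Zero-phase FIR low-pass then keep every ``decim``-th sample.

    The filter is a Hamming-windowed FIR applied forward-backward
    (zero phase), with order ~ 3 fs / transition width.  The cutoff must
    sit below the post-decimation Nyquist frequency.
    """
    decim = int(decim)
    if decim < 1:
        raise ValueError("decim must be >= 1")
    new_fs = recording.fs / decim
    if lowpass >= new_fs / 2:
        raise ValueError(
            f"low-pass {lowpass} Hz is at or above the post-decimation "
            f"Nyquist frequency {new_fs / 2:.2f} Hz"
        )
    # transition band: narrow enough that the stopband starts below the
    # post-decimation Nyquist, wide enough to keep the filter order modest
    width = min(0.3 * lowpass, 2 * (new_fs / 2 - lowpass))
    numtaps = int(3 * recording.fs / width)
    numtaps += 1 - numtaps % 2  # odd order for a type-I linear-phase FIR
    taps = sps.firwin(numtaps, lowpass, width=width, fs=recording.fs)
    filtered = sps.filtfilt(taps, [1.0], recording.data, axis=-1)
    return SensorRecording(data=filtered[..., ::decim], fs=new_fs)


def sensor_covariance(
    recording: SensorRecording, reg_fraction: float = 0.01
) -> SensorCovariance:
    """Sample covariance over all epochs concatenated in time."""
    if reg_fraction < 0:
        raise ValueError("reg_fraction must be >= 0")
    x = recording.concatenated()
    n_ch, n_t = x.shape
    if n_t < n_ch + 1:
        raise ValueError(
            f"need at least channels+1 = {n_ch + 1} samples, got {n_t}"
        )
    c = np.cov(x, ddof=1)
    c = np.atleast_2d(c)
    sv = np.linalg.svd(c, compute_uv=False)
    sigma2 = float(sv[-1])
    if reg_fraction == 0 and sigma2 < 1e-12 * sv[0]:
        raise ValueError(
            "sensor covariance is rank deficient; supply reg_fraction > 0 "
            "(diagonal loading) or record more data"
        )
    return SensorCovariance(matrix=c, reg_fraction=reg_fraction, sigma2_noise=sigma2)


def optimal_orientation(L: np.ndarray, cov: SensorCovariance) -> np.ndarray:
    """Orientation maximizing beamformer output power 1 / (u^T L^T C^-1 L u).

    Solved in closed form as the eigenvector of ``L^T C^-1 L`` with the
    smallest eigenvalue; the sign is fixed so the largest-magnitude
    component is positive.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("leadfield block must be (channels, 3)")
    if not np.abs(L).sum() > 0:
        raise ValueError("leadfield block is all zero")
    cinv = cov.inverse()
    q = L.T @ cinv @ L
    vals, vecs = np.linalg.eigh(q)
    # a (near-)zero eigenvalue marks a direction the sensors cannot see
    # (rank-deficient leadfield); it carries no signal, so restrict the
    # optimum to directions with a nonzero response
    feasible = vals > 1e-12 * vals[-1]
    if not feasible.any():
        raise ValueError("leadfield has no direction visible to the sensors")
    vals, vecs = vals[feasible], vecs[:, feasible]
    if vals.size > 1 and np.isclose(vals[0], vals[1], rtol=1e-9, atol=0):
        warnings.warn(
            "degenerate orientation (tied smallest eigenvalues); "
            "picking deterministically by axis order"
        )
    u = vecs[:, 0]
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u = -u
    return u / np.linalg.norm(u)


def sam_weights(l: np.ndarray, cov: SensorCovariance) -> np.ndarray:
    """Unit-gain minimum-variance weights ``w = C^-1 l / (l^T C^-1 l)``."""
    l = np.asarray(l, dtype=float)
    if not np.abs(l).sum() > 0:
        raise ValueError("oriented leadfield is all zero")
    cinv_l = cov.inverse() @ l
    return cinv_l / (l @ cinv_l)


def virtual_channel(
    w: np.ndarray, sigma2_noise: float, recording: SensorRecording
) -> EpochedSignal:
    """Render a voxel's virtual signal in dimensionless SNR units,
    preserving the epoch structure of the input."""
    w = np.asarray(w, dtype=float)
    if w.shape != (recording.n_channels,):
        raise ValueError("weight vector does not match recording channels")
    if sigma2_noise <= 0:
        raise ValueError("degenerate noise estimate (sigma2_noise <= 0)")
    norm = np.sqrt(sigma2_noise * (w @ w))
    series = np.einsum("c,ecs->es", w, recording.data) / norm
    return EpochedSignal(data=series, fs=recording.fs)


def compute_weights(leadfield: Leadfield, cov: SensorCovariance) -> BeamformerWeights:
    """Orientation + weights for every voxel of a leadfield."""
    if leadfield.n_channels != cov.n_channels:
        raise ValueError("leadfield and covariance channel counts differ")
    n_vox = leadfield.n_voxels
    weights = np.empty((n_vox, leadfield.n_channels))
    orients = np.empty((n_vox, 3))
    for v in range(n_vox):
        L = leadfield.gains[v]
        u = optimal_orientation(L, cov)
        orients[v] = u
        weights[v] = sam_weights(L @ u, cov)
    return BeamformerWeights(weights=weights, orientations=orients)
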