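"""BOLD preprocessing and the three variability/complexity measures.

The preprocessing contract is fixed: spatial Gaussian smoothing, nuisance
regression (motion parameters plus mean white-matter and CSF series, with
the voxel temporal mean added back), then grand-mean scaling so that the
4D mean over in-brain voxels is 100.  On the residual-plus-mean series we
compute SD_BOLD (temporal standard deviation), MSSD (mean squared
successive difference, insensitive to slow trends) and SampEn_BOLD (sample
entropy at a single scale, the TR).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .entropy import sample_entropy
from .geometry import BinaryMask, VolumeGeometry, VolumeMap

__all__ = [
    "BoldTimeseries",
    "smooth_volume",
    "nuisance_regress",
    "grand_mean_scale",
    "preprocess_bold",
    "sd_bold",
    "mssd",
    "sampen_bold",
    "variability_maps",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class BoldTimeseries:
    """4D BOLD run: (nx, ny, nz, T) values on a grid, TR-sampled.

    ``nuisance`` holds the confound regressors (T x k: motion parameters
    and mean WM/CSF series, extracted from unsmoothed data by convention);
    ``brain_mask`` defines the in-brain voxels for grand-mean scaling.
    """

    data: np.ndarray
    geometry: VolumeGeometry
    tr: float
    nuisance: np.ndarray = None  # type: ignore[assignment]
    brain_mask: BinaryMask = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[:3] != tuple(self.geometry.shape):
            raise ValueError("BOLD data must be (nx, ny, nz, T) on its geometry")
        if data.shape[3] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        nuis = self.nuisance
        if nuis is None:
            nuis = np.empty((data.shape[3], 0))
        nuis = np.asarray(nuis, dtype=float)
        if nuis.shape[0] != data.shape[3]:
            raise ValueError("nuisance regressors must match the run length")
        mask = self.brain_mask
        if mask is None:
            mask = BinaryMask(np.ones(self.geometry.shape, dtype=bool), self.geometry)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "nuisance", nuis)
        object.__setattr__(self, "brain_mask", mask)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def smooth_volume(
    data: np.ndarray, geometry: VolumeGeometry, fwhm_mm: float
) -> np.ndarray:
    """3D Gaussian smoothing, sigma = FWHM / 2.3548 per axis in voxel
    units; applied per timepoint for 4D input.  FWHM 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigma = [fwhm_mm / FWHM_TO_SIGMA / v for v in geometry.voxel_size]
    if data.ndim == 4:
        sigma = sigma + [0.0]
    elif data.ndim != 3:
        raise ValueError("expected a 3D volume or 4D run")
    return ndimage.gaussian_filter(data, sigma=sigma)


def nuisance_regress(ts: BoldTimeseries) -> BoldTimeseries:
    """Regress the confounds out of every voxel series.

    Ordinary least squares with an intercept; the residuals are returned
    with each voxel's temporal mean added back, so the signal level (and
    grand-mean scaling downstream) is preserved.
    """
    t = ts.n_volumes
    x = np.column_stack([np.ones(t), ts.nuisance])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"nuisance design is rank deficient ({rank} < {x.shape[1]}); "
            "remove collinear regressors"
        )
    y = ts.data.reshape(-1, t).T  # T x voxels
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = (resid + y.mean(axis=0)).T.reshape(ts.data.shape)
    return replace(ts, data=out)


def grand_mean_scale(ts: BoldTimeseries, target: float = 100.0) -> BoldTimeseries:
    """One global multiplicative factor so the 4D in-brain mean equals
    ``target``.  Idempotent once applied; between-voxel SD ratios are
    unchanged."""
    mean = ts.data[ts.brain_mask.data].mean()
    if mean == 0:
        raise ValueError("in-brain 4D mean is zero; cannot grand-mean scale")
    return replace(ts, data=ts.data * (target / mean))


def preprocess_bold(
    ts: BoldTimeseries, fwhm_mm: float = 8.0, target: float = 100.0
) -> BoldTimeseries:
    """Fixed order: smooth -> nuisance regression -> grand-mean scaling."""
    smoothed = replace(ts, data=smooth_volume(ts.data, ts.geometry, fwhm_mm))
    return grand_mean_scale(nuisance_regress(smoothed), target=target)


def sd_bold(series: np.ndarray) -> np.ndarray | float:
    """Temporal standard deviation, N-1 denominator; last axis is time."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints")
    out = series.std(axis=-1, ddof=1)
    return float(out) if out.ndim == 0 else out


def mssd(series: np.ndarray) -> np.ndarray | float:
    """Mean squared successive difference: sum (x[i+1]-x[i])^2 / (N-1)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints")
    d = np.diff(series, axis=-1)
    out = (d * d).sum(axis=-1) / (series.shape[-1] - 1)
    return float(out) if out.ndim == 0 else out


def sampen_bold(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Single-scale sample entropy with tolerance r x SD of the series —
    the same kernel as the source-space MSE, restricted to scale 1."""
    series = np.asarray(series, dtype=float)
    sd = float(series.std(ddof=1))
    if sd == 0:
        return 0.0  # constant series: all templates match at both lengths
    return sample_entropy(series, m=m, r_abs=r * sd)


def variability_maps(ts: BoldTimeseries, m: int = 2, r: float = 0.2) -> dict[str, VolumeMap]:
    """SD_BOLD, MSSD_BOLD and SampEn_BOLD volume maps for one run."""
    import warnings as _warnings

    geom = ts.geometry
    flat = ts.data.reshape(-1, ts.n_volumes)
    sd_map = sd_bold(flat).reshape(geom.shape)
    mssd_map = mssd(flat).reshape(geom.shape)
    sampen = np.empty(flat.shape[0])
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for i in range(flat.shape[0]):
            sampen[i] = sampen_bold(flat[i], m=m, r=r)
    return {
        "sd": VolumeMap(sd_map, geom),
        "mssd": VolumeMap(mssd_map, geom),
        "sampen": VolumeMap(sampen.reshape(geom.shape), geom),
    }
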