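"""Sample entropy and multiscale entropy (MSE) of epoched signals.

Sample entropy SampEn(m, r) is the negative natural log of the conditional
probability that two sequences matching for m consecutive points (within a
Chebyshev tolerance r, self-matches excluded) still match at m+1 points.
MSE evaluates SampEn on coarse-grained (non-overlapping block-mean)
versions of the signal across scale factors tau; at sampling rate fs the
scale-tau series has time step tau/fs.

Conventions (fixed for bit-reproducibility):

* templates of length m and m+1 are both drawn from start indices
  0 .. N-m-1, the Richman-Moorman counting;
* the tolerance is r x SD of the *original* (scale-1) epoch, held fixed
  across scales (Costa convention), SD with N-1 denominator;
* an epoch/scale with zero template matches at either length is undefined
  (NaN) and excluded from cross-epoch averages rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .signals import EpochedSignal

__all__ = [
    "EntropyParams",
    "MSECurve",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "scale_band_summary",
]

SHORT_SCALES = (1, 5)
LONG_SCALES = (7, 20)


@dataclass(frozen=True)
class EntropyParams:
    """MSE parameters: template length m, tolerance fraction r (of the
    scale-1 epoch SD) and the coarse-graining scales."""

    m: int = 2
    r: float = 0.2
    scales: tuple[int, ...] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        scales = tuple(int(s) for s in self.scales)
        if any(s < 1 for s in scales):
            raise ValueError("scales must be >= 1")
        if list(scales) != sorted(set(scales)):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", scales)


@dataclass(frozen=True)
class MSECurve:
    """Entropy (nats) per coarse-graining scale, averaged across epochs.

    ``n_defined`` counts the epochs contributing at each scale; a scale
    where no epoch yielded a defined value is NaN.
    """

    scales: np.ndarray
    values: np.ndarray
    n_defined: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "n_defined", np.asarray(self.n_defined, dtype=int))
        if not np.all(np.diff(self.scales) > 0):
            raise ValueError("scale axis must be strictly increasing")

    def time_steps_ms(self) -> np.ndarray:
        """Per-scale time step tau/fs in milliseconds."""
        return self.scales / self.fs * 1000.0


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; output length
    floor(N / tau).  tau = 1 is the identity."""
    tau = int(tau)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1] // tau
    if n == 0:
        raise ValueError(f"series of length {series.shape[-1]} too short for tau={tau}")
    if tau == 1:
        return series.copy()
    return series[..., : n * tau].reshape(*series.shape[:-1], n, tau).mean(axis=-1)


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover
    """Matched template pairs at lengths m (B) and m+1 (A), i < j."""
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(series: np.ndarray, m: int = 2, r_abs: float = None) -> float:
    """SampEn(m, r_abs) in nats; ``r_abs`` is an absolute tolerance in the
    units of the series.  Returns NaN (with a warning) when no template
    pair matches at either length."""
    series = np.ascontiguousarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be a positive absolute tolerance")
    if series.size <= m + 1:
        raise ValueError(f"series length {series.size} too short for m={m}")
    a, b = _sampen_counts(series, int(m), float(r_abs))
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no matching templates)")
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(signal: EpochedSignal, params: EntropyParams = EntropyParams()) -> MSECurve:
    """Multiscale entropy of an epoched signal.

    Per epoch: the tolerance is fixed at ``params.r`` x SD of that epoch's
    original series, then SampEn is evaluated on each coarse-grained
    version; values are averaged across epochs per scale, ignoring
    undefined epochs.
    """
    max_tau = params.scales[-1]
    if signal.n_samples // max_tau <= params.m + 1:
        raise ValueError(
            f"epochs of {signal.n_samples} samples are too short for scale {max_tau}"
        )
    values = np.full((signal.n_epochs, len(params.scales)), np.nan)
    for e in range(signal.n_epochs):
        epoch = signal.data[e]
        sd = float(np.std(epoch, ddof=1))
        if sd == 0:
            continue  # flat epoch: no tolerance scale, leave undefined
        r_abs = params.r * sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s, tau in enumerate(params.scales):
                grained = coarse_grain(epoch, tau)
                a, b = _sampen_counts(
                    np.ascontiguousarray(grained), params.m, r_abs
                )
                if a > 0 and b > 0:
                    values[e, s] = -np.log(a / b)
    n_defined = np.sum(~np.isnan(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
    return MSECurve(
        scales=np.asarray(params.scales),
        values=mean,
        n_defined=n_defined,
        fs=signal.fs,
    )


def scale_band_summary(curve: MSECurve, scale_range: tuple[int, int]) -> float:
    """Mean entropy over the defined scales in [lo, hi] (inclusive);
    NaN if no scale in range has a defined value."""
    lo, hi = scale_range
    sel = (curve.scales >= lo) & (curve.scales <= hi)
    if not sel.any():
        raise ValueError(f"no scales in range {scale_range} present in curve")
    vals = curve.values[sel]
    defined = ~np.isnan(vals)
    if not defined.any():
        warnings.warn(f"no defined entropy values in scale range {scale_range}")
        return float("nan")
    return float(vals[defined].mean())
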