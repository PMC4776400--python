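"""Synthetic cohort generator: seeded subjects carrying the effect
structure the downstream analyses are designed to detect.

Three groups are generated: stroke patients (a left-hemisphere spherical
lesion with a "slowing" field that decays with distance from the lesion
border), age-matched old controls (mildly "sped-up" MEG spectra, reduced
BOLD variability and complexity in a configurable region, globally reduced
CBF), and young controls (baseline).  Every random draw descends from the
single cohort seed through named per-subject / per-stage substreams, so an
identical :class:`CohortSpec` reproduces the cohort bit for bit.

MEG-like signals are synthesized in the frequency domain from a
1/f-plus-oscillation power spectrum; the *slowing* knob multiplies the
delta band gain by (1 + s) and divides the alpha and beta gains by the
same factor, shifting relative power toward low frequencies the way
perilesional tissue does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import lfilter  # nuisance-regressor AR filtering

from .asl import ASLParams, ASLSeries, perfusion_signal
from .bold import BoldTimeseries
from .geometry import LR_AXIS, BinaryMask, VolumeGeometry, VolumeMap
from .signals import EpochedSignal, Leadfield, SensorRecording

__all__ = [
    "SpectralProfile",
    "CohortSpec",
    "SubjectRecord",
    "synth_lesion_mask",
    "synth_meg_epochs",
    "synth_sensor_data",
    "synth_bold_run",
    "synth_cohort",
    "make_leadfield",
]

# Gaussian bump centers/widths (Hz) used to place oscillatory power inside
# the canonical bands; widths are narrow enough that a band captures the
# bulk of its bump at the ~2 Hz Welch resolution of 500 ms windows.
BAND_CENTERS: Mapping[str, float] = {
    "delta": 2.5,
    "theta": 5.5,
    "alpha": 10.0,
    "beta": 22.5,
}
BAND_WIDTHS: Mapping[str, float] = {
    "delta": 0.6,
    "theta": 0.6,
    "alpha": 0.8,
    "beta": 3.0,
}


@dataclass(frozen=True)
class SpectralProfile:
    """1/f-plus-oscillation power spectrum with a scalar slowing knob.

    ``band_gains`` are power gains of Gaussian bumps at the canonical band
    centers; ``slowing`` >= 0 multiplies the delta gain by (1 + slowing)
    and divides the alpha and beta gains by it (slowing = 0 reproduces the
    baseline profile exactly).
    """

    one_over_f_exponent: float = 1.0
    one_over_f_gain: float = 1.0
    band_gains: Mapping[str, float] = field(
        default_factory=lambda: {
            "delta": 1.0, "theta": 0.8, "alpha": 2.0, "beta": 0.8,
        }
    )
    noise_floor: float = 0.1
    slowing: float = 0.0

    def __post_init__(self) -> None:
        gains = dict(self.band_gains)
        if any(g < 0 for g in gains.values()):
            raise ValueError("band gains must be >= 0")
        unknown = set(gains) - set(BAND_CENTERS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        if self.slowing < 0:
            raise ValueError("slowing must be >= 0")
        if self.noise_floor < 0 or self.one_over_f_gain < 0:
            raise ValueError("spectral gains must be >= 0")
        object.__setattr__(self, "band_gains", gains)

    def with_slowing(self, slowing: float) -> "SpectralProfile":
        return replace(self, slowing=float(slowing))

    def effective_gains(self) -> dict[str, float]:
        g = dict(self.band_gains)
        factor = 1.0 + self.slowing
        if "delta" in g:
            g["delta"] *= factor
        for name in ("alpha", "beta"):
            if name in g:
                g[name] /= factor
        return g

    def psd(self, freqs: np.ndarray) -> np.ndarray:
        """Model power density at the given frequencies (arbitrary units)."""
        freqs = np.asarray(freqs, dtype=float)
        # clamp the 1/f pole below 1 Hz so the DC bin stays finite
        f_eff = np.maximum(freqs, 1.0)
        s = self.noise_floor + self.one_over_f_gain / f_eff**self.one_over_f_exponent
        for name, gain in self.effective_gains().items():
            c, w = BAND_CENTERS[name], BAND_WIDTHS[name]
            s = s + gain * np.exp(-0.5 * ((freqs - c) / w) ** 2)
        return s


def synth_lesion_mask(
    geometry: VolumeGeometry,
    center: Sequence[int],
    radius_mm: float,
    seed: int = 0,
) -> BinaryMask:
    """Spherical lesion mask, entirely within the left hemisphere.

    Voxels whose centers lie within ``radius_mm`` (Euclidean, mm) of the
    center voxel's center are set.  The center must be in the left half;
    a sphere reaching past the midline is truncated there with a warning.
    Deterministic given its arguments (the seed is accepted for interface
    uniformity).
    """
    del seed  # construction is deterministic
    center = tuple(int(c) for c in center)
    if len(center) != 3 or any(
        not 0 <= c < s for c, s in zip(center, geometry.shape)
    ):
        raise ValueError(f"center {center} outside grid {geometry.shape}")
    if not center[LR_AXIS] < geometry.midline_index:
        raise ValueError("lesion center must lie in the left hemisphere")
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    grids = geometry.voxel_centers()
    c_mm = [center[i] * geometry.voxel_size[i] for i in range(3)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, c_mm))
    sphere = dist2 <= radius_mm**2
    left = geometry.is_left()
    if (sphere & ~left).any():
        warnings.warn("lesion sphere reaches past the midline; truncating")
        sphere &= left
    return BinaryMask(sphere, geometry)


def synth_meg_epochs(
    profile: SpectralProfile,
    n_epochs: int,
    epoch_len_s: float,
    fs: float,
    seed: int | np.random.SeedSequence,
) -> EpochedSignal:
    """Epoched Gaussian signal whose expected spectrum follows the profile.

    Frequency-domain synthesis: each rFFT coefficient is complex Gaussian
    with variance proportional to the model PSD, so the Welch spectrum of
    the output converges to ``profile.psd`` in expectation.
    """
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    highest_edge = max(
        BAND_CENTERS[b] + 2 * BAND_WIDTHS[b] for b in profile.band_gains
    )
    if fs <= 2 * highest_edge:
        raise ValueError(
            f"sampling rate {fs} Hz too low for spectral content up to "
            f"~{highest_edge:.0f} Hz"
        )
    n_exact = epoch_len_s * fs
    n = int(np.floor(n_exact))
    if abs(n_exact - round(n_exact)) > 1e-9 and not np.isclose(n, n_exact):
        warnings.warn(
            f"epoch_len*fs = {n_exact:.3f} is non-integral; using {n} samples"
        )
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.sqrt(profile.psd(freqs) * fs * n / 2.0)
    z = rng.standard_normal((n_epochs, freqs.size, 2))
    coef = amp * (z[..., 0] + 1j * z[..., 1])
    coef[:, 0] = coef[:, 0].real * np.sqrt(2.0)  # DC is real
    if n % 2 == 0:
        coef[:, -1] = coef[:, -1].real * np.sqrt(2.0)  # Nyquist is real
    data = np.fft.irfft(coef, n=n, axis=1)
    return EpochedSignal(data=data, fs=fs)


def synth_sensor_data(
    source_signals: Sequence[EpochedSignal] | np.ndarray,
    leadfield: Leadfield,
    active_voxels: Sequence[int],
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    fs: float = None,
    orientations: np.ndarray = None,
) -> SensorRecording:
    """Forward-project source signals through the leadfield and add white
    sensor noise: ``x(t) = sum_v (L_v u_v) s_v(t) + noise``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    active_voxels = list(active_voxels)
    if max(active_voxels) >= leadfield.n_voxels:
        raise ValueError("active voxel index outside the leadfield")
    if isinstance(source_signals, np.ndarray):
        if fs is None:
            raise ValueError("fs is required with a raw source array")
        src = np.asarray(source_signals, dtype=float)
    else:
        fs_set = {s.fs for s in source_signals}
        if len(fs_set) != 1:
            raise ValueError("source signals must share one sampling rate")
        fs = fs_set.pop()
        src = np.stack([s.data for s in source_signals])
    if src.shape[0] != len(active_voxels):
        raise ValueError("one source signal per active voxel required")
    if orientations is None:
        orientations = np.tile([1.0, 0.0, 0.0], (len(active_voxels), 1))
    orientations = np.asarray(orientations, dtype=float)
    gains = np.einsum(
        "vct,vt->vc",
        leadfield.gains[active_voxels],
        orientations / np.linalg.norm(orientations, axis=1, keepdims=True),
    )  # (active, channels)
    sensors = np.einsum("vc,ves->ecs", gains, src)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)
    return SensorRecording(data=sensors, fs=fs)


def synth_bold_run(
    geometry: VolumeGeometry,
    n_volumes: int,
    tr: float,
    baseline_sd: float | np.ndarray,
    ar1: float | np.ndarray,
    seed: int | np.random.SeedSequence,
    baseline_level: float = 1000.0,
    nuisance: np.ndarray = None,
    nuisance_loading_sd: float = 0.0,
) -> BoldTimeseries:
    """AR(1) BOLD-like run with planted confound contributions.

    The noise-free voxel process is stationary AR(1) with long-run SD
    equal to ``baseline_sd`` (innovation SD scaled by sqrt(1 - ar1^2)).
    If ``nuisance`` regressors are given, each voxel receives a random
    linear combination of them (loadings ~ N(0, nuisance_loading_sd^2)),
    which nuisance regression downstream can remove exactly.
    """
    if n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    ar1_arr = np.broadcast_to(np.asarray(ar1, dtype=float), geometry.shape)
    if np.any(np.abs(ar1_arr) >= 1):
        raise ValueError("|ar1| must be < 1")
    sd_arr = np.broadcast_to(np.asarray(baseline_sd, dtype=float), geometry.shape)
    rng = np.random.default_rng(seed)
    n_vox = geometry.n_voxels
    innov = rng.standard_normal((n_vox, n_volumes))
    phi = ar1_arr.reshape(-1)
    sigma = sd_arr.reshape(-1) * np.sqrt(1.0 - phi**2)
    # burn-in free start: draw x[0] from the stationary distribution
    x = np.empty((n_vox, n_volumes))
    x[:, 0] = sd_arr.reshape(-1) * innov[:, 0]
    for t in range(1, n_volumes):
        x[:, t] = phi * x[:, t - 1] + sigma * innov[:, t]
    data = baseline_level + x.reshape(*geometry.shape, n_volumes)
    if nuisance is not None and nuisance_loading_sd > 0:
        nuisance = np.asarray(nuisance, dtype=float)
        loadings = nuisance_loading_sd * rng.standard_normal(
            (n_vox, nuisance.shape[1])
        )
        data = data + (loadings @ nuisance.T).reshape(*geometry.shape, n_volumes)
    return BoldTimeseries(
        data=data, geometry=geometry, tr=tr, nuisance=nuisance
    )


def make_leadfield(
    n_voxels: int,
    n_channels: int,
    seed: int | np.random.SeedSequence,
) -> Leadfield:
    """Random smooth synthetic leadfield (voxels, channels, 3), unit-scaled.

    Stands in for an anatomical forward model in beamformer simulations;
    columns are random Gaussian gain patterns normalized per voxel.
    """
    rng = np.random.default_rng(seed)
    gains = rng.standard_normal((n_voxels, n_channels, 3))
    norms = np.linalg.norm(gains.reshape(n_voxels, -1), axis=1)
    return Leadfield(gains / norms[:, None, None])


# --------------------------------------------------------------------------
# cohort-level generation


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, geometry, effect sizes and nuisance magnitudes of a
    synthetic cohort.  All randomness descends from ``seed``.

    Effect-size fields (all zero => the three groups are exchangeable):

    * ``rim_slowing`` — peak spectral slowing at the lesion border.
    * ``aging_speeding`` — spectral shift of old subjects away from delta
      toward alpha/beta.
    * ``aging_bold_sd_reduction`` — fractional BOLD-SD reduction of old
      subjects inside ``aging_mask``.
    * ``aging_ar1_increase`` — AR(1) increase of old subjects inside
      ``aging_mask`` (reduces BOLD sample entropy).
    * ``aging_cbf_reduction`` — global CBF deficit (ml/100g/min) of old
      subjects (stroke subjects are old as well).
    * ``rim_cbf_deficit`` — perilesional CBF deficit at the lesion border.
    * ``cbf_slowing_coupling`` — ml/100g/min of CBF change per unit of
      planted slowing (negative couples hypoperfusion to slowing).
    """

    n_stroke: int = 19
    n_old: int = 19
    n_young: int = 19
    geometry: VolumeGeometry = field(
        default_factory=lambda: VolumeGeometry((12, 12, 12), (10.0, 10.0, 10.0))
    )
    seed: int = 0
    # effect sizes
    rim_slowing: float = 1.0
    aging_speeding: float = 0.15
    aging_bold_sd_reduction: float = 0.3
    aging_ar1_increase: float = 0.25
    aging_cbf_reduction: float = 15.0
    rim_cbf_deficit: float = 8.0
    cbf_slowing_coupling: float = -10.0
    subject_cv: float = 0.3
    slowing_length_mm: float = 10.0
    # lesion geometry
    lesion_radius_mm: float = 18.0
    lesion_radius_sd_mm: float = 3.0
    # MEG
    meg_n_epochs: int = 60
    meg_epoch_len_s: float = 5.0
    meg_fs: float = 208.33
    baseline_profile: SpectralProfile = field(default_factory=SpectralProfile)
    # BOLD
    bold_n_volumes: int = 180
    bold_tr_s: float = 2.0
    bold_baseline_sd: float = 5.0
    bold_ar1: float = 0.3
    bold_baseline_level: float = 1000.0
    bold_nuisance_loading: float = 1.0
    aging_mask: BinaryMask = None  # type: ignore[assignment]
    # ASL / CBF
    asl_n_frames: int = 150
    asl_tr_s: float = 3.0
    asl_params: ASLParams = field(default_factory=ASLParams)
    cbf_baseline: float = 56.0
    lesion_cbf: float = 12.0
    cbf_subject_sd: float = 2.0
    cbf_voxel_noise: float = 3.0
    asl_noise_sd: float = 2.0
    asl_base_signal: float = 800.0
    m0_value: float = 1000.0
    gm_mask: BinaryMask = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.n_stroke, self.n_old, self.n_young) < 1:
            raise ValueError("need at least one subject per group")
        for name in (
            "rim_slowing", "aging_speeding", "aging_bold_sd_reduction",
            "aging_ar1_increase", "aging_cbf_reduction", "rim_cbf_deficit",
            "cbf_slowing_coupling",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect size {name} must be finite")
        if self.gm_mask is None:
            object.__setattr__(self, "gm_mask", default_gm_mask(self.geometry))
        if self.aging_mask is None:
            object.__setattr__(
                self, "aging_mask", default_aging_mask(self.geometry)
            )


def default_gm_mask(geometry: VolumeGeometry) -> BinaryMask:
    """Ellipsoidal 'brain' inscribed in the grid (semi-axes 0.45 extent)."""
    grids = geometry.voxel_centers()
    out = np.zeros(geometry.shape, dtype=bool)
    centers = [
        (s - 1) * v / 2.0 for s, v in zip(geometry.shape, geometry.voxel_size)
    ]
    semi = [max(s * v * 0.45, v) for s, v in zip(geometry.shape, geometry.voxel_size)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    out[r2 <= 1.0] = True
    return BinaryMask(out, geometry)


def default_aging_mask(geometry: VolumeGeometry) -> BinaryMask:
    """Central bilateral block (midline-symmetric) standing in for the
    default-mode territory where aging effects are planted."""
    out = np.zeros(geometry.shape, dtype=bool)
    sl = tuple(slice(s // 4, s - s // 4) for s in geometry.shape)
    out[sl] = True
    return BinaryMask(out, geometry)


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: masks, ground truth and signal factories."""

    subject_id: str
    group: str  # 'stroke' | 'old' | 'young'
    geometry: VolumeGeometry
    lesion_mask: BinaryMask
    gm_mask: BinaryMask
    slowing_map: VolumeMap
    cbf_truth: VolumeMap
    m0: VolumeMap
    bold: BoldTimeseries
    asl: ASLSeries
    planted: dict
    _spec: CohortSpec
    _index: int

    def __post_init__(self) -> None:
        if self.group not in ("stroke", "old", "young"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "stroke" and (
            self.lesion_mask.data & ~self.geometry.is_left()
        ).any():
            raise ValueError("stroke lesion must lie in the left hemisphere")

    def profile_at(self, flat_voxel: int) -> SpectralProfile:
        base = self.planted["profile"]
        slowing = float(self.slowing_map.data.reshape(-1)[flat_voxel])
        return base.with_slowing(slowing)

    def meg_signal(self, flat_voxel: int) -> EpochedSignal:
        """Virtual-channel signal at one voxel; deterministic per voxel
        regardless of the order in which voxels are requested."""
        spec = self._spec
        ss = np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(self._index, 2, int(flat_voxel))
        )
        return synth_meg_epochs(
            self.profile_at(flat_voxel),
            n_epochs=spec.meg_n_epochs,
            epoch_len_s=spec.meg_epoch_len_s,
            fs=spec.meg_fs,
            seed=ss,
        )

    def meg_signals(self, mask: BinaryMask) -> dict[int, EpochedSignal]:
        flats = np.flatnonzero(mask.data.reshape(-1))
        return {int(v): self.meg_signal(int(v)) for v in flats}


def _subject_stream(spec: CohortSpec, index: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=spec.seed, spawn_key=(index, stage))


def _truncated_factor(rng: np.random.Generator, cv: float) -> float:
    """Per-subject effect multiplier ~ N(1, cv), truncated at 0.1."""
    return float(max(0.1, 1.0 + cv * rng.standard_normal()))


def _slowing_decay(
    lesion: BinaryMask, geometry: VolumeGeometry, length_mm: float
) -> np.ndarray:
    """exp(-d/length) outside the lesion in the left hemisphere, with d the
    Euclidean distance (mm) from the lesion border; zero inside the lesion
    and everywhere in the right hemisphere (the mirror ROI is clean by
    construction)."""
    if not lesion.data.any():
        return np.zeros(geometry.shape)
    dist = ndimage.distance_transform_edt(
        ~lesion.data, sampling=geometry.voxel_size
    )
    # EDT measures to the nearest lesion voxel *center*; subtract one voxel
    # spacing as the center-to-border offset so tissue touching the lesion
    # carries the full effect (distance-from-border semantics)
    dist = np.maximum(dist - min(geometry.voxel_size), 0.0)
    decay = np.exp(-dist / length_mm)
    decay[lesion.data] = 0.0
    decay[~geometry.is_left()] = 0.0
    return decay


def _make_lesion(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[BinaryMask, tuple[int, int, int], float]:
    geom = spec.geometry
    radius = float(
        np.clip(
            rng.normal(spec.lesion_radius_mm, spec.lesion_radius_sd_mm),
            max(5.0, min(geom.voxel_size)),
            spec.lesion_radius_mm + 3 * spec.lesion_radius_sd_mm,
        )
    )
    # keep the sphere clear of the midline so no truncation warning fires
    max_x_mm = geom.midline_index * geom.voxel_size[LR_AXIS] - radius
    max_x = int(np.floor(max_x_mm / geom.voxel_size[LR_AXIS]))
    max_x = max(1, min(max_x, geom.shape[LR_AXIS] - 1))
    gm_left = spec.gm_mask.data & geom.is_left()
    candidates = np.argwhere(gm_left[: max_x + 1])
    if candidates.size == 0:
        candidates = np.argwhere(geom.is_left()[: max_x + 1])
    center = tuple(int(c) for c in candidates[rng.integers(len(candidates))])
    return synth_lesion_mask(geom, center, radius), center, radius


def _make_subject(spec: CohortSpec, index: int, group: str) -> SubjectRecord:
    geom = spec.geometry
    les_rng = np.random.default_rng(_subject_stream(spec, index, 0))
    eff_rng = np.random.default_rng(_subject_stream(spec, index, 1))
    bold_seed = _subject_stream(spec, index, 3)
    asl_rng = np.random.default_rng(_subject_stream(spec, index, 4))

    empty = BinaryMask(np.zeros(geom.shape, dtype=bool), geom)
    planted: dict = {"group": group}

    # --- lesion and slowing field -------------------------------------
    if group == "stroke":
        lesion, center, radius = _make_lesion(spec, les_rng)
        s_subj = spec.rim_slowing * _truncated_factor(eff_rng, spec.subject_cv)
        decay = _slowing_decay(lesion, geom, spec.slowing_length_mm)
        slowing = s_subj * decay
        planted.update(
            lesion_center=center, lesion_radius_mm=radius, slowing=s_subj
        )
    else:
        lesion, slowing, decay = empty, np.zeros(geom.shape), np.zeros(geom.shape)
        planted.update(slowing=0.0)

    # --- MEG spectral profile -----------------------------------------
    profile = spec.baseline_profile
    if group in ("stroke", "old"):
        speed = spec.aging_speeding * _truncated_factor(eff_rng, spec.subject_cv)
        if spec.aging_speeding == 0:
            speed = 0.0
        gains = dict(profile.band_gains)
        gains["delta"] = gains.get("delta", 0.0) / (1.0 + speed)
        for name in ("alpha", "beta"):
            if name in gains:
                gains[name] *= 1.0 + speed
        profile = replace(profile, band_gains=gains)
        planted["aging_speeding"] = speed
    else:
        planted["aging_speeding"] = 0.0
    planted["profile"] = profile

    # --- BOLD run ------------------------------------------------------
    sd_map = np.full(geom.shape, spec.bold_baseline_sd)
    ar_map = np.full(geom.shape, spec.bold_ar1)
    if group in ("stroke", "old"):
        red = spec.aging_bold_sd_reduction * _truncated_factor(
            eff_rng, spec.subject_cv
        )
        ar_up = spec.aging_ar1_increase * _truncated_factor(
            eff_rng, spec.subject_cv
        )
        if spec.aging_bold_sd_reduction == 0:
            red = 0.0
        if spec.aging_ar1_increase == 0:
            ar_up = 0.0
        inside = spec.aging_mask.data
        sd_map[inside] *= max(0.05, 1.0 - red)
        ar_map[inside] = np.clip(ar_map[inside] + ar_up, -0.99, 0.99)
        planted.update(bold_sd_reduction=red, bold_ar1_increase=ar_up)
    else:
        planted.update(bold_sd_reduction=0.0, bold_ar1_increase=0.0)
    nuis_rng = np.random.default_rng(_subject_stream(spec, index, 5))
    nuisance = lfilter(
        [1.0], [1.0, -0.5], nuis_rng.standard_normal((spec.bold_n_volumes, 8)),
        axis=0,
    )
    bold = synth_bold_run(
        geometry=geom,
        n_volumes=spec.bold_n_volumes,
        tr=spec.bold_tr_s,
        baseline_sd=sd_map,
        ar1=ar_map,
        seed=bold_seed,
        baseline_level=spec.bold_baseline_level,
        nuisance=nuisance,
        nuisance_loading_sd=spec.bold_nuisance_loading,
    )
    bold = replace(bold, brain_mask=spec.gm_mask)

    # --- CBF ground truth and ASL frames ------------------------------
    cbf = np.full(
        geom.shape,
        spec.cbf_baseline + spec.cbf_subject_sd * asl_rng.standard_normal(),
    )
    if group in ("stroke", "old"):
        cbf -= spec.aging_cbf_reduction
    if group == "stroke":
        cbf += (
            -spec.rim_cbf_deficit + spec.cbf_slowing_coupling * planted["slowing"]
        ) * decay
        cbf[lesion.data] = spec.lesion_cbf
    if spec.cbf_voxel_noise > 0:
        cbf = cbf + spec.cbf_voxel_noise * asl_rng.standard_normal(geom.shape)
    cbf = np.maximum(cbf, 0.0)
    m0 = VolumeMap(np.full(geom.shape, spec.m0_value), geom)
    dm = perfusion_signal(cbf, m0.data, spec.asl_params)
    ctrl = (np.arange(spec.asl_n_frames) % 2) == 1  # frame 0 is a tag
    frames = (
        spec.asl_base_signal
        + np.where(ctrl, 0.5, -0.5)[None, None, None, :] * dm[..., None]
    )
    if spec.asl_noise_sd > 0:
        frames = frames + spec.asl_noise_sd * asl_rng.standard_normal(frames.shape)
    asl = ASLSeries(
        data=frames,
        geometry=geom,
        m0=m0,
        tr_s=spec.asl_tr_s,
        first_label="tag",
    )

    return SubjectRecord(
        subject_id=f"{group}{index:03d}",
        group=group,
        geometry=geom,
        lesion_mask=lesion,
        gm_mask=spec.gm_mask,
        slowing_map=VolumeMap(slowing, geom),
        cbf_truth=VolumeMap(cbf, geom),
        m0=m0,
        bold=bold,
        asl=asl,
        planted=planted,
        _spec=spec,
        _index=index,
    )


def synth_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort: stroke, old, then young subjects.

    Subject index (the position in the returned list) keys every random
    substream, so an identical spec yields a bit-identical cohort and one
    stage's outputs do not depend on another stage's draws.
    """
    groups = (
        ["stroke"] * spec.n_stroke + ["old"] * spec.n_old + ["young"] * spec.n_young
    )
    return [_make_subject(spec, i, g) for i, g in enumerate(groups)]
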