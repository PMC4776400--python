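# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic-data results do and do not establish.

## Synthetic cohort: what is emulated

The generator produces three groups on one regular grid (default 12³
voxels of 10 mm — the resolution at which beamformer maps are computed;
one voxel ≈ one source-grid location).  All randomness descends from a
single integer seed through named per-subject, per-stage
`SeedSequence` substreams, so a spec regenerates bit-identically and
changing one stage's draws cannot perturb another stage.

**MEG-like signals.** Virtual-channel epochs are synthesized in the
frequency domain from a model PSD: a flat noise floor, a `1/f` component
(pole clamped below 1 Hz), and Gaussian bumps at 2.5, 5.5, 10 and
22.5 Hz representing delta, theta, alpha and beta oscillations (bump
widths 0.6/0.6/0.8/3.0 Hz — narrow enough that each band captures the
bulk of its bump at the ~2 Hz Welch resolution).  Default power gains
(delta 1.0, theta 0.8, alpha 2.0, beta 0.8, floor 0.1, 1/f gain 1.0)
give a plausible resting spectrum with a dominant alpha peak.  Each rFFT
coefficient is complex Gaussian with variance proportional to the model
PSD, so the expected Welch spectrum equals the model and epochs are
stationary Gaussian — no nonstationarity, no artifacts, no cross-voxel
correlation.  Epochs are 5 s at 208.33 Hz (floor → 1041 samples), 60 per
subject by default (5 min of data).

**The slowing knob.** A scalar `s ≥ 0` multiplies the delta gain by
`(1+s)` and divides the alpha and beta gains by `(1+s)`; `s = 0` is
exactly baseline.  One knob moves relative power in the four directions
of the perilesional pattern, and — because low frequencies survive
block-averaging while the tolerance `r` stays pinned to the scale-1 SD —
it simultaneously lowers sample entropy at fine scales and raises it at
coarse scales.  The paper-level pattern therefore emerges from the
measurement chain rather than being written into the measures.

**Stroke subjects.** A spherical lesion (radius ~N(18, 3²) mm, truncated
to stay left of the midline) is placed at a random gray-matter site in
the left hemisphere.  The slowing field is `s_subj · exp(−d/10 mm)` with
`d` the Euclidean distance from the lesion border (EDT minus one voxel
spacing, floored at 0), zero inside the lesion and everywhere in the
right hemisphere — so the mirror ROI is clean by construction.
`s_subj` is the cohort-level effect size (default 1.0) jittered
per subject with CV 0.3, which is what makes across-subject
correlations estimable at n = 19.

**CBF.** Ground truth is `base + subject jitter (SD 2) −
(deficit + |coupling|·s_subj)·decay + voxel noise (SD 3)`, with
base 56 ml/100g/min for young, −15 for old and stroke (global aging
deficit), rim deficit 8 and coupling −10 ml/100g/min per unit slowing;
lesion core fixed at 12.  ASL frames are generated by the *forward*
kinetic model (ΔM split ±½ around a constant tissue signal, thermal
noise SD 2), so the quantification stage is exercised end to end.
The group means the pipeline recovers (≈ 56/41/38) follow from these
defaults, which were chosen once as physiologically plausible 3 T
values; they are inputs, not findings.

**BOLD.** Stationary AR(1) voxel series (young φ = 0.3, SD 5 on a
baseline level of 1000) plus planted linear contributions of 8 stored
nuisance regressors (6 motion-like + WM + CSF channels, AR(0.5)).  Old
and stroke subjects have SD reduced by 30 % and φ raised by 0.25 inside
a central bilateral block standing in for default-mode territory (no
atlas download).  The φ increase is what lowers sample entropy: SampEn
with `r = 0.2 × SD` is scale-invariant, so a pure SD reduction cannot
move it — planting the aging complexity effect requires an
autocorrelation change, and this is the package's explicit mechanism.
Because nuisance contributions are exact linear combinations of the
stored regressors, the regression stage removes them exactly.

**What passing does not show.** The generator has no anatomy, no
hemodynamic response, no motion or physiological noise, no cross-voxel
source correlation, and effect sizes are not calibrated to patient data
(none are published for these quantities).  Green directional tests
demonstrate that the pipeline *recovers planted structure with correct
signs and calibrated false-positive rates*, not that real data would
yield the same magnitudes.

## Measurement conventions

- **Welch spectra:** 500 ms Hamming windows (104 samples at 208.33 Hz),
  50 % overlap, FFT length = window length, no detrending, density
  scaling.  Relative band power uses half-open `[low, high)` band edges
  on bin centers and a closed 0–80 Hz total band; the DC bin is included
  in the denominator (config switch `include_dc`).  With ~2 Hz bins the
  4 Hz bin belongs to theta and the 12 Hz bin to the 12–15 Hz gap.
- **Sample entropy:** Richman–Moorman counting (templates of length m
  and m+1 both start at indices `0..N−m−1`, self-matches excluded,
  Chebyshev distance), `−ln(A/B)`; undefined (NaN, warned) when either
  count is zero, and undefined epochs/scales are excluded from averages
  rather than imputed.  The numba kernel is validated against a pure-
  Python O(N²) enumeration for exact equality.
- **MSE:** per 5 s epoch, tolerance fixed at `r × SD` of that epoch's
  original series (N−1 SD), held constant across scales (Costa
  convention); coarse-graining is non-overlapping block means of length
  τ (output length ⌊N/τ⌋); entropy is computed per epoch then averaged.
  Scale summaries are plain means over scales 1–5 and 7–20.
- **Beamformer:** orientation is the eigenvector of `LᵀC⁻¹L` with the
  smallest *nonzero* eigenvalue (raw dipole power objective; null
  directions of a rank-deficient leadfield carry no signal and are
  excluded), sign fixed so the largest-magnitude component is positive;
  ties resolved by axis order with a warning.  The covariance inverse
  uses diagonal loading `C + 0.01·mean(diag C)·I` by default; σ²_noise
  is always taken from the unregularized covariance.  The anti-alias
  filter is a Hamming-windowed FIR applied forward–backward, order
  ≈ 3·fs / transition width, transition chosen to end below the
  post-decimation Nyquist.
- **BOLD preprocessing** is fixed as smooth (8 mm FWHM, σ = FWHM/2.3548
  per axis in voxel units) → nuisance regression (OLS with intercept,
  voxel mean added back; rank-deficient designs rejected) → grand-mean
  scaling of the in-brain 4D mean to 100.  SD and MSSD use N−1
  denominators.
- **ASL:** surround subtraction interpolates the opposite condition from
  the two temporal neighbors (single neighbor at the boundaries, so
  boundary frames retain linear-drift sensitivity; interior frames
  cancel drift exactly), then averages the two per-frame differences of
  each tag/control pair.  Kinetic constants default to λ = 0.9 ml/g,
  α = 0.95, T1_blood = 1650 ms with TI1 = 700 ms, TI2 = 1800 ms; all are
  config-exposed.  Per-slice TI2 increments are omitted (the synthetic
  grid has no slice timing); a config hook would be the place to add
  them.
- **ROIs:** dilation is metric (mm, center-to-center, ≤ comparison,
  anisotropic voxel sizes honored).  The rim is
  `(dilate(lesion, 10 mm) ∖ lesion) ∩ gray matter`, optionally block-
  downsampled with an "any" rule (preserves thin rims).  Mirroring is
  pure index reflection on a grid that is validated to be symmetric
  about its midline, which guarantees exactly equal rim and mirror
  voxel counts.
- **Statistics:** equal-variance Student t (two-sided), chosen over
  Welch to match the common neuroimaging default; cluster connectivity
  faces-only (6), config-switchable; positive and negative effects are
  clustered separately; surviving clusters labeled in decreasing size
  order.  Map-level FDR is the plug-in estimate `q = p0·m / #{p ≤ p0}`
  clipped at 1; per-voxel BH q values accompany it.  Spearman maps use
  average ranks and the t approximation for p.  Sign tests are exact
  binomial, zeros dropped.

## Problem sizes

Simulation-heavy checks run at desk scale, chosen once: 12³ grids at
10 mm; 24 five-second MEG epochs per voxel in the pipeline runs (the
generator default remains 60); full 180-volume BOLD runs and 150-frame
ASL series for the directional analyses; 96-volume runs, 4-frame ASL
and no smoothing for the 50-replicate null calibration (t-test
calibration does not depend on run length, and at 10 mm voxels the 8 mm
kernel is sub-voxel and near-identity).  The full directional pipeline
completes in about two minutes on one CPU; the null calibration in
about half a minute.

## Known limitations

- The spec of the orientation objective (raw power vs pseudo-Z) and the
  exact FDR estimator variant are conventions; both are documented above
  and isolated behind single functions.
- Epoch rejection is modeled as a caller-supplied keep-list (artifact
  detection is out of scope); the cohort generator produces no
  artifacts.
- `table_summary` reproduces the bundled tables' printed means; the
  time-post-onset column parses "Xy Ym" to X + Y/12 years, which gives
  4.24 rather than the printed 4.26 mean — the original parsing
  convention is unknown, so that cell is not asserted anywhere.
- Lesion masking of group BOLD maps is available via the mask arguments
  but defaults to off.
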