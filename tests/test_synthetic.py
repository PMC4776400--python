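import numpy as np
import pytest

from restdyn.bold import mssd, nuisance_regress, sd_bold
from restdyn.geometry import VolumeGeometry
from restdyn.spectral import epoch_psd, relative_band_power
from restdyn.synthetic import (
    CohortSpec,
    SpectralProfile,
    synth_bold_run,
    synth_cohort,
    synth_lesion_mask,
    synth_meg_epochs,
)
from restdyn.volume_ops import RimParams, mirror, perilesional_rim

from .oracles import lattice_ball_count


class TestLesionMask:
    def test_radius_zero_is_center_voxel(self, geom_iso1):
        mask = synth_lesion_mask(geom_iso1, (5, 10, 10), 0.0)
        assert mask.count == 1
        assert mask.data[5, 10, 10]

    def test_count_matches_lattice_enumeration(self):
        geom = VolumeGeometry((43, 43, 43), (1.0, 1.0, 1.0))
        mask = synth_lesion_mask(geom, (10, 21, 21), 10.0)
        assert mask.count == lattice_ball_count(10.0, (1, 1, 1))

    def test_deterministic(self, geom_iso1):
        a = synth_lesion_mask(geom_iso1, (4, 10, 10), 5.0)
        b = synth_lesion_mask(geom_iso1, (4, 10, 10), 5.0)
        assert (a.data == b.data).all()

    def test_right_hemisphere_center_rejected(self, geom_iso1):
        with pytest.raises(ValueError, match="left"):
            synth_lesion_mask(geom_iso1, (15, 10, 10), 3.0)

    def test_midline_crossing_truncated_with_warning(self, geom_iso1):
        with pytest.warns(UserWarning, match="truncat"):
            mask = synth_lesion_mask(geom_iso1, (8, 10, 10), 5.0)
        assert not (mask.data & geom_iso1.is_right()).any()
        assert not mask.data[10].any()  # midline plane itself excluded


class TestMEGSynthesis:
    def test_epoch_shape_follows_floor(self):
        sig = synth_meg_epochs(SpectralProfile(), 60, 5.0, 208.33, seed=0)
        assert sig.data.shape == (60, 1041)

    def test_pure_alpha_profile_dominates_spectrum(self):
        profile = SpectralProfile(
            one_over_f_gain=0.0,
            noise_floor=0.0,
            band_gains={"alpha": 1.0},
        )
        sig = synth_meg_epochs(profile, 30, 5.0, 208.33, seed=1)
        # 2 s windows: fine enough resolution that the alpha bump is not
        # smeared into the 7-8 and 12-15 Hz band gaps by the taper
        from restdyn.spectral import SpectralParams

        params = SpectralParams(window_len_s=2.0)
        alpha = relative_band_power(epoch_psd(sig, params), "alpha", params=params)
        assert alpha > 0.9

    def test_slowing_shifts_relative_power(self):
        """Monte-Carlo across 50 seeds: slowing 2 raises mean relative
        delta power and lowers mean relative beta power vs slowing 0."""
        base = SpectralProfile()
        slow = base.with_slowing(2.0)
        delta_diff, beta_diff = [], []
        for seed in range(50):
            s0 = epoch_psd(synth_meg_epochs(base, 2, 5.0, 208.33, seed=seed))
            s2 = epoch_psd(
                synth_meg_epochs(slow, 2, 5.0, 208.33, seed=1000 + seed)
            )
            delta_diff.append(
                relative_band_power(s2, "delta") - relative_band_power(s0, "delta")
            )
            beta_diff.append(
                relative_band_power(s2, "beta") - relative_band_power(s0, "beta")
            )
        assert np.mean(delta_diff) > 0
        assert np.mean(beta_diff) < 0

    def test_zero_slowing_reproduces_baseline(self):
        base = SpectralProfile()
        assert base.with_slowing(0.0).effective_gains() == base.band_gains

    def test_seeded_determinism(self):
        a = synth_meg_epochs(SpectralProfile(), 3, 2.0, 208.33, seed=42)
        b = synth_meg_epochs(SpectralProfile(), 3, 2.0, 208.33, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            synth_meg_epochs(SpectralProfile(), 2, 1.0, 40.0, seed=0)


class TestBoldSynthesis:
    GEOM = VolumeGeometry((4, 4, 4), (10.0, 10.0, 10.0))

    def test_zero_sd_constant_after_regression(self, rng):
        nuis = rng.standard_normal((30, 3))
        run = synth_bold_run(
            self.GEOM, 30, 2.0, baseline_sd=0.0, ar1=0.0, seed=5,
            nuisance=nuis, nuisance_loading_sd=2.0,
        )
        out = nuisance_regress(run)
        flat = out.data.reshape(-1, 30)
        assert np.allclose(sd_bold(flat), 0.0, atol=1e-8)

    def test_white_run_sd_matches_baseline(self):
        run = synth_bold_run(
            VolumeGeometry((1, 1, 1), (1, 1, 1)), 10_000, 2.0,
            baseline_sd=3.0, ar1=0.0, seed=6,
        )
        assert abs(sd_bold(run.data[0, 0, 0]) - 3.0) < 0.15  # 5%

    def test_white_run_mssd_over_variance_near_two(self):
        run = synth_bold_run(
            VolumeGeometry((1, 1, 1), (1, 1, 1)), 10_000, 2.0,
            baseline_sd=2.0, ar1=0.0, seed=7,
        )
        x = run.data[0, 0, 0]
        assert abs(mssd(x) / x.var(ddof=1) - 2.0) < 0.1

    def test_ar1_bound_enforced(self):
        with pytest.raises(ValueError, match="ar1"):
            synth_bold_run(self.GEOM, 10, 2.0, 1.0, ar1=1.0, seed=0)


class TestCohort:
    def small_spec(self, **kw):
        defaults = dict(
            n_stroke=2, n_old=2, n_young=2, seed=9,
            meg_n_epochs=2, bold_n_volumes=20, asl_n_frames=20,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_bit_identical_regeneration(self):
        a = synth_cohort(self.small_spec())
        b = synth_cohort(self.small_spec())
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.bold.data, sb.bold.data)
            assert np.array_equal(sa.asl.data, sb.asl.data)
            assert np.array_equal(sa.lesion_mask.data, sb.lesion_mask.data)
            assert np.array_equal(sa.cbf_truth.data, sb.cbf_truth.data)
            sig_a, sig_b = sa.meg_signal(100), sb.meg_signal(100)
            assert np.array_equal(sig_a.data, sig_b.data)

    def test_meg_factory_order_independent(self):
        subj = synth_cohort(self.small_spec())[0]
        first = subj.meg_signal(50).data.copy()
        subj.meg_signal(51)
        assert np.array_equal(subj.meg_signal(50).data, first)

    def test_slowing_maximal_in_rim_zero_in_mirror(self):
        cohort = synth_cohort(self.small_spec(n_stroke=3))
        for subj in (s for s in cohort if s.group == "stroke"):
            rim = perilesional_rim(
                subj.lesion_mask, RimParams(10.0, subj.gm_mask)
            )
            if rim.count == 0:
                continue
            slowing = subj.slowing_map.data
            outside = ~rim.data & ~subj.lesion_mask.data & subj.gm_mask.data
            assert slowing[rim.data].max() == pytest.approx(slowing.max())
            assert slowing[rim.data].mean() > slowing[outside].mean()
            assert np.allclose(slowing[mirror(rim).data], 0.0)

    def test_controls_have_no_lesion_or_slowing(self):
        cohort = synth_cohort(self.small_spec())
        for subj in cohort:
            if subj.group != "stroke":
                assert subj.lesion_mask.count == 0
                assert np.allclose(subj.slowing_map.data, 0.0)

    def test_planted_cbf_coupling_negative_across_subjects(self):
        """Across 19 stroke subjects the rim-mean ground-truth CBF is
        negatively correlated with the rim-mean planted slowing."""
        spec = self.small_spec(n_stroke=19, n_old=1, n_young=1, seed=33)
        cohort = synth_cohort(spec)
        cbf_means, slow_means = [], []
        for subj in (s for s in cohort if s.group == "stroke"):
            rim = perilesional_rim(subj.lesion_mask, RimParams(10.0, subj.gm_mask))
            if rim.count == 0:
                continue
            cbf_means.append(subj.cbf_truth.mean_in(rim))
            slow_means.append(subj.slowing_map.mean_in(rim))
        assert len(cbf_means) >= 15
        r = np.corrcoef(cbf_means, slow_means)[0, 1]
        assert r < 0

    def test_zero_effects_make_groups_statistically_identical(self):
        spec = self.small_spec(
            rim_slowing=0.0, aging_speeding=0.0, aging_bold_sd_reduction=0.0,
            aging_ar1_increase=0.0, aging_cbf_reduction=0.0,
            rim_cbf_deficit=0.0, cbf_slowing_coupling=0.0,
        )
        cohort = synth_cohort(spec)
        stroke, young = cohort[0], cohort[-1]
        assert np.allclose(stroke.slowing_map.data, 0.0)
        # identical planted BOLD parameters -> same marginal SD field
        assert stroke.planted["bold_sd_reduction"] == 0.0
        assert stroke.planted["aging_speeding"] == 0.0
        assert (
            stroke.planted["profile"].band_gains
            == young.planted["profile"].band_gains
        )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            CohortSpec(n_stroke=0)
        with pytest.raises(ValueError, match="finite"):
            CohortSpec(rim_slowing=float("nan"))
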