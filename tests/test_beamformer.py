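import numpy as np
import pytest

from restdyn.beamformer import (
    compute_weights,
    optimal_orientation,
    preprocess_sensors,
    sam_weights,
    sensor_covariance,
    virtual_channel,
)
from restdyn.signals import SensorRecording
from restdyn.synthetic import SpectralProfile, make_leadfield, synth_meg_epochs, synth_sensor_data


def random_psd_cov(n, rng, reg=0.0):
    from restdyn.beamformer import SensorCovariance

    a = rng.standard_normal((n, 2 * n))
    c = a @ a.T / (2 * n)
    sv = np.linalg.svd(c, compute_uv=False)
    return SensorCovariance(matrix=c, reg_fraction=reg, sigma2_noise=float(sv[-1]))


class TestPreprocess:
    def test_decimation_by_three_gives_20833(self, rng):
        rec = SensorRecording(rng.standard_normal((2, 4, 3125)), fs=625.0)
        out = preprocess_sensors(rec, lowpass=80.0, decim=3)
        assert out.fs == pytest.approx(625.0 / 3)
        assert round(out.fs, 2) == 208.33
        assert out.n_samples == 1042  # ceil(3125 / 3)

    def test_dc_passes_unchanged(self):
        rec = SensorRecording(np.full((1, 3, 2000), 7.0), fs=625.0)
        out = preprocess_sensors(rec, lowpass=80.0, decim=3)
        assert np.allclose(out.data, 7.0, atol=1e-6)

    def test_stopband_tone_attenuated(self):
        t = np.arange(6250) / 625.0
        tone = np.sin(2 * np.pi * 100.0 * t)
        rec = SensorRecording(tone[None, None, :], fs=625.0)
        out = preprocess_sensors(rec, lowpass=80.0, decim=3)
        rms_in = np.sqrt(np.mean(tone**2))
        rms_out = np.sqrt(np.mean(out.data**2))
        assert rms_out < 0.05 * rms_in

    def test_lowpass_above_new_nyquist_rejected(self, rng):
        rec = SensorRecording(rng.standard_normal((1, 2, 1000)), fs=625.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_sensors(rec, lowpass=110.0, decim=3)


class TestCovariance:
    def test_scaling_is_quadratic(self, rng):
        data = rng.standard_normal((1, 5, 400))
        c1 = sensor_covariance(SensorRecording(data, 100.0)).matrix
        c3 = sensor_covariance(SensorRecording(3 * data, 100.0)).matrix
        assert np.allclose(c3, 9 * c1)

    def test_white_noise_noise_power_near_one(self, rng):
        data = rng.standard_normal((1, 8, 40_000))
        cov = sensor_covariance(SensorRecording(data, 100.0))
        # smallest eigenvalue of a Wishart is biased slightly low
        assert 0.85 < cov.sigma2_noise < 1.05

    def test_rank_deficient_rejected_without_loading(self, rng):
        mix = rng.standard_normal((6, 2))
        data = mix @ rng.standard_normal((1, 2, 500))[0]
        with pytest.raises(ValueError, match="reg_fraction"):
            sensor_covariance(SensorRecording(data[None], 100.0), reg_fraction=0.0)

    def test_too_few_samples_rejected(self, rng):
        rec = SensorRecording(rng.standard_normal((1, 10, 8)), 100.0)
        with pytest.raises(ValueError, match="samples"):
            sensor_covariance(rec)


class TestOrientation:
    def test_single_feasible_column(self, rng):
        cov = random_psd_cov(6, rng)
        L = np.zeros((6, 3))
        L[:, 0] = rng.standard_normal(6)
        u = optimal_orientation(L, cov)
        assert np.allclose(np.abs(u), [1.0, 0.0, 0.0], atol=1e-10)

    def test_sign_convention_invariant_to_leadfield_negation(self, rng):
        cov = random_psd_cov(8, rng)
        L = rng.standard_normal((8, 3))
        assert np.allclose(optimal_orientation(L, cov), optimal_orientation(-L, cov))

    def test_matches_spherical_grid_search_within_two_degrees(self, rng):
        """Closed-form smallest-eigenvector orientation vs brute force over
        a 1 degree spherical grid of candidate orientations."""
        for _ in range(3):
            cov = random_psd_cov(8, rng)
            L = rng.standard_normal((8, 3))
            q = L.T @ cov.inverse() @ L
            theta = np.deg2rad(np.arange(0.0, 180.0, 1.0))
            phi = np.deg2rad(np.arange(0.0, 360.0, 1.0))
            tt, pp = np.meshgrid(theta, phi, indexing="ij")
            dirs = np.stack(
                [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)],
                axis=-1,
            ).reshape(-1, 3)
            power_inv = np.einsum("ni,ij,nj->n", dirs, q, dirs)
            best = dirs[np.argmin(power_inv)]
            u = optimal_orientation(L, cov)
            angle = np.rad2deg(np.arccos(np.clip(abs(best @ u), -1, 1)))
            assert angle <= 2.0


class TestWeights:
    def test_identity_covariance_closed_form(self, rng):
        from restdyn.beamformer import SensorCovariance

        cov = SensorCovariance(np.eye(5), 0.0, 1.0)
        l = rng.standard_normal(5)
        assert np.allclose(sam_weights(l, cov), l / (l @ l))

    def test_unit_gain_for_random_psd(self, rng):
        cov = random_psd_cov(7, rng)
        l = rng.standard_normal(7)
        w = sam_weights(l, cov)
        assert abs(w @ l - 1.0) < 1e-8

    def test_unit_gain_across_a_whole_grid(self, rng):
        lf = make_leadfield(10, 12, seed=3)
        rec = SensorRecording(rng.standard_normal((4, 12, 500)), 208.33)
        cov = sensor_covariance(rec)
        bw = compute_weights(lf, cov)
        for v in range(10):
            l = lf.gains[v] @ bw.orientations[v]
            assert abs(bw.weights[v] @ l - 1.0) < 1e-8


class TestVirtualChannel:
    def test_scale_invariance_of_snr_units(self, rng):
        data = rng.standard_normal((3, 6, 800))
        rec1 = SensorRecording(data, 208.33)
        rec2 = SensorRecording(5.0 * data, 208.33)
        cov1, cov2 = sensor_covariance(rec1), sensor_covariance(rec2)
        lf = make_leadfield(1, 6, seed=0)
        u1 = optimal_orientation(lf.gains[0], cov1)
        w1 = sam_weights(lf.gains[0] @ u1, cov1)
        w2 = sam_weights(lf.gains[0] @ u1, cov2)
        s1 = virtual_channel(w1, cov1.sigma2_noise, rec1)
        s2 = virtual_channel(w2, cov2.sigma2_noise, rec2)
        assert np.allclose(s1.data, s2.data, rtol=1e-8)

    def test_epoch_structure_preserved(self, rng):
        rec = SensorRecording(rng.standard_normal((5, 4, 300)), 100.0)
        s = virtual_channel(np.ones(4), 1.0, rec)
        assert s.data.shape == (5, 300)

    def test_zero_noise_estimate_rejected(self, rng):
        rec = SensorRecording(rng.standard_normal((1, 4, 100)), 100.0)
        with pytest.raises(ValueError, match="noise"):
            virtual_channel(np.ones(4), 0.0, rec)


class TestSourceRecovery:
    def test_single_source_recovered_above_095(self):
        lf = make_leadfield(5, 24, seed=7)
        src = synth_meg_epochs(SpectralProfile(), 8, 5.0, 208.33, seed=11)
        rec = synth_sensor_data([src], lf, [2], noise_sd=0.002, seed=13)
        cov = sensor_covariance(rec)
        u = optimal_orientation(lf.gains[2], cov)
        w = sam_weights(lf.gains[2] @ u, cov)
        vc = virtual_channel(w, cov.sigma2_noise, rec)
        corr = np.corrcoef(vc.data.ravel(), src.data.ravel())[0, 1]
        assert abs(corr) > 0.95

    def test_noiseless_single_source_has_rank_one(self):
        lf = make_leadfield(3, 10, seed=1)
        src = synth_meg_epochs(SpectralProfile(), 2, 2.0, 208.33, seed=2)
        rec = synth_sensor_data([src], lf, [0], noise_sd=0.0, seed=3)
        x = rec.concatenated()
        s = np.linalg.svd(x, compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    def test_two_source_leakage_low_for_orthogonal_leadfields(self, rng):
        n_ch = 24
        gains = np.zeros((2, n_ch, 3))
        q, _ = np.linalg.qr(rng.standard_normal((n_ch, 6)))
        gains[0] = q[:, :3]
        gains[1] = q[:, 3:]
        from restdyn.signals import Leadfield

        lf = Leadfield(gains)
        s1 = synth_meg_epochs(SpectralProfile(), 6, 5.0, 208.33, seed=21)
        s2 = synth_meg_epochs(SpectralProfile(), 6, 5.0, 208.33, seed=22)
        rec = synth_sensor_data([s1, s2], lf, [0, 1], noise_sd=0.01, seed=23)
        cov = sensor_covariance(rec)
        u = optimal_orientation(lf.gains[0], cov)
        w = sam_weights(lf.gains[0] @ u, cov)
        vc = virtual_channel(w, cov.sigma2_noise, rec)
        leak = np.corrcoef(vc.data.ravel(), s2.data.ravel())[0, 1]
        assert abs(leak) < 0.2
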