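"""Coil-combination operator tests: sensitivity and noise-covariance
estimation, Roemer normalizations, sum-of-squares, phase correction, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coilcomb as cc
from coilcomb.combine import DEFAULT_PEAK_WINDOWS_PPM


def random_instance(seed, nch=3, nfid=32):
    """A random multi-channel voxel, sensitivity, and PD noise covariance."""
    rng = np.random.default_rng(seed)
    p = cc.MultiChannelFid(
        rng.standard_normal((nch, nfid)) + 1j * rng.standard_normal((nch, nfid)), 2e-4
    )
    b = cc.SensitivityVector(rng.standard_normal(nch) + 1j * rng.standard_normal(nch))
    a = rng.standard_normal((nch, nch)) + 1j * rng.standard_normal((nch, nch))
    R = cc.NoiseCovariance(a @ a.conj().T + nch * np.eye(nch))
    return p, b, R, rng


class TestEstimateSensitivity:
    def test_noise_free_estimate_proportional_to_b(self, fid31):
        b = cc.true_sensitivity(5)
        p = cc.synth_voxel(fid31, b, 0.0)
        est = cc.estimate_sensitivity(p, (2, 5))
        expected = b.values * fid31.samples[1:5].mean()
        np.testing.assert_allclose(est.values, expected, rtol=1e-12)
        assert est.provenance == cc.Provenance.SELF

    @pytest.mark.parametrize("point_range,n_used", [((2, 5), 4), ((1, 5), 5)])
    def test_index_ranges_are_one_based_inclusive(self, point_range, n_used):
        # FID crafted so the average reveals exactly which points were used
        data = np.zeros((1, 10), dtype=complex)
        data[0, : point_range[1]] = 1.0
        data[0, point_range[1] :] = 100.0  # would corrupt the mean if included
        p = cc.MultiChannelFid(data, 2e-4)
        est = cc.estimate_sensitivity(p, point_range)
        assert est.values[0] == pytest.approx((n_used * 1.0) / n_used)

    def test_invalid_ranges_rejected(self):
        p = cc.MultiChannelFid(np.ones((2, 8), dtype=complex), 2e-4)
        with pytest.raises(ValueError):
            cc.estimate_sensitivity(p, (3, 2))
        with pytest.raises(ValueError):
            cc.estimate_sensitivity(p, (1, 20))


class TestNoiseCovariance:
    def test_white_noise_estimate_close_to_2I(self):
        rng = np.random.default_rng(0)
        scan = rng.standard_normal((100_000, 4)) + 1j * rng.standard_normal((100_000, 4))
        R = cc.estimate_noise_covariance(scan)
        target = 2.0 * np.eye(4)
        assert np.linalg.norm(R.matrix - target) / np.linalg.norm(target) < 0.05

    def test_duplicated_channel_gives_equal_cross_and_diagonal_terms(self):
        rng = np.random.default_rng(1)
        ch = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        other = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        scan = np.stack([ch, ch, other], axis=1)
        R = cc.estimate_noise_covariance(scan)
        # jitter only touches the diagonal at ~1e-10 relative scale
        assert abs(R.matrix[0, 1] - R.matrix[0, 0]) <= 1e-8 * abs(R.matrix[0, 0])

    def test_zero_scan_is_an_error(self):
        with pytest.raises(ValueError, match="singular"):
            cc.estimate_noise_covariance(np.zeros((100, 3), dtype=complex))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            cc.estimate_noise_covariance(np.ones((3, 4), dtype=complex))

    def test_non_pd_matrix_rejected_by_type(self):
        with pytest.raises(ValueError, match="positive definite"):
            cc.NoiseCovariance(np.diag([1.0, 0.0]))


class TestRoemerUniformNoise:
    def test_single_channel_identity(self):
        p = cc.MultiChannelFid((np.arange(8) + 1j)[None, :], 2e-4)
        out = cc.roemer_combine(
            p, cc.SensitivityVector([1.0]), cc.NoiseCovariance(np.eye(1)), scale=2.0
        )
        np.testing.assert_allclose(out.fid, 2.0 * p.data[0])

    def test_sixteen_channel_gain_is_four(self, fid31):
        # |b_k| = 1, R = I: combined peak is sqrt(16) = 4 times the true signal
        b = cc.true_sensitivity(16)
        p = cc.synth_voxel(fid31, b, 0.0)
        out = cc.roemer_combine(p, b)
        np.testing.assert_allclose(out.fid, 4.0 * fid31.samples, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matched_filter_beats_random_weights(self, seed):
        # brute-force oracle: analytic SNR |w^H b| / sqrt(w^H R w) of the
        # Roemer weighting vs 10^4 random unit weight vectors
        _, b, R, rng = random_instance(seed)
        w_opt = np.linalg.solve(R.matrix, b.values)
        snr_opt = abs(w_opt.conj() @ b.values) / np.sqrt(
            np.real(w_opt.conj() @ R.matrix @ w_opt)
        )
        w_rand = rng.standard_normal((10_000, 3)) + 1j * rng.standard_normal((10_000, 3))
        num = np.abs(w_rand.conj() @ b.values)
        den = np.sqrt(np.real(np.einsum("ni,ik,nk->n", w_rand.conj(), R.matrix, w_rand)))
        assert snr_opt >= (num / den).max() - 1e-12

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_whitening_equivalence(self, seed):
        import scipy.linalg

        p, b, R, _ = random_instance(seed)
        w = np.linalg.inv(scipy.linalg.sqrtm(R.matrix).astype(complex))
        out = cc.roemer_combine(p, b, R)
        white = cc.roemer_combine(
            cc.MultiChannelFid(w @ p.data, p.dwell_s),
            cc.SensitivityVector(w @ b.values),
            cc.NoiseCovariance(np.eye(3)),
        )
        assert np.linalg.norm(out.fid - white.fid) <= 1e-8 * np.linalg.norm(out.fid)

    @settings(derandomize=True, max_examples=20)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=0.01, max_value=10),
    )
    def test_scale_invariance_up_to_unit_rotation(self, seed, angle, mag):
        p, b, R, _ = random_instance(seed)
        c = mag * np.exp(1j * angle)
        out1 = cc.roemer_combine(p, b, R)
        out2 = cc.roemer_combine(p, cc.SensitivityVector(c * b.values), R)
        np.testing.assert_allclose(np.abs(out1.fid), np.abs(out2.fid), rtol=1e-8)

    def test_uniform_noise_contract_white(self):
        # MC-pathway convention: white noise of per-component std sigma
        # combined with R = I gives output noise of the same sigma
        rng = np.random.default_rng(3)
        sigma, nch, n = 0.7, 4, 10_000
        p = cc.MultiChannelFid(
            sigma * (rng.standard_normal((nch, n)) + 1j * rng.standard_normal((nch, n))), 2e-4
        )
        b = cc.SensitivityVector(rng.standard_normal(nch) + 1j * rng.standard_normal(nch))
        out = cc.roemer_combine(p, b)
        assert np.std(out.fid.real) == pytest.approx(sigma, rel=0.05)

    def test_uniform_noise_contract_correlated(self):
        # with R equal to the true complex covariance the combined output has
        # unit complex variance (1/sqrt(2) per component), for any b
        rng = np.random.default_rng(3)
        nch, n = 4, 10_000
        a = rng.standard_normal((nch, nch)) + 1j * rng.standard_normal((nch, nch))
        chol = np.linalg.cholesky(a @ a.conj().T + nch * np.eye(nch))
        white = rng.standard_normal((nch, n)) + 1j * rng.standard_normal((nch, n))
        p = cc.MultiChannelFid(chol @ white, 2e-4)
        R = cc.NoiseCovariance(2.0 * (chol @ chol.conj().T))  # complex variance 2
        for seed in range(3):
            r2 = np.random.default_rng(seed)
            b = cc.SensitivityVector(r2.standard_normal(nch) + 1j * r2.standard_normal(nch))
            out = cc.roemer_combine(p, b, R)
            assert np.std(out.fid.real) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_dimension_mismatch_rejected(self):
        p = cc.MultiChannelFid(np.ones((2, 8), dtype=complex), 2e-4)
        with pytest.raises(ValueError):
            cc.roemer_combine(p, cc.SensitivityVector([1.0, 1.0, 1.0]))


class TestRoemerUniformSensitivity:
    def test_flattening_recovers_signal_regardless_of_norm(self, fid31):
        rng = np.random.default_rng(0)
        b = cc.SensitivityVector(5.0 * (rng.standard_normal(6) + 1j * rng.standard_normal(6)))
        p = cc.MultiChannelFid(np.outer(b.values, fid31.samples), fid31.dwell_s)
        out = cc.roemer_combine_uniform_sensitivity(p, b)
        np.testing.assert_allclose(out.fid, fid31.samples, atol=1e-10)

    def test_single_channel_unit_gain(self):
        p = cc.MultiChannelFid(2.0 * (np.arange(8) + 0j)[None, :], 2e-4)
        out = cc.roemer_combine_uniform_sensitivity(p, cc.SensitivityVector([2.0]))
        np.testing.assert_allclose(out.fid, np.arange(8))

    @pytest.mark.parametrize("seed", range(5))
    def test_differs_from_uniform_noise_by_sqrt_quad(self, seed):
        p, b, R, _ = random_instance(seed)
        un = cc.roemer_combine(p, b, R)
        us = cc.roemer_combine_uniform_sensitivity(p, b, R)
        quad = np.real(b.values.conj() @ np.linalg.solve(R.matrix, b.values))
        np.testing.assert_allclose(un.fid, us.fid * np.sqrt(quad), rtol=1e-10)

    def test_vanishing_sensitivity_flagged_missing(self):
        p = cc.MultiChannelFid(np.ones((2, 8), dtype=complex), 2e-4)
        tiny = cc.SensitivityVector([1e-9, 1e-9])
        out = cc.roemer_combine_uniform_sensitivity(p, tiny, norm_reference=1.0)
        assert out.missing and np.all(np.isnan(out.fid.real))


class TestSumOfSquares:
    def test_single_channel_is_magnitude(self):
        p = cc.MultiChannelFid((np.arange(8) - 4j)[None, :], 2e-4)
        np.testing.assert_allclose(cc.sum_of_squares(p), np.abs(p.data[0]))

    def test_unit_sensitivities_give_sqrt_nch_gain(self, fid31):
        b = cc.true_sensitivity(16)
        p = cc.synth_voxel(fid31, b, 0.0)
        np.testing.assert_allclose(cc.sum_of_squares(p), 4.0 * np.abs(fid31.samples), atol=1e-10)

    def test_pure_noise_noncentral_floor_matches_chi_mean(self):
        from scipy.special import gamma

        rng = np.random.default_rng(0)
        nch, n = 8, 10_000
        p = cc.MultiChannelFid(
            rng.standard_normal((nch, n)) + 1j * rng.standard_normal((nch, n)), 2e-4
        )
        out = cc.sum_of_squares(p)
        k = 2 * nch  # real degrees of freedom
        chi_mean = np.sqrt(2.0) * gamma((k + 1) / 2) / gamma(k / 2)
        assert out.min() > 0
        assert out.mean() == pytest.approx(chi_mean, rel=0.02)


class TestPhaseCorrect:
    @staticmethod
    def _spec(model, rotate=None):
        s = cc.make_spectrum(model)
        combined = cc.CombinedSpectrum(
            np.fft.ifft(np.fft.ifftshift(s if rotate is None else s * rotate)),
            model.dwell_s,
            model.f0_mhz,
        )
        return s, combined

    def test_already_real_spectrum_needs_no_correction(self, model31):
        _, combined = self._spec(model31)
        out = cc.phase_correct(combined, mode="both")
        assert min(out.phase0, 2 * np.pi - out.phase0) < 0.05
        assert out.phase1 == 0.0

    def test_zero_order_rotation_recovered_equivariantly(self, model31):
        # the recovered phi0 shifts by exactly the injected rotation (the
        # absolute argmax carries a small dispersion-tail offset)
        s, base = self._spec(model31)
        _, combined = self._spec(model31, rotate=np.exp(1j * 0.7))
        phi_base = cc.phase_correct(base, mode="zero").phase0
        out = cc.phase_correct(combined, mode="zero")
        assert np.angle(np.exp(1j * (out.phase0 - phi_base + 0.7))) == pytest.approx(
            0.0, abs=1e-4
        )
        assert np.real(out.spectrum).max() == pytest.approx(np.real(s).max(), rel=1e-4)

    def test_linear_phase_rotation_height_restored(self, model31):
        # the reference-peak height objective is flat in the first-order term
        # (any ramp is absorbed by phi0 at the peak sample), so the
        # identifiable content is the restored peak height and phi0
        ppm = model31.ppm_axis
        f = (ppm - model31.carrier_ppm) * model31.f0_mhz
        s, combined = self._spec(model31, rotate=np.exp(1j * (0.7 + 0.002 * f)))
        out = cc.phase_correct(combined, mode="both")
        win = (ppm >= -1) & (ppm <= 1)
        assert np.real(out.spectrum)[win].max() == pytest.approx(
            np.real(s)[win].max(), rel=1e-3
        )
        assert np.angle(np.exp(1j * (out.phase0 + 0.7))) == pytest.approx(0.0, abs=0.05)

    def test_pure_noise_returns_finite_low_confidence(self):
        rng = np.random.default_rng(5)
        combined = cc.CombinedSpectrum(
            rng.standard_normal(256) + 1j * rng.standard_normal(256), 2e-4, 120.6
        )
        out = cc.phase_correct(combined, mode="both")
        assert np.isfinite(out.phase0) and np.isfinite(out.phase1)
        assert out.low_confidence

    def test_empty_window_is_an_error(self, model31):
        _, combined = self._spec(model31)
        with pytest.raises(ValueError, match="window"):
            cc.phase_correct(combined, reference_window=(100.0, 101.0))


class TestSnrMetrics:
    def test_constructed_snr_close_to_a_over_sigma(self):
        # long spectrum (4096 points) so the noise-window std is well estimated
        model31 = cc.default_model_31p(n_points=4096)
        rng = np.random.default_rng(0)
        s = cc.make_spectrum(model31)
        noise = 0.05 * rng.standard_normal(s.size)
        combined = cc.CombinedSpectrum(
            np.fft.ifft(np.fft.ifftshift(s + noise)), model31.dwell_s, model31.f0_mhz
        )
        m = cc.snr_metrics(combined)
        assert m.snr["PCr"] == pytest.approx(1.0 / 0.05, rel=0.10)

    def test_noise_window_must_be_disjoint(self, model31):
        s = cc.make_spectrum(model31)
        combined = cc.CombinedSpectrum(
            np.fft.ifft(np.fft.ifftshift(s)), model31.dwell_s, model31.f0_mhz
        )
        with pytest.raises(ValueError, match="overlaps"):
            cc.snr_metrics(combined, noise_window=(10, 20), peak_windows={"x": (19, 21)})

    def test_zero_spectrum_flags_missing_not_infinite(self, model31):
        combined = cc.CombinedSpectrum(np.zeros(256), model31.dwell_s, model31.f0_mhz)
        m = cc.snr_metrics(combined)
        assert m.noise_std == 0.0
        assert all(np.isnan(v) for v in m.snr.values())

    def test_default_windows_sit_on_pcr_and_aatp(self):
        assert DEFAULT_PEAK_WINDOWS_PPM["PCr"] == (-1.0, 1.0)
        assert DEFAULT_PEAK_WINDOWS_PPM["aATP"][0] < -7.52 < DEFAULT_PEAK_WINDOWS_PPM["aATP"][1]
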