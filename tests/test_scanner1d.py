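import numpy as np
import pytest

from petkin.scanner1d import (Scanner1D, Scanner1DConfig, default_attenuation,
                              select_bandwidth)


@pytest.fixture(scope="module")
def scanner():
    return Scanner1D(Scanner1DConfig(tau=1.0e6, seed=0))


@pytest.fixture(scope="module")
def smooth_source():
    x = np.linspace(0, 1, 128)
    return 0.15 + np.clip(1 - np.abs(x - 0.5) * 4, 0, 1)


class TestConfig:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            Scanner1DConfig(beta=0.0)
        with pytest.raises(ValueError):
            Scanner1DConfig(tau=-1)
        with pytest.raises(ValueError):
            Scanner1DConfig(attenuation=np.zeros(128))

    def test_kernel_spectrum_dc_is_one(self):
        cfg = Scanner1DConfig()
        kappa = cfg.kernel_spectrum
        assert kappa[0] == 1.0
        nu = np.fft.fftfreq(128) * 128
        np.testing.assert_allclose(kappa[1:], np.abs(nu[1:]) ** -1.35)

    def test_default_attenuation_range(self):
        a = default_attenuation()
        assert np.all((a >= 0.5) & (a <= 1.0))


class TestProjection:
    def test_dc_preserved_for_constant_source(self, scanner):
        """kappa_0 = 1: a constant source projects to a scaled attenuation."""
        src = np.full((1, 128), 2.0)
        q = scanner.project(src, np.array([1.0]), scale=1.0)
        np.testing.assert_allclose(q[0], 2.0 * scanner.cfg.attenuation,
                                   rtol=1e-12)

    def test_matches_spatial_domain_oracle(self, scanner, smooth_source):
        """FFT projection equals a direct O(N^2) circular convolution."""
        kappa = scanner.cfg.kernel_spectrum
        kernel = np.real(np.fft.ifft(kappa))  # spatial kernel
        n = 128
        oracle = np.array([
            sum(kernel[(i - j) % n] * smooth_source[j] for j in range(n))
            for i in range(n)
        ])
        q = scanner.project(smooth_source[None], np.array([1.0]), scale=1.0)
        np.testing.assert_allclose(q[0], scanner.cfg.attenuation * oracle,
                                   atol=1e-10)

    def test_study_scaling_hits_dose(self, scanner, smooth_source):
        frames = np.stack([smooth_source, 2 * smooth_source])
        dur = np.array([0.5, 1.0])
        scale = scanner.study_scale(frames, dur)
        expected = scanner.project(frames, dur, scale)
        assert expected.sum() == pytest.approx(scanner.cfg.tau)

    def test_negative_source_rejected(self, scanner):
        with pytest.raises(ValueError):
            scanner.project(-np.ones((1, 128)), np.array([1.0]), scale=1.0)


class TestSampling:
    def test_zero_expectation_gives_zero_counts(self, scanner):
        y = scanner.sample_counts(np.zeros((3, 128)), rng=1)
        assert np.all(y == 0)

    def test_poisson_mean_and_variance(self, scanner):
        """Mean and variance of samples at expectation 5 match Poisson."""
        rng = np.random.default_rng(2)
        y = scanner.sample_counts(np.full((10000,), 5.0), rng=rng)
        se = np.sqrt(5.0 / 10000)
        assert abs(y.mean() - 5.0) < 3 * se
        # var of sample variance for Poisson(5): (mu + 2 mu^2)/n approx
        se_var = np.sqrt((5 + 2 * 25) / 10000)
        assert abs(y.var(ddof=1) - 5.0) < 3 * se_var

    def test_total_counts_near_dose(self, scanner, smooth_source):
        frames = np.tile(smooth_source, (5, 1))
        dur = np.ones(5)
        expected = scanner.project(frames, dur)
        y = scanner.sample_counts(expected, rng=3)
        assert abs(y.sum() - scanner.cfg.tau) < 4 * np.sqrt(scanner.cfg.tau)

    def test_seed_reproducibility(self, scanner, smooth_source):
        expected = scanner.project(smooth_source[None], np.array([1.0]))
        y1 = scanner.sample_counts(expected, rng=7)
        y2 = scanner.sample_counts(expected, rng=7)
        np.testing.assert_array_equal(y1, y2)

    def test_negative_expectation_rejected(self, scanner):
        with pytest.raises(ValueError):
            scanner.sample_counts(np.array([-1.0]))


class TestFBP:
    def test_noiseless_round_trip_exact(self, scanner, smooth_source):
        """Reconstructing the exact expectations recovers the source."""
        dur = np.array([1.0])
        scale = scanner.study_scale(smooth_source[None], dur)
        expected = scanner.project(smooth_source[None], dur, scale)
        z = scanner.recon_fbp(expected, dur, scale)
        np.testing.assert_allclose(z[0], smooth_source, atol=1e-10)

    def test_zero_bandwidth_is_identity_smoother(self, scanner, smooth_source):
        dur = np.array([1.0])
        scale = scanner.study_scale(smooth_source[None], dur)
        y = scanner.sample_counts(scanner.project(smooth_source[None], dur, scale),
                                  rng=5).astype(float)
        raw = scanner.recon_fbp(y, dur, scale, bandwidth=0.0)
        again = scanner.recon_fbp(y, dur, scale, bandwidth=0.0)
        np.testing.assert_array_equal(raw, again)

    def test_mse_decreases_with_dose(self, smooth_source):
        """Quadrupling the dose strictly reduces replicate-average voxel MSE."""
        dur = np.array([1.0])
        mses = []
        for tau in (2.5e5, 1.0e6):
            sc = Scanner1D(Scanner1DConfig(tau=tau))
            scale = sc.study_scale(smooth_source[None], dur)
            expected = np.clip(sc.project(smooth_source[None], dur, scale), 0, None)
            rng = np.random.default_rng(9)
            err = 0.0
            for _ in range(200):
                y = rng.poisson(expected).astype(float)
                z = sc.recon_fbp(y, dur, scale, bandwidth=1.0)
                err += np.mean((z[0] - smooth_source) ** 2) / 200
            mses.append(err)
        assert mses[1] < mses[0]


class TestML:
    def test_zero_counts_give_zero_image(self, scanner):
        dur = np.array([1.0])
        lam = scanner.recon_ml(np.zeros((1, 128)), dur, 1.0)
        np.testing.assert_allclose(lam, 0.0)

    def test_noiseless_fixed_point(self, scanner, smooth_source):
        """On exact data from a positive source, ML recovers it closely."""
        dur = np.array([1.0])
        scale = scanner.study_scale(smooth_source[None], dur)
        expected = scanner.project(smooth_source[None], dur, scale)
        lam, info = scanner.recon_ml(expected, dur, scale, return_info=True)
        assert info[0]["converged"]
        assert np.max(np.abs(lam[0] - smooth_source)) < 0.01 * smooth_source.max()

    def test_nonnegativity_and_deviance_monotone(self, scanner, smooth_source):
        from petkin.scanner1d import _poisson_deviance, _poisson_irls
        dur = np.array([1.0])
        scale = scanner.study_scale(smooth_source[None], dur)
        expected = np.clip(scanner.project(smooth_source[None], dur, scale), 0, None)
        rng = np.random.default_rng(21)
        kernel_matrix = scanner.blur(np.eye(128))
        A = (scale * dur[0]) * (scanner.cfg.attenuation[:, None] * kernel_matrix.T)
        for _ in range(5):
            y = rng.poisson(expected[0]).astype(float)
            # track deviance across iterations manually
            lam = np.full(128, y.sum() / A.sum())
            devs = [_poisson_deviance(y, A @ lam)]
            from scipy.optimize import nnls
            for _ in range(15):
                mu = np.maximum(A @ lam, 1e-8)
                sw = 1 / np.sqrt(mu)
                lam_new, _ = nnls(A * sw[:, None], y * sw)
                t = 1.0
                while _poisson_deviance(y, A @ (lam + t * (lam_new - lam))) > devs[-1] + 1e-12:
                    t *= 0.5
                    if t < 1e-6:
                        break
                lam = lam + t * (lam_new - lam)
                devs.append(_poisson_deviance(y, A @ lam))
            assert np.all(np.diff(devs) <= 1e-9)
            assert np.all(lam >= 0)
            lam_pkg, _ = _poisson_irls(A, y, 200, 1e-8)
            assert np.all(lam_pkg >= 0)

    def test_forward_total_matches_observed_counts(self, scanner, smooth_source):
        """At the ML optimum the forward-projected total equals observed total."""
        dur = np.array([1.0])
        scale = scanner.study_scale(smooth_source[None], dur)
        expected = np.clip(scanner.project(smooth_source[None], dur, scale), 0, None)
        y = scanner.sample_counts(expected, rng=12).astype(float)
        lam = scanner.recon_ml(y, dur, scale)
        fwd = scanner.project(lam, dur, scale)
        assert abs(fwd.sum() - y.sum()) / y.sum() < 1e-3


class TestBandwidthSelection:
    def test_zero_noise_selects_zero(self):
        truth = np.sin(np.linspace(0, 2 * np.pi, 128)) + 2.0
        recs = np.tile(truth, (4, 1))
        h, risks = select_bandwidth(recs, truth, np.array([0.0, 1.0, 2.0]))
        assert h == 0.0

    def test_flat_truth_selects_largest(self):
        rng = np.random.default_rng(4)
        truth = np.full(128, 3.0)
        recs = truth + rng.normal(0, 1.0, (20, 128))
        grid = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        h, risks = select_bandwidth(recs, truth, grid)
        assert h == grid[-1]

    def test_argmin_property(self):
        rng = np.random.default_rng(5)
        truth = np.cos(np.linspace(0, 4 * np.pi, 128)) + 2
        recs = truth + rng.normal(0, 0.5, (10, 128))
        grid = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        h, risks = select_bandwidth(recs, truth, grid)
        assert risks[list(grid).index(h)] == risks.min()

    def test_practice_mode_agrees_with_truth_mode(self):
        """Replicate-pair risk picks a bandwidth near the truth-based one."""
        rng = np.random.default_rng(6)
        truth = np.cos(np.linspace(0, 4 * np.pi, 128)) + 2
        recs = truth + rng.normal(0, 0.7, (40, 128))
        grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0])
        h_truth, _ = select_bandwidth(recs, truth, grid)
        h_blind, _ = select_bandwidth(recs, None, grid)
        assert abs(np.searchsorted(grid, h_blind)
                   - np.searchsorted(grid, h_truth)) <= 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.ones((2, 8)), None, np.array([]))
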