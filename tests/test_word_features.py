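import numpy as np
import pytest

from voicelevel.word_features import (
    WaveletConfig,
    gaussian_wavelet,
    higuchi_fd,
    largest_lyapunov,
    reconstruct_phase_space,
    wavelet_coefficients,
    wavelet_energy,
)


class TestPhaseSpace:
    def test_basic_embedding(self):
        ps = reconstruct_phase_space(np.array([1.0, 2, 3, 4]), delay=1, dimension=2)
        assert np.array_equal(ps.points, [[1, 2], [2, 3], [3, 4]])

    def test_point_count_formula(self):
        ps = reconstruct_phase_space(np.arange(10.0), delay=2, dimension=2)
        assert ps.points.shape == (8, 2)

    def test_constant_series_collapses(self):
        ps = reconstruct_phase_space(np.full(20, 2.0), delay=3, dimension=3)
        assert np.allclose(ps.points, ps.points[0])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            reconstruct_phase_space(np.arange(5.0), delay=3, dimension=3)


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0), kmax=8) == pytest.approx(1.0, abs=0.02)

    def test_white_noise_dimension_two(self):
        ds = [higuchi_fd(np.random.default_rng(s).standard_normal(5000)) for s in range(20)]
        assert np.mean(ds) == pytest.approx(2.0, abs=0.1)

    def test_fine_sine_dimension_one(self):
        x = np.sin(2 * np.pi * 4 * np.linspace(0, 1, 5000))
        assert higuchi_fd(x) == pytest.approx(1.0, abs=0.1)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(2000)
        assert higuchi_fd(3.0 * x - 7.0) == pytest.approx(higuchi_fd(x), rel=1e-9)

    def test_complexity_ordering_sine_pink_white(self):
        """D grows from smooth sine through 1/f noise to white noise."""
        results = []
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 4000
            sine = np.sin(2 * np.pi * 4 * np.linspace(0, 1, n))
            white = rng.standard_normal(n)
            spec = np.fft.rfft(rng.standard_normal(n))
            freqs = np.fft.rfftfreq(n)
            freqs[0] = freqs[1]
            pink = np.fft.irfft(spec / np.sqrt(freqs), n)
            results.append((higuchi_fd(sine), higuchi_fd(pink), higuchi_fd(white)))
        d_sine, d_pink, d_white = np.mean(results, axis=0)
        assert d_sine < d_pink < d_white

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(100.0), kmax=1)


def logistic_orbit(n, x0=0.3):
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x


class TestLyapunov:
    def test_logistic_map_ln2(self):
        x = logistic_orbit(2000)
        lam = largest_lyapunov(x, delay=1, dimension=2, fit_range=8)
        # independent oracle: mean log |f'(x)| along the same orbit
        oracle = np.mean(np.log(np.abs(4.0 - 8.0 * x)))
        assert oracle == pytest.approx(np.log(2.0), abs=0.01)
        assert lam == pytest.approx(np.log(2.0), abs=0.05)

    def test_pure_sine_near_zero(self):
        x = np.sin(2 * np.pi * 10 * np.linspace(0, 1, 3000))
        assert largest_lyapunov(x) <= 0.02

    def test_damped_oscillation_negative(self):
        n = 3000
        x = np.exp(-np.linspace(0, 12, n)) * np.sin(2 * np.pi * 30 * np.linspace(0, 1, n))
        assert largest_lyapunov(x) < 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            largest_lyapunov(np.sin(np.arange(50.0)), delay=1, dimension=5)


def direct_wavelet_oracle(x, j, cfg):
    """Naive O(n*|k|) summation of the coefficient definition (no FFT)."""
    scale = cfg.a0**j
    half = int(np.floor(cfg.support * scale))
    t_rel = np.arange(-half, half + 1)
    u, psi = gaussian_wavelet(cfg.order, cfg.support)
    psi_t = np.interp(t_rel / scale, u, psi)
    m = psi_t.size
    step = max(1, int(round(cfg.b0 * scale)))
    coeffs = []
    for start in range(0, x.size - m + 1, step):
        acc = 0.0
        for i in range(m):
            acc += x[start + i] * psi_t[i]
        coeffs.append(acc * scale ** (-0.5))
    return np.asarray(coeffs)


class TestWaveletEnergy:
    CFG = WaveletConfig(scales=(3, 4, 5))  # small scales keep the oracle fast

    def test_zero_signal_zero_energy(self):
        e = wavelet_energy(np.zeros(2000), self.CFG)
        assert all(v == 0.0 for v in e.values())

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(2000)
        e1 = wavelet_energy(x, self.CFG)
        e2 = wavelet_energy(3.0 * x, self.CFG)
        for j in self.CFG.scales:
            assert e2[j] == pytest.approx(9.0 * e1[j], rel=1e-9)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(1500)
            for j in self.CFG.scales:
                prod = wavelet_coefficients(x, j, self.CFG)
                ref = direct_wavelet_oracle(x, j, self.CFG)
                assert prod == pytest.approx(ref, rel=1e-6)

    def test_default_scales_are_dyadic_789(self):
        cfg = WaveletConfig()
        assert cfg.scales == (7, 8, 9) and cfg.a0 == 2.0 and cfg.order == 5

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError):
            wavelet_energy(np.ones(100), WaveletConfig(scales=(9,)))

    def test_scale_separates_low_and_high_frequency(self):
        """A low-frequency tone concentrates energy at coarser scales than a
        high-frequency tone (scales 3-5 at unit sampling)."""
        n = 4000
        t = np.arange(n)
        lo = np.sin(2 * np.pi * 0.005 * t)
        hi = np.sin(2 * np.pi * 0.05 * t)
        e_lo = wavelet_energy(lo, self.CFG)
        e_hi = wavelet_energy(hi, self.CFG)
        assert e_lo[5] / (e_lo[3] + 1e-12) > e_hi[5] / (e_hi[3] + 1e-12)
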