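"""Histogram, FFT-KDE, ECF shrinkage and density inversion."""

import numpy as np
import pytest
from scipy.stats import norm

from steptrace.density import (ECFSpectrum, average_power,
                               dominant_periodicity, ecf, histogram_density,
                               kde_fft, reconstruct_density, shrink,
                               wrap_angles, MAD_GAUSSIAN_FACTOR)


class TestHistogram:
    def test_single_sample_single_bin(self):
        est = histogram_density([0.3], 1, range=(0.0, 1.0))
        assert est.density[0] == pytest.approx(1.0)
        assert est.integral() == pytest.approx(1.0)

    def test_uniform_data_flat_histogram(self, rng):
        x = rng.random(10 ** 6)
        est = histogram_density(x, 10, range=(0.0, 1.0))
        assert np.allclose(est.density, 1.0, rtol=0.01)

    def test_integral_is_one_for_arbitrary_data(self, rng):
        for n_bins in (1, 7, 40):
            est = histogram_density(rng.normal(0, 3, 5000), n_bins)
            assert est.integral() == pytest.approx(1.0, abs=1e-6)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            histogram_density([], 5)


class TestKDE:
    def test_single_delta_reproduces_gaussian_kernel(self):
        h = 0.5
        est = kde_fft(np.array([0.0]), h, grid_size=2001)
        expected = norm.pdf(est.grid, 0.0, h)
        assert np.allclose(est.density, expected, atol=1e-6)

    def test_fft_matches_direct_sum_oracle(self, rng):
        # both routes evaluate the KDE of the grid-snapped delta train;
        # FFT convolution must agree with brute-force summation
        x = rng.normal(0, 1, 100)
        h = 0.3
        est = kde_fft(x, h, grid_size=512)
        grid = est.grid
        dx = grid[1] - grid[0]
        snapped = grid[np.clip(np.rint((x - grid[0]) / dx).astype(int),
                               0, grid.size - 1)]
        direct = norm.pdf(grid[:, None], snapped[None, :], h).mean(axis=1)
        assert np.allclose(est.density, direct, atol=1e-8)

    def test_integral_close_to_one(self, rng):
        est = kde_fft(rng.normal(0, 2, 2000), 0.4, grid_size=2048)
        assert est.integral() == pytest.approx(1.0, abs=1e-6)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_fft([1.0], 0.0)


class TestECF:
    def test_all_angles_zero_gives_unit_coefficients(self):
        spec = ecf(np.zeros(100), F_max=10)
        assert np.allclose(spec.coeffs, 1.0)

    def test_equispaced_comb_identity(self):
        # N samples over K equispaced angles: |P(K)| = 1 and P vanishes
        # off multiples of K (geometric sum)
        K = 13
        angles = np.tile(2 * np.pi * np.arange(K) / K, 40)
        spec = ecf(angles, F_max=3 * K)
        mags = np.abs(spec.coeffs)
        for f in range(1, 3 * K + 1):
            if f % K == 0:
                assert mags[f - 1] == pytest.approx(1.0, abs=1e-12)
            else:
                assert mags[f - 1] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_have_1_over_n_power(self, rng):
        N = 10 ** 4
        power = []
        for _ in range(30):
            spec = ecf(rng.uniform(0, 2 * np.pi, N), F_max=50)
            power.append(np.mean(np.abs(spec.coeffs) ** 2))
        assert np.mean(power) == pytest.approx(1.0 / N, rel=0.1)

    def test_wrap_invariance(self, rng):
        th = rng.uniform(0, 30 * np.pi, 500)  # unwrapped, many turns
        a = ecf(th, F_max=20).coeffs
        b = ecf(wrap_angles(th), F_max=20).coeffs
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            ecf(np.array([]), 5)


class TestShrinkage:
    def comb_spectrum(self, K=26, F=100, n=10 ** 4):
        angles = np.tile(2 * np.pi * np.arange(K) / K, n // K)
        return ecf(angles, F_max=F)

    def test_noiseless_comb_keeps_only_multiples(self):
        res = shrink(self.comb_spectrum(), mode="mad")
        assert set(res.kept_freqs) == {26, 52, 78}

    def test_pure_noise_survival_matches_rayleigh_tail(self):
        # under uniform angles the magnitudes are Rayleigh(1/sqrt(2N));
        # the threshold lands near 2x the component scale, so the
        # per-coefficient survival rate should match the analytic tail
        # exp(-lambda^2 * N) and every survivor stays at the noise floor
        N = 10 ** 4
        surv_frac, tail_pred = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spec = ecf(rng.uniform(0, 2 * np.pi, N), F_max=100)
            res = shrink(spec, mode="mad")
            surv_frac.append(len(res.kept_freqs) / 100)
            tail_pred.append(np.exp(-res.lam ** 2 * N))
            surviving = np.abs(res.shrunk_coeffs)
            assert np.all(surviving < 10.0 / np.sqrt(N))
        assert np.mean(surv_frac) == pytest.approx(np.mean(tail_pred),
                                                   abs=0.05)
        assert np.mean(surv_frac) < 0.3

    def test_mad_and_gaussian_scales_agree_on_clean_magnitudes(self, rng):
        # on outlier-free (near-)Rayleigh magnitudes the two zeta
        # estimates agree within a loose factor; on magnitudes with a few
        # large signal coefficients MAD stays small while std inflates
        mags = np.abs(rng.normal(0, 0.01, 100) + 1j * rng.normal(0, 0.01, 100))
        spec = ECFSpectrum(np.arange(1, 101), mags.astype(complex), 100)
        g = shrink(spec, mode="gaussian")
        m = shrink(spec, mode="mad")
        assert m.zeta == pytest.approx(g.zeta, rel=0.5)
        spiked = mags.copy()
        spiked[[25, 51]] = 0.9
        spec2 = ECFSpectrum(np.arange(1, 101), spiked.astype(complex), 100)
        assert (shrink(spec2, "mad").zeta
                < 0.5 * shrink(spec2, "gaussian").zeta)

    def test_mad_factor_is_gaussian_consistent(self):
        assert MAD_GAUSSIAN_FACTOR == pytest.approx(
            1.0 / norm.ppf(0.75), abs=1e-3)

    def test_shrinkage_idempotent(self):
        spec = self.comb_spectrum()
        once = shrink(spec, mode="mad")
        again = shrink(ECFSpectrum(once.freqs, once.shrunk_coeffs,
                                   spec.n_samples), mode="mad")
        # already-kept coefficients dominate; nothing new appears
        assert set(again.kept_freqs) <= set(once.kept_freqs)

    def test_average_power_pools_traces(self, rng):
        specs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            angles = np.tile(2 * np.pi * np.arange(10) / 10, 100)
            angles += r.normal(0, 0.05, angles.size)
            specs.append(ecf(angles, F_max=40))
        pooled = average_power(specs)
        res = shrink(pooled, mode="mad")
        assert dominant_periodicity(res) == 10


class TestReconstruction:
    def test_all_zero_coefficients_give_uniform_density(self):
        from steptrace.density import ShrinkageResult

        res = ShrinkageResult(np.arange(1, 51), np.zeros(50, dtype=complex),
                              0.01, 0.003, "mad", all_shrunk=True)
        dens = reconstruct_density(res, grid_size=256)
        assert np.allclose(dens.density, 1.0 / (2 * np.pi), atol=1e-12)
        assert dens.integral() == pytest.approx(1.0, abs=1e-9)

    def test_comb_reconstruction_has_K_equal_maxima(self):
        K = 8
        angles = np.tile(2 * np.pi * np.arange(K) / K, 500)
        res = shrink(ecf(angles, F_max=50), mode="mad")
        dens = reconstruct_density(res, grid_size=K * 64)
        d = dens.density
        peaks = [i for i in range(d.size)
                 if d[i] >= d[i - 1] and d[i] > d[(i + 1) % d.size]
                 and d[i] > 1.5 / (2 * np.pi)]
        assert len(peaks) == K
        peak_angles = np.sort(dens.grid[peaks])
        assert np.allclose(peak_angles, 2 * np.pi * np.arange(K) / K,
                           atol=2 * np.pi / (K * 64) + 1e-9)

    def test_integral_one_after_clipping(self):
        res = shrink(self_spec(), mode="mad")
        dens = reconstruct_density(res)
        assert dens.integral() == pytest.approx(1.0, abs=1e-6)


def self_spec():
    angles = np.tile(2 * np.pi * np.arange(26) / 26, 400)
    return ecf(angles, F_max=100)


class TestDominantPeriodicity:
    def test_comb_returns_K(self):
        res = shrink(self_spec(), mode="mad")
        assert dominant_periodicity(res) == 26

    def test_empty_survivor_set_returns_zero(self):
        from steptrace.density import ShrinkageResult

        res = ShrinkageResult(np.arange(1, 21), np.zeros(20, dtype=complex),
                              0.01, 0.003, "mad", all_shrunk=True)
        assert dominant_periodicity(res) == 0
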