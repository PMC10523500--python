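"""Fourier/lattice theory of translation-symmetric codes."""

import math

import numpy as np
import pytest
from scipy.linalg import circulant

import popdim as P
from popdim.translation import TruncationError, unit_ball_volume


class TestCirculantEigenvalues:
    def test_delta_and_constant_profiles(self):
        delta = P.CorrelationProfile(np.r_[1.0, np.zeros(7)])
        assert np.allclose(P.circulant_eigenvalues(delta).values, 1.0)
        const = P.CorrelationProfile(np.ones(8))
        vals = P.circulant_eigenvalues(const).values
        assert np.allclose(vals, np.r_[8.0, np.zeros(7)])

    @pytest.mark.parametrize("sigma", [0.075, 0.1, 0.15, 0.2])
    @pytest.mark.parametrize("N", [16, 50, 64])
    def test_fft_equals_dense_eigendecomposition(self, sigma, N):
        # exact identity, including non-positive-definite wide-tuning profiles
        prof = P.gaussian_profile(sigma, N)
        fft = P.circulant_eigenvalues(prof).values
        dense = np.sort(np.linalg.eigvalsh(circulant(prof.samples)))[::-1]
        assert np.allclose(fft, dense, rtol=1e-8, atol=1e-10 * dense[0])

    def test_matches_gaussian_form_for_narrow_tuning(self):
        # the Fourier-Gaussian closed form holds when wrap-around is negligible
        prof = P.gaussian_profile(0.05, 50)
        vals = P.circulant_eigenvalues(prof).values
        p = np.arange(6)
        expected = np.exp(-4 * np.pi**2 * 0.05**2 * p.astype(float) ** 2)
        top = vals[:11][::2]  # p = 0 and the +/- degenerate pairs
        assert np.allclose(top / top[0], expected, rtol=1e-6)

    def test_asymmetric_profile_rejected(self):
        prof = P.CorrelationProfile(np.array([1.0, 0.8, 0.1, 0.05]))
        with pytest.raises(ValueError, match="symmetric"):
            P.circulant_eigenvalues(prof)


class TestGaussianSpectrum1D:
    def test_shape_and_ratio(self):
        spec = P.gaussian_spectrum_1d(0.075, 50)
        assert spec.values[0] == 1.0  # p = 0 dominates
        assert spec.values[1] / spec.values[0] == pytest.approx(
            math.exp(-4 * math.pi**2 * 0.075**2)
        )
        assert spec.values[1] == pytest.approx(0.8009, abs=1e-4)

    def test_consistent_with_radial_spectrum_at_D1(self):
        spec = P.gaussian_spectrum_1d(0.1, 24)
        rs = P.radial_spectrum(0.1, 1, 24)
        assert np.allclose(np.sort(rs.expand()), np.sort(spec.values))


class TestRadialSpectrum:
    @pytest.mark.parametrize("D,N_d", [(1, 9), (2, 10), (2, 7), (3, 6), (3, 10)])
    def test_multiset_equals_brute_force_lattice(self, D, N_d):
        sigma = 0.15
        rs = P.radial_spectrum(sigma, D, N_d)
        assert rs.total_count == N_d**D
        freqs = np.fft.fftfreq(N_d, 1.0 / N_d).astype(int)
        mesh = np.meshgrid(*[freqs] * D, indexing="ij")
        sq = sum(m.astype(np.int64) ** 2 for m in mesh).ravel()
        brute = np.sort(np.exp(-4 * np.pi**2 * sigma**2 * sq.astype(float)))[::-1]
        assert np.array_equal(
            np.sort(sq), np.repeat(rs.m, rs.multiplicity.astype(int))
        )
        assert np.allclose(rs.expand(), brute, rtol=1e-14)

    def test_shell_multiplicities(self):
        for D in (2, 3, 4):
            rs = P.radial_spectrum(0.1, D, 9)
            assert rs.multiplicity[rs.m == 0][0] == 1
            assert rs.multiplicity[rs.m == 1][0] == 2 * D


class TestLatticeLinearDimension:
    def test_reduces_to_1d(self):
        rs = P.radial_spectrum(0.075, 1, 30)
        L_lattice = P.linear_dimension_lattice(rs, 0.05).L
        L_direct = P.linear_dimension(P.gaussian_spectrum_1d(0.075, 30), 0.05).L
        assert L_lattice == L_direct == 7

    def test_equals_brute_force_sort_and_sum(self):
        rs = P.radial_spectrum(0.15, 2, 10)
        flat = rs.expand()
        cum = np.cumsum(flat)
        brute_L = int(np.searchsorted(cum, 0.95 * cum[-1] - 1e-12) + 1)
        # whole-shell counting may round brute-force L up to the shell edge
        rep = P.linear_dimension_lattice(rs, 0.05, check_truncation=False)
        assert rep.L >= brute_L
        assert rep.L - brute_L < rep.extras["crossing_shell_multiplicity"]

    def test_truncation_guard(self):
        rs = P.radial_spectrum(0.15, 2, 10)  # Nyquist eigenvalue ~ 2e-10
        with pytest.raises(TruncationError, match="raise N_d"):
            P.linear_dimension_lattice(rs, 0.05)

    def test_monotone_in_sigma_and_D(self):
        eps = 0.05
        Ls = [
            P.linear_dimension_lattice(
                P.radial_spectrum(s, 2, P.min_lattice_size(s)), eps
            ).L
            for s in (0.075, 0.1, 0.15, 0.2)
        ]
        assert Ls == sorted(Ls, reverse=True)  # narrower tuning -> larger L
        Ld = [
            P.linear_dimension_lattice(
                P.radial_spectrum(0.1, D, P.min_lattice_size(0.1)), eps
            ).L
            for D in (1, 2, 3, 4, 5)
        ]
        assert Ld == sorted(Ld)  # higher intrinsic dimension -> larger L

    def test_exponential_growth_in_D(self):
        # log L vs D has positive, non-decreasing increments (convex-to-linear)
        for sigma in (0.075, 0.1, 0.15):
            n = P.min_lattice_size(sigma)
            logL = [
                math.log(
                    P.linear_dimension_lattice(P.radial_spectrum(sigma, D, n), 0.05).L
                )
                for D in range(2, 9)
            ]
            inc = np.diff(logL)
            assert np.all(inc > 0)
            assert inc[-1] > 0.9 * inc[0]  # does not flatten out


class TestMultiDimensionalSimulation:
    def test_simulated_2d_spectrum_matches_lattice_theory(self):
        # 10x10 periodic Gaussian population, T = 1e4 uniform samples
        grid = P.make_center_grid(2, 10)
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=0.1, space=P.LatentSpace(D=2)
        )
        sim = P.simulate_population(tuning, grid, T=10_000, seed=3)
        emp = P.eigen_spectrum(P.covariance(sim)).normalized()
        ana = P.radial_spectrum(0.1, 2, 10).expand()
        ana = ana / ana.sum()
        assert np.max(np.abs(emp[:9] - ana[:9]) / ana[:9]) < 0.05


class TestClosedForm1D:
    def test_value_and_scaling(self):
        b = P.closed_form_L_1d(0.075, 0.05)
        assert b.value == pytest.approx(5.88, abs=0.01)
        # value * sigma constant across sigma at fixed epsilon
        prods = [P.closed_form_L_1d(s, 0.05).value * s for s in (0.02, 0.1, 0.3)]
        assert np.allclose(prods, prods[0])
        # 1.96 / (sqrt(2) pi sigma) form at epsilon = 0.05
        assert b.value == pytest.approx(1.96 / (math.sqrt(2) * math.pi * 0.075), rel=1e-3)

    def test_limit_eps_to_one(self):
        assert P.closed_form_L_1d(0.1, 0.999999).value == pytest.approx(0.0, abs=1e-4)


class TestChiBounds:
    def test_median_mode_small_example(self):
        b = P.chi_bounds(0.1, 2, 0.05, "median_lower_bound")
        # radius ~ 1.325 -> origin plus the 4 unit lattice vectors
        assert b.value == 5
        assert b.params["s"] == pytest.approx(1.1254, abs=1e-4)

    def test_quantile_equals_median_at_half(self):
        a = P.chi_bounds(0.12, 3, 0.5, "median_lower_bound")
        b = P.chi_bounds(0.12, 3, 0.5, "quantile_semianalytic")
        assert a.value == b.value

    def test_median_bound_below_exact_everywhere(self):
        for sigma in (0.075, 0.1, 0.15, 0.2):
            n = P.min_lattice_size(sigma)
            for D in range(2, 9):
                exact = P.linear_dimension_lattice(
                    P.radial_spectrum(sigma, D, n), 0.05
                ).L
                bound = P.chi_bounds(sigma, D, 0.05, "median_lower_bound").value
                assert bound <= exact

    def test_invalid_modes(self):
        with pytest.raises(ValueError, match="0.5"):
            P.chi_bounds(0.1, 3, 0.7, "median_lower_bound")
        with pytest.raises(ValueError, match="D > 1"):
            P.chi_bounds(0.1, 1, 0.05, "median_lower_bound")


class TestInterpolatedSpectrum:
    def test_d1_reduces_to_pairwise_gaussian(self):
        p = np.arange(1, 10)
        vals = P.interpolated_spectrum(0.1, 1, p)
        assert np.allclose(vals, np.exp(-4 * np.pi**2 * 0.01 * (p / 2.0) ** 2))
        assert unit_ball_volume(1) == pytest.approx(2.0)

    def test_monotone_decreasing(self):
        vals = P.interpolated_spectrum(0.15, 3, np.arange(1, 200))
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("D,N_d", [(2, 10), (3, 10), (4, 8)])
    def test_threads_the_step_spectrum(self, D, N_d):
        # at each shell boundary the smooth curve lies within a factor two
        # of the bracketing step values
        rs = P.radial_spectrum(0.15, D, N_d)
        lam = rs.lam / rs.lam[0]
        ranks = np.cumsum(rs.multiplicity)
        interp = P.interpolated_spectrum(0.15, D, ranks)
        keep = np.nonzero(lam > 1e-8)[0][:-1]
        for i in keep:
            assert interp[i] <= 2.0 * lam[i]
            assert interp[i] >= 0.5 * lam[i + 1]


class TestUncertaintyBounds:
    def test_support_bound_endpoints(self):
        assert P.support_bound(50, 50).value == 1.0
        assert P.support_bound(1, 50).value == 50.0
        # delta profile saturates the bound: N nonzero eigenvalues
        delta = P.CorrelationProfile(np.r_[1.0, np.zeros(49)])
        vals = P.circulant_eigenvalues(delta).values
        assert np.count_nonzero(vals > 1e-12) == 50

    def test_concentration_bound_value_and_consistency(self):
        b = P.concentration_bound(10, 100, 0.05, 0.5)
        assert b.value == pytest.approx(100 * 0.5 * 0.95 / 10)
        # doubling K halves the bound
        assert P.concentration_bound(20, 100, 0.05, 0.5).value == pytest.approx(
            b.value / 2
        )

    def test_concentration_bound_below_measured_L(self):
        # Gaussian profile, N = 50, sigma = 0.075, eps_hat = 0.5
        prof = P.gaussian_profile(0.075, 50)
        K = P.profile_support_size(prof, 0.5)
        bound = P.concentration_bound(K, 50, 0.05, 0.5).value
        L = P.linear_dimension(P.circulant_eigenvalues(prof), 0.05).L
        assert bound <= L

    def test_localized_scaling(self):
        assert P.localized_scaling_bound(1, 0.2).value == 1.0
        assert P.localized_scaling_bound(3, 0.0).value == 27.0
        # log(value) / (D log D) -> 1 - eps
        D = 40
        val = P.localized_scaling_bound(D, 0.05)
        assert math.log(val.value) / (D * math.log(D)) == pytest.approx(0.95)
        # very large D degrades gracefully to infinity with the log exposed
        huge = P.localized_scaling_bound(400, 0.05)
        assert math.isinf(huge.value)
        assert huge.params["log_value"] == pytest.approx(0.95 * 400 * math.log(400))
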