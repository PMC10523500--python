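"""Tuning-curve primitives and the population simulator."""

import numpy as np
import pytest

import popdim as P
from popdim.populations import MAX_GRID_SIZE


class TestCenterGrid:
    @pytest.mark.parametrize(
        "D,N_d,expected",
        [
            (1, 4, {0.0, 0.25, 0.5, 0.75}),
            (1, 50, None),
            (2, 3, None),
        ],
    )
    def test_even_periodic_lattice(self, D, N_d, expected):
        grid = P.make_center_grid(D, N_d, "even", "periodic")
        assert grid.N == N_d**D
        if expected is not None:
            assert set(grid.centers.ravel()) == expected
        if D == 1:
            gaps = np.diff(np.sort(grid.centers[:, 0]))
            assert np.allclose(gaps, 1.0 / N_d)
        if D == 2 and N_d == 3:
            axis = {0.0, 1 / 3, 2 / 3}
            assert set(np.round(grid.centers[:, 0], 12)) == set(np.round(list(axis), 12))

    def test_random_grid_is_seeded(self):
        a = P.make_center_grid(2, 5, "random", "periodic", seed=3)
        b = P.make_center_grid(2, 5, "random", "periodic", seed=3)
        c = P.make_center_grid(2, 5, "random", "periodic", seed=4)
        assert np.array_equal(a.centers, b.centers)
        assert not np.array_equal(a.centers, c.centers)
        assert np.all((a.centers >= 0) & (a.centers < 1))

    def test_size_guard(self):
        with pytest.raises(ValueError, match="size"):
            P.make_center_grid(10, 10)
        assert 10**10 > MAX_GRID_SIZE  # the case above really is oversized


class TestTuningPrimitives:
    def test_gaussian_peak_and_closed_form(self):
        space = P.LatentSpace(D=1, boundary="open")
        assert P.gaussian_tuning_response([0.4], [0.4], 0.1, space) == 1.0
        # two tuning widths away from the center: exp(-2)
        val = P.gaussian_tuning_response([0.4 + 0.2], [0.4], 0.1, space)
        assert np.isclose(val, np.exp(-2.0))

    def test_gaussian_wraps_around_periodic_boundary(self):
        space = P.LatentSpace(D=1, boundary="periodic")
        val = P.gaussian_tuning_response([0.95], [0.05], 0.075, space)
        # wrap distance is 0.10, not 0.90
        assert np.isclose(val, np.exp(-(0.1**2) / (2 * 0.075**2)))
        assert np.isclose(val, 0.4111, atol=5e-5)

    def test_gaussian_symmetric_in_arguments(self):
        space = P.LatentSpace(D=2, boundary="periodic")
        a, b = np.array([0.1, 0.9]), np.array([0.7, 0.2])
        assert P.gaussian_tuning_response(a, b, 0.1, space) == pytest.approx(
            P.gaussian_tuning_response(b, a, 0.1, space)
        )

    def test_dimension_mismatch_raises(self):
        space = P.LatentSpace(D=2)
        with pytest.raises(ValueError, match="coordinates"):
            P.gaussian_tuning_response([0.1], [0.1, 0.2], 0.1, space)

    @pytest.mark.parametrize(
        "x,mu,s,expected",
        [
            (0.3, 0.3, 4.0, 0.5),
            (0.9, 0.2, 0.0, 0.5),
            (1.0, 0.0, 5.0, 1.0 / (1.0 + np.exp(-5.0))),
        ],
    )
    def test_sigmoid_values(self, x, mu, s, expected):
        assert P.sigmoid_factor_response(x, mu, s) == pytest.approx(expected)

    def test_varwidth_gaussian_values(self):
        assert P.varwidth_gaussian_factor_response(0.5, 0.5, 0.1) == 1.0
        assert P.varwidth_gaussian_factor_response(0.6, 0.5, 0.1) == pytest.approx(
            np.exp(-0.5)
        )
        with pytest.raises(ValueError):
            P.varwidth_gaussian_factor_response(0.5, 0.5, -0.1)

    def test_varwidth_profile_sharpest_at_center(self):
        w = P.varwidth_profile(8)
        assert np.allclose(w, [0.2, 0.15, 0.1, 0.05, 0.05, 0.1, 0.15, 0.2])
        assert np.allclose(w, w[::-1])  # symmetric about the middle

    def test_product_tuning(self):
        ones = [lambda x: np.ones_like(np.asarray(x, float))] * 3
        assert P.product_tuning_response([0.1, 0.2, 0.3], ones) == 1.0
        fs = [lambda x: 0.5 * np.ones_like(np.asarray(x, float)),
              lambda x: 0.2 * np.ones_like(np.asarray(x, float))]
        assert P.product_tuning_response([0.0, 0.0], fs) == pytest.approx(0.1)
        # hybrid at sigmoid midpoint x Gaussian center
        hybrid = [P.SigmoidFactor(0.5, 3.0), P.GaussianFactor(0.4, 0.1)]
        assert P.product_tuning_response([0.5, 0.4], hybrid) == pytest.approx(0.5)


class TestSimulatePopulation:
    def test_rates_bounded_and_deterministic(self, sim_1d_narrow):
        assert sim_1d_narrow.values.shape == (50, 10_000)
        assert sim_1d_narrow.values.min() >= 0.0
        assert sim_1d_narrow.values.max() <= 1.0 + 1e-12
        again = P.simulate_population(
            sim_1d_narrow.tuning, sim_1d_narrow.grid, T=10_000, seed=7
        )
        assert np.array_equal(again.values, sim_1d_narrow.values)

    def test_lattice_sampler_hits_peaks(self):
        grid = P.make_center_grid(1, 8)
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=0.1, space=P.LatentSpace(D=1)
        )
        sim = P.simulate_population(tuning, grid, T=8, sampler="lattice")
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_covariance_is_circulant_under_lattice_sampling(self):
        # translation symmetry: each covariance row is a cyclic shift of row 0
        grid = P.make_center_grid(1, 16)
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=0.1, space=P.LatentSpace(D=1)
        )
        sim = P.simulate_population(tuning, grid, T=16, sampler="lattice")
        C = P.covariance(sim).values
        for n in range(16):
            assert np.allclose(C[n], np.roll(C[0], n), atol=1e-12)

    def test_monte_carlo_covariance_converges(self):
        # covariance error vs exact quadrature shrinks ~ 1/sqrt(T)
        grid = P.make_center_grid(1, 20)
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=0.1, space=P.LatentSpace(D=1)
        )
        exact = P.quadrature_profile(0.1, 20).samples
        errs = {}
        for T in (500, 8000):
            sim = P.simulate_population(tuning, grid, T=T, seed=11)
            errs[T] = np.abs(P.covariance(sim).values[0] - exact).max()
        assert errs[8000] < errs[500]
        assert errs[8000] < 5.0 / np.sqrt(8000)

    def test_product_covariance_factorizes(self):
        # 2D product code: covariance = entrywise product of factor covariances
        banks = [P.sigmoid_factor_bank(4), P.varwidth_gaussian_factor_bank(4)]
        C2d = P.product_population_covariance(banks, 256).values
        C1 = P.factor_covariance(banks[0], 256).values
        C2 = P.factor_covariance(banks[1], 256).values
        assert np.allclose(C2d, np.kron(C1, C2), rtol=1e-10, atol=1e-12)

    def test_simulator_matches_quadrature_for_product_code(self):
        banks = [P.sigmoid_factor_bank(3)] * 2
        grid = P.make_center_grid(2, 3)
        tuning = P.TuningSpec(family="product", factor_banks=banks)
        sim = P.simulate_population(tuning, grid, T=20_000, seed=5)
        C_mc = P.covariance(sim).values
        C_quad = P.product_population_covariance(banks, 256).values
        assert np.abs(C_mc - C_quad).max() < 0.01

    def test_roundtrip_serialization(self, tmp_path, sim_1d_narrow):
        small = P.simulate_population(
            sim_1d_narrow.tuning, sim_1d_narrow.grid, T=25, seed=3
        )
        path = tmp_path / "pop.csv"
        P.save_population(small, path)
        back = P.load_population(path)
        assert np.array_equal(back.values, small.values)
        assert np.array_equal(back.latents, small.latents)
        assert back.tuning.sigma == small.tuning.sigma
        assert back.seed == 3

    def test_invalid_T_rejected(self):
        grid = P.make_center_grid(1, 4)
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=0.1, space=P.LatentSpace(D=1)
        )
        with pytest.raises(ValueError):
            P.simulate_population(tuning, grid, T=0)
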