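import numpy as np
import pytest

import popdim as P


@pytest.fixture(scope="session")
def sim_1d_narrow():
    """N=50 periodic Gaussian population, sigma=0.075, T=10^4, seeded."""
    grid = P.make_center_grid(1, 50, "even", "periodic")
    tuning = P.TuningSpec(
        family="gaussian_translation", sigma=0.075, space=P.LatentSpace(D=1)
    )
    return P.simulate_population(tuning, grid, T=10_000, seed=7)


@pytest.fixture(scope="session")
def gaussian_fixture_set():
    """Small simulated Gaussian populations across widths (bound checks)."""
    sims = []
    for i, sigma in enumerate([0.075, 0.1, 0.15, 0.2]):
        grid = P.make_center_grid(1, 30, "even", "periodic")
        tuning = P.TuningSpec(
            family="gaussian_translation", sigma=sigma, space=P.LatentSpace(D=1)
        )
        sims.append(P.simulate_population(tuning, grid, T=2000, seed=100 + i))
    return sims


@pytest.fixture(scope="session")
def sigmoid_factor_spectrum():
    return P.factor_spectrum(P.sigmoid_factor_bank(8))
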