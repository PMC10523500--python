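"""Analytic spectra and bounds for translation-symmetric population codes.

When tuning curves are shifted copies of one template on an evenly tiled
periodic domain, the neuron-neuron covariance is circulant (1D) or
block-circulant (multi-D) and is diagonalized by the discrete Fourier
basis: the eigenvalues are the Fourier transform of the correlation
profile c(delta).  For Gaussian tuning of width sigma the profile is
Gaussian with width sqrt(2)*sigma, and the eigenvalue at integer
frequency vector p is

    lambda_p = K3 * exp(-4 pi^2 sigma^2 |p|^2),

a Gaussian in Fourier space whose width is *inversely* proportional to
the tuning width.  In D dimensions the eigenvalues live on the integer
lattice; their magnitude depends only on |p|^2, so the spectrum is fully
described by the multiplicity of each integer squared radius.  Counting
eigenvalues inside the sphere that holds a 1-eps mass fraction gives the
linear dimension; chi-distribution quantiles of the Fourier-space
Gaussian give closed-form estimates and lower bounds that grow
exponentially with D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .spectra import DimensionReport, EigenSpectrum, linear_dimension

__all__ = [
    "CorrelationProfile",
    "RadialSpectrum",
    "TheoryBound",
    "TruncationError",
    "gaussian_profile",
    "quadrature_profile",
    "circulant_eigenvalues",
    "gaussian_spectrum_1d",
    "radial_spectrum",
    "linear_dimension_lattice",
    "closed_form_L_1d",
    "fourier_gaussian_width",
    "chi_bounds",
    "lattice_ball_count",
    "interpolated_spectrum",
    "support_bound",
    "concentration_bound",
    "profile_support_size",
    "localized_scaling_bound",
    "min_lattice_size",
]


class TruncationError(ValueError):
    """The finite frequency lattice drops non-negligible eigenvalue mass;
    the caller should raise N_d."""


@dataclass
class CorrelationProfile:
    """Sampled correlation profile c(l/N) on the even periodic grid (1D)."""

    samples: np.ndarray
    periodic: bool = True
    sigma: float | None = None  # underlying tuning width, when Gaussian

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("profile must be a 1D sample vector")

    @property
    def N(self) -> int:
        return self.samples.size


def gaussian_profile(sigma: float, N: int, peak: float = 1.0) -> CorrelationProfile:
    """Correlation profile of Gaussian tuning of width sigma on the even
    periodic grid: c(delta) = K2 exp(-delta^2 / (4 sigma^2)), delta wrapped."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    delta = np.arange(N) / N
    delta = np.minimum(delta, 1.0 - delta)
    return CorrelationProfile(
        samples=peak * np.exp(-(delta**2) / (4.0 * sigma**2)),
        periodic=True,
        sigma=sigma,
    )


def quadrature_profile(
    sigma: float, N: int, quadrature_points: int = 8192
) -> CorrelationProfile:
    """Exact correlation profile of periodic Gaussian tuning, by quadrature:
    c(l/N) = int_0^1 g(d(x, 0)) g(d(x, l/N)) dx with wrapped distance d.

    Unlike the closed-form Gaussian profile exp(-delta^2/(4 sigma^2)),
    this is the true (hence positive-definite) covariance profile at any
    width; the two agree for narrow tuning.  The midpoint rule on a
    periodic smooth integrand converges spectrally.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    M = quadrature_points
    x = (np.arange(M) + 0.5) / M
    g0 = np.exp(-np.minimum(x, 1.0 - x) ** 2 / (2.0 * sigma**2))
    samples = np.empty(N)
    for l in range(N):
        d = np.abs(x - l / N)
        d = np.minimum(d, 1.0 - d)
        samples[l] = np.mean(g0 * np.exp(-(d**2) / (2.0 * sigma**2)))
    return CorrelationProfile(samples=samples, periodic=True, sigma=sigma)


def circulant_eigenvalues(profile: CorrelationProfile) -> EigenSpectrum:
    """Eigenvalues of the circulant matrix built from ``profile``:
    the DFT of its first row, real for symmetric profiles.

    Values are reported exactly as the matrix spectrum.  A profile that is
    not positive definite on the circle — e.g. the plain Gaussian of
    wrapped distance once sigma is large enough for the wrap-around kink
    to matter — yields small negative eigenvalues, which are preserved so
    the result stays equal to the dense eigendecomposition.
    """
    fourier = np.fft.fft(profile.samples)
    scale = max(float(np.abs(fourier).max()), 1.0)
    if np.abs(fourier.imag).max() > 1e-9 * scale:
        raise ValueError(
            "DFT has a non-negligible imaginary part: profile is not symmetric"
        )
    vals = np.sort(fourier.real)[::-1]
    return EigenSpectrum(values=vals, source="analytic_translation")


def _frequencies(N: int) -> np.ndarray:
    """Integer DFT frequencies, Nyquist counted once for even N."""
    return np.fft.fftfreq(N, d=1.0 / N).astype(int)


def gaussian_spectrum_1d(sigma: float, N: int, normalized: bool = False) -> EigenSpectrum:
    """Large-N spectrum of a 1D Gaussian code: lambda_p = exp(-4 pi^2 sigma^2 p^2)
    over the N integer frequencies p, sorted descending."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if N < 3:
        raise ValueError("need N >= 3 frequencies")
    p = _frequencies(N)
    vals = np.exp(-4.0 * np.pi**2 * sigma**2 * p.astype(float) ** 2)
    vals = np.sort(vals)[::-1]
    if normalized:
        vals = vals / vals.sum()
    return EigenSpectrum(values=vals, source="analytic_translation")


@dataclass
class RadialSpectrum:
    """Multi-D lattice spectrum compressed by integer squared radius.

    ``m`` are the distinct values of |p|^2 over the frequency lattice,
    ``lam[i] = exp(-4 pi^2 sigma^2 m[i])`` and ``multiplicity[i]`` counts
    the lattice vectors at that squared radius; multiplicities sum to
    N_d ** D.  Built by D-fold convolution of the per-dimension histogram
    of p_d^2 values, never by enumerating the full lattice.
    """

    m: np.ndarray
    lam: np.ndarray
    multiplicity: np.ndarray
    D: int
    sigma: float
    N_d: int

    @property
    def total_count(self) -> int:
        return int(round(float(self.multiplicity.sum())))

    def total_mass(self) -> float:
        return float(np.dot(self.multiplicity, self.lam))

    def expand(self) -> np.ndarray:
        """Flat descending eigenvalue multiset (small lattices only)."""
        if self.total_count > 10**7:
            raise ValueError("lattice too large to expand explicitly")
        out = np.repeat(self.lam, self.multiplicity.astype(int))
        return np.sort(out)[::-1]


def _squared_radius_multiplicities(freqs: np.ndarray, D: int) -> np.ndarray:
    """counts[m] of lattice vectors p in freqs^D with |p|^2 = m, via
    D-fold convolution of the per-dimension histogram of p_d^2."""
    sq = freqs.astype(np.int64) ** 2
    base = np.bincount(sq)
    counts = base.astype(float)
    for _ in range(D - 1):
        counts = np.convolve(counts, base)
    return counts


def radial_spectrum(sigma: float, D: int, N_d: int) -> RadialSpectrum:
    """Analytic lattice spectrum of a D-dimensional Gaussian code with N_d
    frequency indices (neurons) per dimension."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if D < 1:
        raise ValueError("D must be >= 1")
    if N_d < 3:
        raise ValueError("need N_d >= 3")
    counts = _squared_radius_multiplicities(_frequencies(N_d), D)
    m = np.nonzero(counts)[0]
    lam = np.exp(-4.0 * np.pi**2 * sigma**2 * m.astype(float))
    return RadialSpectrum(
        m=m, lam=lam, multiplicity=counts[m], D=D, sigma=sigma, N_d=N_d
    )


#: largest tolerable dropped eigenvalue (relative to lambda_0 = 1) when the
#: finite lattice stands in for the infinite-frequency spectrum
TRUNCATION_TOL = 1e-12


def min_lattice_size(sigma: float, tol: float = TRUNCATION_TOL) -> int:
    """Smallest even N_d whose Nyquist eigenvalue exp(-4 pi^2 sigma^2 (N_d/2)^2)
    is below ``tol``, so the finite lattice carries all relevant mass."""
    half = math.sqrt(-math.log(tol) / (4.0 * math.pi**2 * sigma**2))
    n = 2 * math.ceil(half)
    return n + (n % 2)


def linear_dimension_lattice(
    rs: RadialSpectrum, epsilon: float, check_truncation: bool = True
) -> DimensionReport:
    """Linear dimension of a lattice spectrum by whole-shell counting.

    Shells are accumulated in ascending |p|^2 (descending eigenvalue); the
    shell that crosses the 1-eps mass threshold is counted in full, since
    its eigenvalues are exactly degenerate and a minimal L would split the
    tie arbitrarily.  The report's ``extras`` record the crossing shell.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if check_truncation:
        edge = math.exp(
            -4.0 * math.pi**2 * rs.sigma**2 * (rs.N_d / 2.0) ** 2
        )
        if edge > TRUNCATION_TOL:
            raise TruncationError(
                f"Nyquist eigenvalue {edge:.2e} exceeds {TRUNCATION_TOL:.0e}: "
                f"raise N_d above {min_lattice_size(rs.sigma)} "
                f"(got {rs.N_d}) or pass check_truncation=False"
            )
    mass = rs.multiplicity * rs.lam
    cum_mass = np.cumsum(mass)
    total = cum_mass[-1]
    idx = int(np.searchsorted(cum_mass, (1.0 - epsilon) * total - 1e-12 * total))
    L = int(round(float(np.sum(rs.multiplicity[: idx + 1]))))
    pr = float(np.dot(rs.multiplicity, rs.lam) ** 2 / np.dot(rs.multiplicity, rs.lam**2))
    return DimensionReport(
        epsilon=epsilon,
        L=L,
        participation_ratio=pr,
        source="analytic_translation",
        extras={
            "crossing_shell_m": int(rs.m[idx]),
            "crossing_shell_multiplicity": int(rs.multiplicity[idx]),
        },
    )


@dataclass
class TheoryBound:
    """A closed-form prediction or bound on linear dimension."""

    kind: str
    value: float
    validity: str = ""
    params: dict = field(default_factory=dict)


def closed_form_L_1d(sigma: float, epsilon: float) -> TheoryBound:
    """Continuum linear dimension of a 1D Gaussian code:
    L = erfinv(1 - eps) / (pi sigma); at eps = 0.05 this is
    1.96 / (sqrt(2) pi sigma), the 95% CI width of a Gaussian."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    value = float(special.erfinv(1.0 - epsilon) / (math.pi * sigma))
    return TheoryBound(
        kind="closed_form_1d",
        value=value,
        validity="Gaussian-integral approximation; N not too small",
        params={"sigma": sigma, "epsilon": epsilon},
    )


def fourier_gaussian_width(sigma: float) -> float:
    """Width s of the Fourier-space Gaussian: lambda_p = exp(-|p|^2/(2 s^2))
    with s = 1 / (2 sqrt(2) pi sigma)."""
    return 1.0 / (2.0 * math.sqrt(2.0) * math.pi * sigma)


def lattice_ball_count(D: int, r2: float) -> int:
    """Number of integer lattice points p in Z^D with |p|^2 <= r2, counted
    exactly via the radial multiplicity convolution."""
    if r2 < 0:
        return 0
    R = int(math.floor(math.sqrt(r2)))
    freqs = np.arange(-R, R + 1)
    counts = _squared_radius_multiplicities(freqs, D)
    mmax = int(math.floor(r2))
    return int(round(float(counts[: mmax + 1].sum())))


def chi_bounds(
    sigma: float,
    D: int,
    epsilon: float,
    mode: str = "median_lower_bound",
) -> TheoryBound:
    """Chi-distribution estimates of the lattice linear dimension.

    The Fourier-space spectrum is a D-dimensional Gaussian of width
    s = 1/(2 sqrt(2) pi sigma) per axis, so the radius containing a mass
    fraction q of eigenvalues is s times the chi(D) q-quantile.  The
    number of lattice points inside that radius is:

    * ``median_lower_bound`` (q = 1/2): a true lower bound on L whenever
      eps <= 0.5 and D > 1 — at least half the mass lies within the
      median radius of the continuum Gaussian;
    * ``quantile_semianalytic`` (q = 1 - eps): a semianalytic fit.

    Quantiles come from the exact chi-squared quantile function
    (Q = sqrt(chi2.ppf(q, D))), not the (D - 2/3) approximation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    s = fourier_gaussian_width(sigma)
    if mode == "median_lower_bound":
        if epsilon > 0.5:
            raise ValueError(
                "median lower bound is only valid for epsilon <= 0.5"
            )
        if D <= 1:
            raise ValueError("median lower bound requires D > 1")
        Q = math.sqrt(stats.chi2.ppf(0.5, df=D))
        validity = "lower bound on L for eps <= 0.5, D > 1"
    elif mode == "quantile_semianalytic":
        Q = math.sqrt(stats.chi2.ppf(1.0 - epsilon, df=D))
        validity = "semianalytic fit, not a bound"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r = s * Q
    value = float(lattice_ball_count(D, r * r))
    return TheoryBound(
        kind="chi_median" if mode == "median_lower_bound" else "chi_quantile",
        value=value,
        validity=validity,
        params={"sigma": sigma, "D": D, "epsilon": epsilon, "s": s, "radius": r},
    )


def unit_ball_volume(D: int) -> float:
    """Volume of the unit ball in R^D."""
    return math.pi ** (D / 2.0) / math.gamma(D / 2.0 + 1.0)


def interpolated_spectrum(sigma: float, D: int, p_index: np.ndarray | int) -> np.ndarray:
    """Smooth interpolation of the step-like lattice spectrum.

    Rank p (1-based, counting eigenvalues in descending order) is mapped
    to the radius of the ball containing p lattice points,
    r(p) = (p / V_D)^(1/D) with V_D the unit-D-ball volume, and the
    eigenvalue is the Fourier Gaussian at that radius,
    exp(-4 pi^2 sigma^2 r^2).  Threads the degenerate shells of the exact
    spectrum between the power-law-like and exponential regimes.
    """
    p = np.asarray(p_index, dtype=float)
    if np.any(p < 1):
        raise ValueError("rank index must be >= 1")
    r = (p / unit_ball_volume(D)) ** (1.0 / D)
    return np.exp(-4.0 * math.pi**2 * sigma**2 * r**2)


def support_bound(K: int, N: int) -> TheoryBound:
    """Fourier support uncertainty principle: a K-sparse correlation profile
    on N points has at least N/K nonzero eigenvalues."""
    if K < 1 or K > N:
        raise ValueError("need 1 <= K <= N")
    return TheoryBound(
        kind="support_K",
        value=N / K,
        validity="counts nonzero eigenvalues, any profile",
        params={"K": K, "N": N},
    )


def concentration_bound(
    K: int, N: int, epsilon: float, epsilon_hat: float
) -> TheoryBound:
    """Concentration uncertainty principle: if a 1 - eps_hat fraction of the
    correlation-profile mass sits on K points, the smallest set holding a
    1 - eps fraction of eigenvalue mass has size >= N (1-eps_hat)(1-eps)/K.
    For a multi-D code pass N = N_d ** D."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0.0 < epsilon < 1.0 and 0.0 < epsilon_hat < 1.0):
        raise ValueError("epsilon and epsilon_hat must lie in (0, 1)")
    return TheoryBound(
        kind="concentration_K",
        value=N * (1.0 - epsilon_hat) * (1.0 - epsilon) / K,
        validity="lower bound on L_(1-eps)",
        params={"K": K, "N": N, "epsilon": epsilon, "epsilon_hat": epsilon_hat},
    )


def profile_support_size(profile: CorrelationProfile, epsilon_hat: float) -> int:
    """Size K of the smallest set of profile samples (largest magnitudes
    first) holding a 1 - eps_hat fraction of total |c| mass."""
    mags = np.sort(np.abs(profile.samples))[::-1]
    total = mags.sum()
    if total <= 0:
        raise ValueError("profile has no mass")
    cum = np.cumsum(mags)
    return int(np.searchsorted(cum, (1.0 - epsilon_hat) * total - 1e-12 * total) + 1)


def localized_scaling_bound(D: int, epsilon: float) -> TheoryBound:
    """Supraexponential growth for truly localized (compact-support) tuning:
    L scales as D^(D (1-eps)).  An asymptotic-order statement, not a sharp
    numeric bound at small D."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    log_value = D * (1.0 - epsilon) * math.log(D) if D > 1 else 0.0
    value = math.exp(log_value) if log_value < 700 else math.inf
    return TheoryBound(
        kind="localized",
        value=value,
        validity="asymptotic order in D, compact-support tuning",
        params={"D": D, "epsilon": epsilon, "log_value": log_value},
    )
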