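"""Tensor-product spectra and entropy bounds for multiplicative codes.

For tuning curves that factor across latent dimensions, the covariance is
a tensor (Kronecker) product of per-dimension factor covariances, so its
eigenvalues are all products of one eigenvalue per factor.  Normalized
factor eigenvalues behave like outcome probabilities of independent
categorical variables, and the (1-eps)-linear dimension is the size of
the smallest high-probability set of the joint variable.  The asymptotic
equipartition property then gives L ~ 2^(D H), with H the Shannon entropy
of the factor eigenvalues — exponential growth in the intrinsic
dimension D, with the entropy as the rate.

Large-D product spectra are handled in the log2 domain: per-factor
histograms of log2-eigenvalues are convolved D times, tracking both the
eigenvalue count and the eigenvalue mass per bin, so populations of 8^14
"neurons" are summarized without ever materializing the multiset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .populations import Factor
from .spectra import CovarianceMatrix, DimensionReport, eigen_spectrum
from .translation import TheoryBound

__all__ = [
    "FactorSpectrum",
    "ProductSpectrum",
    "AEPBound",
    "factor_covariance",
    "factor_spectrum",
    "product_population_covariance",
    "tensor_spectrum",
    "linear_dimension_product",
    "aep_estimate",
    "binomial_lower_bound",
    "exact_binomial_L",
    "dirichlet_factor",
]

#: switch from explicit eigenvalue multisets to log-histograms above this size
EXPLICIT_LIMIT = 10**6

#: log2-eigenvalue histogram resolution in bits
HIST_BIN_BITS = 0.01


@dataclass
class FactorSpectrum:
    """Eigenvalues of one factor covariance, normalized to sum to 1."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.sort(np.asarray(self.values, dtype=float))[::-1]
        if np.any(vals < -1e-12):
            raise ValueError("factor eigenvalues must be nonnegative")
        vals = np.clip(vals, 0.0, None)
        total = vals.sum()
        if total <= 0:
            raise ValueError("factor spectrum has no mass")
        self.values = vals / total

    @property
    def entropy(self) -> float:
        """Shannon entropy in bits, with 0 log 0 := 0."""
        v = self.values[self.values > 0]
        return float(-np.sum(v * np.log2(v)))

    @property
    def participation_ratio(self) -> float:
        return float(1.0 / np.sum(self.values**2))


def factor_covariance(
    factors: Sequence[Factor], quadrature_points: int = 512
) -> CovarianceMatrix:
    """Pairwise factor-product integrals c_rs = int f_r(x) f_s(x) dx over a
    uniform latent on [0, 1], by fixed-order Gauss-Legendre quadrature.

    The Gram-matrix form F W F^T (with positive weights W) is PSD by
    construction; the integrands are smooth, so order 512 puts quadrature
    error far below eigenvalue tolerances.
    """
    if quadrature_points < 256:
        raise ValueError("use at least 256 quadrature points")
    nodes, weights = np.polynomial.legendre.leggauss(quadrature_points)
    x = 0.5 * (nodes + 1.0)  # map [-1, 1] -> [0, 1]
    w = 0.5 * weights
    F = np.stack([f(x) for f in factors], axis=0)  # (N_d, Q)
    C = (F * w) @ F.T
    C = 0.5 * (C + C.T)
    return CovarianceMatrix(values=C, centered=False, divisor=quadrature_points)


def factor_spectrum(
    factors: Sequence[Factor], quadrature_points: int = 512
) -> FactorSpectrum:
    """Normalized eigenvalues of the factor covariance of one dimension."""
    spec = eigen_spectrum(factor_covariance(factors, quadrature_points))
    return FactorSpectrum(values=spec.values)


def product_population_covariance(
    banks: Sequence[Sequence[Factor]], quadrature_points: int = 256
) -> CovarianceMatrix:
    """Explicit N x N covariance of a full product-code population.

    Every neuron (one factor per dimension, all combinations) is evaluated
    on the full tensor product of Gauss-Legendre grids over [0, 1]^D and
    the pairwise integrals are accumulated directly — no Kronecker
    shortcut — so this is an independent route against which the
    tensor-product spectrum can be checked.  Feasible for small D only.
    """
    D = len(banks)
    n_neurons = math.prod(len(b) for b in banks)
    nodes, weights = np.polynomial.legendre.leggauss(quadrature_points)
    x = 0.5 * (nodes + 1.0)
    w1 = 0.5 * weights
    n_grid = quadrature_points**D
    if n_neurons * n_grid > 2 * 10**8:
        raise ValueError("tensor-grid quadrature too large; reduce D or order")
    # per-dimension factor responses on the 1D grid
    per_dim = [np.stack([f(x) for f in bank], axis=0) for bank in banks]  # (N_d, Q)
    # full response of each neuron on the tensor grid, built dimension by dimension
    F = None
    W = None
    for resp in per_dim:
        if F is None:
            F, W = resp, w1
        else:
            F = (F[:, None, :, None] * resp[None, :, None, :]).reshape(
                F.shape[0] * resp.shape[0], -1
            )
            W = np.outer(W, w1).ravel()
    C = (F * W) @ F.T
    C = 0.5 * (C + C.T)
    return CovarianceMatrix(values=C, centered=False, divisor=n_grid)


@dataclass
class ProductSpectrum:
    """Eigenvalues of a D-fold tensor-product covariance.

    ``mode='explicit'``: ``values`` is the full descending multiset.
    ``mode='histogram'``: ``bin_log2`` are bin centers of log2(eigenvalue),
    with ``counts`` eigenvalues and ``masses`` total eigenvalue mass per
    bin; ``zero_mass_count`` tracks exactly-zero eigenvalues separately.
    Total mass is 1 in both modes (products of normalized factors).
    """

    D: int
    mode: str
    values: np.ndarray | None = None
    bin_log2: np.ndarray | None = None
    counts: np.ndarray | None = None
    masses: np.ndarray | None = None
    zero_mass_count: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def total_count(self) -> float:
        if self.mode == "explicit":
            return float(self.values.size + self.zero_mass_count)
        return float(self.counts.sum() + self.zero_mass_count)

    def total_mass(self) -> float:
        if self.mode == "explicit":
            return float(self.values.sum())
        return float(self.masses.sum())

    @property
    def participation_ratio(self) -> float:
        if self.mode != "explicit":
            raise ValueError("PR is exact only in explicit mode")
        return float(self.values.sum() ** 2 / np.sum(self.values**2))


def _factor_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, float]:
    """(counts, masses, offset_bin, zero_count) of one factor's log2 values;
    bin b holds eigenvalues with round(log2 lam / width) == b + offset."""
    pos = values[values > 0]
    zero_count = values.size - pos.size
    logs = np.log2(pos)
    bins = np.round(logs / HIST_BIN_BITS).astype(np.int64)
    offset = int(bins.min())
    width = int(bins.max()) - offset + 1
    counts = np.zeros(width)
    masses = np.zeros(width)
    np.add.at(counts, bins - offset, 1.0)
    np.add.at(masses, bins - offset, pos)
    return counts, masses, offset, float(zero_count)


def tensor_spectrum(
    factors: FactorSpectrum | Sequence[FactorSpectrum], D: int | None = None
) -> ProductSpectrum:
    """Spectrum of the D-fold tensor product of factor covariances.

    A single FactorSpectrum is reused for all D dimensions (tuning with
    the same functional form along each dimension).  The explicit
    eigenvalue multiset is built when the product population has at most
    ``EXPLICIT_LIMIT`` neurons; beyond that, log2-domain histograms of the
    factor eigenvalues are convolved, carrying counts and masses.
    """
    if isinstance(factors, FactorSpectrum):
        if D is None:
            raise ValueError("D is required when one factor is reused")
        factor_list = [factors] * D
    else:
        factor_list = list(factors)
        if D is not None and D != len(factor_list):
            raise ValueError(f"D={D} but {len(factor_list)} factor spectra given")
        D = len(factor_list)
    if D < 1:
        raise ValueError("D must be >= 1")

    n_total = math.prod(f.values.size for f in factor_list)
    if n_total <= EXPLICIT_LIMIT:
        vals = factor_list[0].values
        for f in factor_list[1:]:
            vals = np.outer(vals, f.values).ravel()
        vals = np.sort(vals)[::-1]
        return ProductSpectrum(D=D, mode="explicit", values=vals)

    counts, masses, offset, zeros_frac = None, None, 0, 0.0
    nonzero_counts = []
    for f in factor_list:
        c, m, off, z = _factor_histogram(f.values)
        nonzero_counts.append(f.values.size - z)
        if counts is None:
            counts, masses, offset = c, m, off
        else:
            counts = np.convolve(counts, c)
            masses = np.convolve(masses, m)
            offset += off
        # a zero in any factor makes the whole product zero
    total = math.prod(f.values.size for f in factor_list)
    nonzero_total = math.prod(nonzero_counts)
    bin_log2 = (np.arange(counts.size) + offset) * HIST_BIN_BITS
    return ProductSpectrum(
        D=D,
        mode="histogram",
        bin_log2=bin_log2,
        counts=counts,
        masses=masses,
        zero_mass_count=float(total - nonzero_total),
        meta={"bin_bits": HIST_BIN_BITS},
    )


def linear_dimension_product(ps: ProductSpectrum, epsilon: float) -> DimensionReport:
    """Linear dimension of a product spectrum.

    Explicit mode counts the minimal descending prefix.  Histogram mode
    accumulates bins in descending eigenvalue order and counts the
    crossing bin in full (error at most one bin's occupancy, mirroring
    whole-shell counting for lattice spectra).
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if ps.mode == "explicit":
        vals = ps.values
        total = float(vals.sum())
        cum = np.cumsum(vals)
        L = int(np.searchsorted(cum, (1.0 - epsilon) * total - 1e-12 * total) + 1)
        pr = ps.participation_ratio
        extras = {}
    else:
        # descending eigenvalue = descending log2 bin
        order = slice(None, None, -1)
        masses = ps.masses[order]
        counts = ps.counts[order]
        total = float(masses.sum())
        cum = np.cumsum(masses)
        idx = int(np.searchsorted(cum, (1.0 - epsilon) * total - 1e-12 * total))
        L = int(round(float(counts[: idx + 1].sum())))
        lam = 2.0 ** ps.bin_log2[order]
        pr = float(masses.sum() ** 2 / np.sum(lam * masses))
        extras = {"crossing_bin_occupancy": float(counts[idx])}
    return DimensionReport(
        epsilon=epsilon,
        L=L,
        participation_ratio=pr,
        source="analytic_product",
        extras=extras,
    )


@dataclass
class AEPBound:
    """Entropy-based estimates of product-code linear dimension."""

    estimate: float  # 2^(D H)
    lower_bound: float  # 2^(D (H - delta)), the plotted asymptotic bound
    entropy: float
    D: int
    delta: float


def aep_estimate(
    factors: FactorSpectrum | Sequence[FactorSpectrum],
    D: int | None = None,
    delta: float = 0.05,
) -> AEPBound:
    """Asymptotic-equipartition estimate of L for a product code.

    The high-probability set of D i.i.d. factors has ~2^(D H) outcomes,
    H the per-factor eigenvalue entropy in bits; for mixed factors H is
    the average factor entropy.  ``lower_bound`` is the 2^(D (H - delta))
    variant (asymptotically a bound for any delta > 0).
    """
    if isinstance(factors, FactorSpectrum):
        if D is None:
            raise ValueError("D is required when one factor is reused")
        H = factors.entropy
    else:
        if D is not None and D != len(factors):
            raise ValueError("D disagrees with the factor list length")
        D = len(factors)
        H = float(np.mean([f.entropy for f in factors]))
    return AEPBound(
        estimate=2.0 ** (D * H),
        lower_bound=2.0 ** (D * (H - delta)),
        entropy=H,
        D=D,
        delta=delta,
    )


def _binary_entropy(rho: float) -> float:
    if rho <= 0.0 or rho >= 1.0:
        return 0.0
    return float(-rho * math.log2(rho) - (1.0 - rho) * math.log2(1.0 - rho))


#: floor on rho keeping the prefactor finite in the degenerate regime
RHO_FLOOR = 1e-6


def binomial_lower_bound(gamma: float, D: int, epsilon: float) -> TheoryBound:
    """Nonasymptotic lower bound on L for two-eigenvalue factors {1-g, g}.

    The product spectrum is binomial, and binomial-coefficient sums give

        L >= 1/(8 rho (1-rho)) * 2^((Hb(rho) - log2(D)/(2D)) * D),

    with rho >= gamma - (1 + ln 2)/D and Hb the binary entropy.  Valid
    for eps <= 0.5 and gamma <= 0.5; when Hb(rho) < log2(D)/(2D) the bound
    degenerates and the trivial value 1 is returned.
    """
    if epsilon > 0.5:
        raise ValueError("bound is valid only for epsilon <= 0.5")
    if not 0.0 < gamma <= 0.5:
        raise ValueError("gamma must lie in (0, 0.5]")
    if D < 1:
        raise ValueError("D must be >= 1")
    rho = max(gamma - (1.0 + math.log(2.0)) / D, RHO_FLOOR)
    Hb = _binary_entropy(rho)
    penalty = math.log2(D) / (2.0 * D)
    if Hb < penalty:
        return TheoryBound(
            kind="binomial",
            value=1.0,
            validity="degenerate regime (Hb(rho) < log2(D)/(2D)): trivial bound",
            params={"gamma": gamma, "D": D, "rho": rho, "Hb": Hb},
        )
    log2_value = -math.log2(8.0 * rho * (1.0 - rho)) + (Hb - penalty) * D
    value = 2.0**log2_value if log2_value < 1000 else math.inf
    return TheoryBound(
        kind="binomial",
        value=value,
        validity="eps <= 0.5, gamma <= 0.5",
        params={"gamma": gamma, "D": D, "rho": rho, "Hb": Hb,
                "log2_value": log2_value},
    )


def exact_binomial_L(gamma: float, D: int, epsilon: float) -> float:
    """Exact high-probability-set size for the binomial product spectrum:
    outcomes k = 0..D carry probability C(D,k) (1-g)^(D-k) g^k each of
    per-outcome magnitude (1-g)^(D-k) g^k; count outcomes in descending
    magnitude until mass 1 - eps.  Independent enumeration oracle for
    :func:`binomial_lower_bound`."""
    if not 0.0 < gamma <= 0.5:
        raise ValueError("gamma must lie in (0, 0.5]")
    k = np.arange(D + 1)
    pmf = stats.binom.pmf(k, D, gamma)
    # per-outcome magnitude decreases with k for gamma <= 0.5
    cum = np.cumsum(pmf)
    idx = int(np.searchsorted(cum, (1.0 - epsilon) - 1e-12))
    counts = np.exp(
        [math.lgamma(D + 1) - math.lgamma(j + 1) - math.lgamma(D - j + 1) for j in k]
    )
    return float(np.sum(counts[: idx + 1]))


def dirichlet_factor(alpha: float, N_d: int, seed: int | None = None) -> FactorSpectrum:
    """Model-agnostic factor: one draw of N_d eigenvalues from a symmetric
    Dirichlet(alpha), sorted descending (sums to 1 by construction)."""
    if alpha <= 0:
        raise ValueError("concentration parameter must be positive")
    rng = np.random.default_rng(seed)
    vals = rng.dirichlet(np.full(N_d, alpha))
    return FactorSpectrum(values=vals, meta={"alpha": alpha, "seed": seed})
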