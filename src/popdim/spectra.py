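"""Covariance spectra and linear-dimension statistics.

The central quantity is the (1-eps)-linear dimension L of a data matrix:
the smallest number of principal components (equivalently, eigenvalues of
the neuron-neuron covariance) whose variance sums to a fraction 1-eps of
the total.  This is the standard "number of PCs to explain X% variance"
criterion of neural data analysis, made precise.

Covariances are *non-mean-subtracted* by default: c(m, n) = E[y_m y_n].
Centered covariances are supported for the mean-subtraction bound, which
states that the centered linear dimension is at least L - 1 of the raw
one (a Weyl-inequality consequence of centering being a rank-one update).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .populations import PopulationResponseMatrix

__all__ = [
    "CovarianceMatrix",
    "EigenSpectrum",
    "DimensionReport",
    "covariance",
    "eigen_spectrum",
    "linear_dimension",
    "participation_ratio",
    "mean_subtraction_bound_check",
]

#: eigenvalues more negative than -NEG_EIG_RTOL * lambda_max signal a bug
NEG_EIG_RTOL = 1e-10


@dataclass
class CovarianceMatrix:
    """N x N symmetric PSD covariance with its construction metadata."""

    values: np.ndarray
    centered: bool
    divisor: int

    @property
    def N(self) -> int:
        return self.values.shape[0]


@dataclass
class EigenSpectrum:
    """Descending nonnegative eigenvalues (squared singular values of A)."""

    values: np.ndarray
    source: str = "empirical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def normalized(self) -> np.ndarray:
        """Eigenvalues as fractions of variance (sum to 1)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.values / tot


@dataclass
class DimensionReport:
    """Linear-dimension summary of one spectrum.

    ``L`` is the minimal count of leading eigenvalues reaching mass 1-eps;
    ``L_conservative = L - 1`` is the variant robust to finite-size effects
    and to mean subtraction, used when comparing against saturating
    empirical estimates.
    """

    epsilon: float
    L: int
    participation_ratio: float
    source: Literal[
        "empirical", "analytic_translation", "analytic_product"
    ] = "empirical"
    extras: dict = field(default_factory=dict)

    @property
    def L_conservative(self) -> int:
        return self.L - 1


def covariance(
    A: PopulationResponseMatrix | np.ndarray, centered: bool = False
) -> CovarianceMatrix:
    """Neuron-neuron covariance (A A^T) / T, optionally mean-subtracted.

    The divisor is T (a plain expectation over latent samples), not T-1:
    spectra are only ever used as fractions of total variance.
    """
    values = A.values if isinstance(A, PopulationResponseMatrix) else np.asarray(A, float)
    if values.size == 0:
        raise ValueError("empty activity matrix")
    if values.ndim != 2:
        raise ValueError(f"activity matrix must be 2D, got shape {values.shape}")
    T = values.shape[1]
    if centered:
        values = values - values.mean(axis=1, keepdims=True)
    C = (values @ values.T) / T
    C = 0.5 * (C + C.T)  # symmetrize away roundoff
    return CovarianceMatrix(values=C, centered=centered, divisor=T)


def eigen_spectrum(C: CovarianceMatrix | np.ndarray) -> EigenSpectrum:
    """Descending eigenvalues of a symmetric PSD matrix.

    Small negative eigenvalues (roundoff) are clipped to zero; negatives
    beyond ``NEG_EIG_RTOL`` of the largest eigenvalue raise, because they
    signal a non-PSD construction upstream rather than noise.
    """
    M = C.values if isinstance(C, CovarianceMatrix) else np.asarray(C, float)
    if not np.allclose(M, M.T, rtol=1e-8, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("matrix is not symmetric within tolerance")
    vals = np.linalg.eigvalsh(M)[::-1].copy()
    lam_max = vals[0] if vals.size else 0.0
    tol = NEG_EIG_RTOL * max(lam_max, 1.0)
    if vals.size and vals[-1] < -tol:
        raise ValueError(
            f"eigenvalue {vals[-1]:.3e} is negative beyond tolerance "
            f"{-tol:.3e}: covariance is not PSD"
        )
    np.clip(vals, 0.0, None, out=vals)
    return EigenSpectrum(values=vals)


def linear_dimension(
    spec: EigenSpectrum | np.ndarray, epsilon: float, source: str = "empirical"
) -> DimensionReport:
    """Smallest L with sum of the top-L eigenvalues >= (1-eps) of the total."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if not isinstance(spec, EigenSpectrum):
        spec = EigenSpectrum(np.sort(np.asarray(spec, float))[::-1])
    vals = np.sort(spec.values)[::-1]
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("all-zero spectrum has no linear dimension")
    cum = np.cumsum(vals)
    L = int(np.searchsorted(cum, (1.0 - epsilon) * total - 1e-12 * total) + 1)
    return DimensionReport(
        epsilon=epsilon,
        L=L,
        participation_ratio=participation_ratio(spec),
        source=source,  # type: ignore[arg-type]
    )


def participation_ratio(spec: EigenSpectrum | np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 — scale-invariant spread of the spectrum."""
    vals = spec.values if isinstance(spec, EigenSpectrum) else np.asarray(spec, float)
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("all-zero spectrum has no participation ratio")
    return float(total**2 / np.sum(vals**2))


def mean_subtraction_bound_check(
    A: PopulationResponseMatrix | np.ndarray, epsilon: float
) -> tuple[int, int, bool]:
    """Compare linear dimension before and after mean subtraction.

    Returns (L_raw, L_centered, bound_holds) where the bound is
    L_centered >= L_raw - 1.  A population whose centered activity is
    exactly zero (constant rates) has L_centered = 0.
    """
    spec_raw = eigen_spectrum(covariance(A, centered=False))
    L_raw = linear_dimension(spec_raw, epsilon).L
    spec_cen = eigen_spectrum(covariance(A, centered=True))
    if spec_cen.total <= 1e-14 * max(spec_raw.total, 1.0):
        L_cen = 0
    else:
        L_cen = linear_dimension(spec_cen, epsilon).L
    return L_raw, L_cen, L_cen >= L_raw - 1
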