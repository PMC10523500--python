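"""Synthetic neural populations with parameterized tuning curves.

This module generates the N x T activity matrices that every downstream
spectral analysis consumes.  Two families of population codes are
implemented:

* **translation-symmetric Gaussian tuning** — every neuron responds with
  the same Gaussian bump, shifted to its own preferred value (tuning
  center) of a D-dimensional latent variable on the unit hypercube, with
  periodic or open boundaries.  This is the standard model for place
  cells, orientation-tuned cells, head-direction cells, etc.
* **multiplicative (product) tuning** — each neuron's tuning curve is a
  product of one-dimensional factors, one per latent dimension
  (sigmoids with assorted slopes, Gaussians with position-dependent
  widths, or a mixture).  This captures gain modulation, separable
  spatiotemporal receptive fields and similar codes.

Responses are noise-free firing rates: the geometry under study is that
of the mean-rate manifold itself, and noise could only increase the
measured linear dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "LatentSpace",
    "CenterGrid",
    "TuningSpec",
    "PopulationResponseMatrix",
    "SigmoidFactor",
    "GaussianFactor",
    "make_center_grid",
    "gaussian_tuning_response",
    "sigmoid_factor_response",
    "varwidth_gaussian_factor_response",
    "product_tuning_response",
    "simulate_population",
    "sigmoid_factor_bank",
    "varwidth_gaussian_factor_bank",
    "hybrid_factor_banks",
    "varwidth_profile",
    "save_population",
    "load_population",
]

Boundary = Literal["periodic", "open"]

#: refuse center grids larger than this (N = N_d ** D neurons)
MAX_GRID_SIZE = 10**7


@dataclass(frozen=True)
class LatentSpace:
    """D-dimensional latent domain: the unit hypercube [0, 1]^D."""

    D: int
    boundary: Boundary = "periodic"

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError(f"intrinsic dimension must be >= 1, got {self.D}")
        if self.boundary not in ("periodic", "open"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Boundary-respecting Euclidean distance between points.

        Broadcasts over leading axes; the trailing axis is the coordinate
        axis of length D.  With periodic boundaries each coordinate
        difference is wrapped onto [0, 0.5].
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape[-1] != self.D or b.shape[-1] != self.D:
            raise ValueError(
                f"points must have {self.D} coordinates, "
                f"got shapes {a.shape} and {b.shape}"
            )
        diff = np.abs(a - b)
        if self.boundary == "periodic":
            diff = np.minimum(diff, 1.0 - diff)
        return np.sqrt(np.sum(diff**2, axis=-1))


@dataclass(frozen=True)
class CenterGrid:
    """Tuning-curve centers tiling the latent domain.

    ``centers`` is an (N, D) array; for grid-structured populations
    N = N_d ** D with the same per-dimension count N_d.
    """

    centers: np.ndarray
    N_d: int
    D: int
    spacing: Literal["even", "random"]
    boundary: Boundary

    @property
    def N(self) -> int:
        return self.centers.shape[0]


def make_center_grid(
    D: int,
    N_d: int,
    spacing: Literal["even", "random"] = "even",
    boundary: Boundary = "periodic",
    seed: int | None = None,
) -> CenterGrid:
    """Build the lattice (or random cloud) of N_d**D tuning centers.

    With ``even`` spacing and periodic boundaries the per-coordinate
    centers are k / N_d for k = 0..N_d-1, so consecutive wrap-around gaps
    are all equal.  With open boundaries the endpoints are included
    (linspace over [0, 1]).  ``random`` draws i.i.d. uniform centers.
    """
    if N_d < 2:
        raise ValueError(f"need at least 2 centers per dimension, got {N_d}")
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    n_total = N_d**D
    if n_total > MAX_GRID_SIZE:
        raise ValueError(
            f"grid of {N_d}**{D} = {n_total} centers exceeds the safe size "
            f"bound {MAX_GRID_SIZE}; use the analytic lattice spectrum instead"
        )
    if spacing == "even":
        if boundary == "periodic":
            axis = np.arange(N_d) / N_d
        else:
            axis = np.linspace(0.0, 1.0, N_d)
        mesh = np.meshgrid(*([axis] * D), indexing="ij")
        centers = np.stack([m.ravel() for m in mesh], axis=-1)
    elif spacing == "random":
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0.0, 1.0, size=(n_total, D))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return CenterGrid(centers=centers, N_d=N_d, D=D, spacing=spacing, boundary=boundary)


# ---------------------------------------------------------------------------
# tuning-curve primitives
# ---------------------------------------------------------------------------


def gaussian_tuning_response(
    x: np.ndarray,
    center: np.ndarray,
    sigma: float,
    space: LatentSpace,
    peak_rate: float = 1.0,
) -> np.ndarray:
    """Translation-symmetric Gaussian bump: K1 * exp(-d(x, center)^2 / (2 sigma^2)).

    ``d`` is the boundary-respecting Euclidean distance, so with periodic
    boundaries the bump wraps around the domain.  Symmetric in (x, center).
    """
    if sigma <= 0:
        raise ValueError(f"tuning width must be positive, got {sigma}")
    d = space.distance(x, center)
    return peak_rate * np.exp(-(d**2) / (2.0 * sigma**2))


def sigmoid_factor_response(x: np.ndarray, mu: float, s: float) -> np.ndarray:
    """Logistic factor 1 / (1 + exp(-s (x - mu))), monotone in x for s > 0."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-s * (x - mu)))


def varwidth_gaussian_factor_response(
    x: np.ndarray, mu: float, width: float
) -> np.ndarray:
    """Gaussian factor exp(-(x - mu)^2 / (2 width^2)) with open boundary."""
    if width <= 0:
        raise ValueError(f"factor width must be positive, got {width}")
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - mu) ** 2) / (2.0 * width**2))


@dataclass(frozen=True)
class SigmoidFactor:
    """One sigmoidal 1D factor: center mu and slope s."""

    mu: float
    slope: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return sigmoid_factor_response(x, self.mu, self.slope)


@dataclass(frozen=True)
class GaussianFactor:
    """One Gaussian 1D factor with its own width (open boundary)."""

    mu: float
    width: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return varwidth_gaussian_factor_response(x, self.mu, self.width)


Factor = Callable[[np.ndarray], np.ndarray]


def product_tuning_response(
    x: np.ndarray, factors: Sequence[Factor], peak_rate: float = 1.0
) -> np.ndarray:
    """Multiplicative tuning: product of one factor response per dimension.

    ``x`` has trailing axis of length D = len(factors).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(factors):
        raise ValueError(
            f"point has {x.shape[-1]} coordinates but {len(factors)} factors given"
        )
    out = np.ones(x.shape[:-1], dtype=float)
    for d, f in enumerate(factors):
        out = out * f(x[..., d])
    return peak_rate * out


# ---------------------------------------------------------------------------
# standard factor banks (the concrete multiplicative models studied)
# ---------------------------------------------------------------------------


def varwidth_profile(
    n: int = 8, w_min: float = 0.05, step: float = 0.05, w_max: float = 0.2
) -> np.ndarray:
    """Widths for the variable-width Gaussian bank: sharpest at the center.

    The minimum width sits at the centermost tuning centers and increases
    in fixed steps toward the ends of [0, 1], capped at ``w_max`` — e.g.
    for n=8: (0.2, 0.15, 0.1, 0.05, 0.05, 0.1, 0.15, 0.2).
    """
    half = (n - 1) / 2.0
    # integer number of steps away from the center position
    k = np.ceil(np.abs(np.arange(n) - half)).astype(int) - (1 if n % 2 == 0 else 0)
    widths = w_min + step * np.maximum(k, 0)
    return np.minimum(widths, w_max)


def sigmoid_factor_bank(n: int = 8, slope_range: tuple[float, float] = (-5.0, 5.0)) -> list[SigmoidFactor]:
    """n sigmoids with centers evenly spaced in [0, 1] and slopes evenly
    spaced over ``slope_range`` (endpoints included; for even n none is 0)."""
    mus = np.linspace(0.0, 1.0, n)
    slopes = np.linspace(slope_range[0], slope_range[1], n)
    return [SigmoidFactor(mu, s) for mu, s in zip(mus, slopes)]


def varwidth_gaussian_factor_bank(n: int = 8) -> list[GaussianFactor]:
    """n Gaussians with centers evenly spaced in [0, 1] and the symmetric
    sharp-in-the-middle width profile of :func:`varwidth_profile`."""
    mus = np.linspace(0.0, 1.0, n)
    widths = varwidth_profile(n)
    return [GaussianFactor(mu, w) for mu, w in zip(mus, widths)]


def hybrid_factor_banks(D: int, n: int = 8) -> list[list[Factor]]:
    """Per-dimension factor banks for the hybrid model: sigmoidal factors on
    even dimensions, variable-width Gaussian factors on odd dimensions."""
    banks: list[list[Factor]] = []
    for d in range(D):
        if d % 2 == 0:
            banks.append(list(sigmoid_factor_bank(n)))
        else:
            banks.append(list(varwidth_gaussian_factor_bank(n)))
    return banks


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


@dataclass
class TuningSpec:
    """Parameterization of a tuning-curve family.

    family='gaussian_translation' uses ``sigma`` and ``space``;
    family='product' uses ``factor_banks`` (one list of N_d factors per
    dimension — neurons take all combinations, one factor per dimension).
    """

    family: Literal["gaussian_translation", "product"]
    sigma: float | None = None
    space: LatentSpace | None = None
    factor_banks: list[list[Factor]] | None = None
    peak_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.family == "gaussian_translation":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian_translation requires a positive sigma")
            if self.space is None:
                raise ValueError("gaussian_translation requires a LatentSpace")
        elif self.family == "product":
            if not self.factor_banks:
                raise ValueError("product tuning requires factor banks")
        else:
            raise ValueError(f"unknown tuning family {self.family!r}")


@dataclass
class PopulationResponseMatrix:
    """N x T matrix of firing rates plus full provenance.

    values[n, t] is the rate of neuron n at latent sample t; reproducible
    bit-for-bit from (tuning, grid, sampler, seed).
    """

    values: np.ndarray
    tuning: TuningSpec
    latents: np.ndarray
    grid: CenterGrid | None = None
    sampler: str = "uniform_random"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


def _sample_latents(
    D: int, T: int, sampler: str, seed: int | None, grid: CenterGrid
) -> np.ndarray:
    if sampler == "uniform_random":
        rng = np.random.default_rng(seed)
        return rng.uniform(0.0, 1.0, size=(T, D))
    if sampler == "lattice":
        # deterministic: cycle through the center lattice itself
        reps = int(np.ceil(T / grid.N))
        tiled = np.tile(grid.centers, (reps, 1))
        return tiled[:T]
    raise ValueError(f"unknown sampler {sampler!r}")


def simulate_population(
    tuning: TuningSpec,
    grid: CenterGrid,
    T: int,
    sampler: Literal["uniform_random", "lattice"] = "uniform_random",
    seed: int | None = None,
) -> PopulationResponseMatrix:
    """Simulate noise-free rates of the whole population at T latent samples.

    Row n is the tuning curve of neuron n evaluated at the T sampled latent
    values.  For product tuning, neuron n with lattice index (i_1..i_D)
    uses factor i_d of bank d.
    """
    if T < 1:
        raise ValueError(f"need at least one latent sample, got T={T}")
    if grid.N < 1:
        raise ValueError("empty center grid")
    latents = _sample_latents(grid.D, T, sampler, seed, grid)

    if tuning.family == "gaussian_translation":
        space = tuning.space
        assert space is not None and tuning.sigma is not None
        # (N, T) distances via broadcasting: centers (N,1,D) vs latents (1,T,D)
        d = space.distance(grid.centers[:, None, :], latents[None, :, :])
        values = tuning.peak_rate * np.exp(-(d**2) / (2.0 * tuning.sigma**2))
    else:
        banks = tuning.factor_banks
        assert banks is not None
        if len(banks) != grid.D:
            raise ValueError(
                f"{len(banks)} factor banks for a {grid.D}-dimensional grid"
            )
        for bank in banks:
            if len(bank) != grid.N_d:
                raise ValueError("factor count per dimension must equal N_d")
        # evaluate each bank on its latent coordinate, then combine per neuron
        per_dim = [
            np.stack([f(latents[:, d]) for f in bank], axis=0)  # (N_d, T)
            for d, bank in enumerate(banks)
        ]
        idx = np.stack(
            np.meshgrid(*[np.arange(grid.N_d)] * grid.D, indexing="ij"), axis=-1
        ).reshape(-1, grid.D)
        values = np.ones((grid.N, T), dtype=float)
        for d in range(grid.D):
            values *= per_dim[d][idx[:, d]]
        values *= tuning.peak_rate

    return PopulationResponseMatrix(
        values=values,
        tuning=tuning,
        latents=latents,
        grid=grid,
        sampler=sampler,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# text serialization: CSV matrix + JSON sidecar
# ---------------------------------------------------------------------------


def _tuning_to_dict(t: TuningSpec) -> dict:
    d: dict = {"family": t.family, "peak_rate": t.peak_rate}
    if t.family == "gaussian_translation":
        assert t.space is not None
        d["sigma"] = t.sigma
        d["D"] = t.space.D
        d["boundary"] = t.space.boundary
    else:
        banks = []
        assert t.factor_banks is not None
        for bank in t.factor_banks:
            entries = []
            for f in bank:
                if isinstance(f, SigmoidFactor):
                    entries.append({"kind": "sigmoid", "mu": f.mu, "slope": f.slope})
                elif isinstance(f, GaussianFactor):
                    entries.append({"kind": "gaussian_varwidth", "mu": f.mu, "width": f.width})
                else:
                    raise TypeError("only SigmoidFactor/GaussianFactor serialize")
            banks.append(entries)
        d["factor_banks"] = banks
    return d


def _tuning_from_dict(d: dict) -> TuningSpec:
    if d["family"] == "gaussian_translation":
        return TuningSpec(
            family="gaussian_translation",
            sigma=d["sigma"],
            space=LatentSpace(D=d["D"], boundary=d["boundary"]),
            peak_rate=d["peak_rate"],
        )
    banks: list[list[Factor]] = []
    for bank in d["factor_banks"]:
        fs: list[Factor] = []
        for e in bank:
            if e["kind"] == "sigmoid":
                fs.append(SigmoidFactor(e["mu"], e["slope"]))
            else:
                fs.append(GaussianFactor(e["mu"], e["width"]))
        banks.append(fs)
    return TuningSpec(family="product", factor_banks=banks, peak_rate=d["peak_rate"])


def save_population(pop: PopulationResponseMatrix, path: str | Path) -> None:
    """Write the rate matrix as CSV (neurons x time) plus a JSON sidecar
    with tuning, grid, sampler and seed; lossless to 15 significant digits."""
    path = Path(path)
    np.savetxt(path, pop.values, delimiter=",", fmt="%.17g")
    sidecar = {
        "tuning": _tuning_to_dict(pop.tuning),
        "sampler": pop.sampler,
        "seed": pop.seed,
        "shape": list(pop.values.shape),
        "latents": [[float(v) for v in row] for row in pop.latents],
    }
    if pop.grid is not None:
        sidecar["grid"] = {
            "N_d": pop.grid.N_d,
            "D": pop.grid.D,
            "spacing": pop.grid.spacing,
            "boundary": pop.grid.boundary,
            "centers": [[float(v) for v in row] for row in pop.grid.centers],
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_population(path: str | Path) -> PopulationResponseMatrix:
    """Inverse of :func:`save_population`."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = None
    if "grid" in sidecar:
        g = sidecar["grid"]
        grid = CenterGrid(
            centers=np.asarray(g["centers"], dtype=float),
            N_d=g["N_d"],
            D=g["D"],
            spacing=g["spacing"],
            boundary=g["boundary"],
        )
    return PopulationResponseMatrix(
        values=values,
        tuning=_tuning_from_dict(sidecar["tuning"]),
        latents=np.asarray(sidecar["latents"], dtype=float),
        grid=grid,
        sampler=sidecar["sampler"],
        seed=sidecar["seed"],
    )
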