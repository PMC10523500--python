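# Methods

## Model and assumptions

The package studies noise-free rate models y_n(t) = f(x(t), α_n): a
population of N neurons driven by a D-dimensional latent variable x on
the unit hypercube, sampled uniformly.  Noise is deliberately absent —
the object of study is the geometry of the mean-rate manifold itself, and
any additive noise can only raise the measured linear dimension, so all
lower bounds computed here transfer to noisy data.  Two families are
implemented:

* **Translation-symmetric Gaussian tuning** (periodic or open
  boundaries): identical Gaussian bumps of width σ, centers tiling the
  domain.  The periodic Gaussian is the plain Gaussian of the wrapped
  distance, *not* a wrapped-Gaussian (theta-function) sum.  This matters:
  the wrapped-distance profile exp(−δ²/4σ²) is not positive definite on
  the circle once σ is large enough for the kink at δ = 0.5 to carry
  weight.  At σ = 0.15, N = 50 the circulant built from it has a genuine
  −0.10 eigenvalue, and the Fourier-Gaussian spectrum
  λ_p = exp(−4π²σ²p²) deviates from the sampled-profile DFT by 5.7%
  already at p = 1.  The closed forms are therefore treated as valid for
  narrow tuning (σ ≲ 0.1 on the unit domain with these grids); the exact
  alternative at any width is `quadrature_profile`, the true correlation
  profile c(δ) = ∫ g g dx computed by midpoint quadrature (8192 points,
  spectrally accurate for periodic smooth integrands), whose DFT matches
  seeded simulations within ~1.7% at T = 10⁴ for every width in
  {0.075, 0.1, 0.15, 0.2}.
* **Multiplicative tuning**: products of 1D factors, one per latent
  dimension.  The concrete banks mirror common receptive-field models:
  8 sigmoids per dimension with centers evenly spaced in [0, 1]
  (endpoints included) and slopes evenly spaced in [−5, 5] (endpoints
  included, so none is exactly 0), paired center-to-slope in order; 8
  Gaussians with the same centers and widths 0.05–0.2 in steps of 0.05
  assigned symmetrically about the middle of the domain as
  (0.2, 0.15, 0.1, 0.05, 0.05, 0.1, 0.15, 0.2) — sharpest tuning at the
  center of stimulus space, as in foveal vision.  Two symmetric
  assignments are consistent with "minimum at the center, increasing in
  steps toward the ends" for 8 centers; this one is fixed as the default.
  Hybrid populations interleave the two kinds by dimension parity (even
  dimensions sigmoidal, odd Gaussian), a concrete reading of "equal
  mixture".

## Key statistics

* **(1−ϵ)-linear dimension L**: minimal count of descending covariance
  eigenvalues reaching a 1−ϵ fraction of total variance.  Default
  ϵ = 0.05 for translation-symmetric analyses and 0.1 for product codes.
  Reports carry both L and the conservative L−1; comparisons between
  empirical (population-limited) and analytic values use L−1 semantics
  where saturation effects matter.
* **Participation ratio** (Σλ)²/Σλ²: scale-invariant, between 1 and the
  spectrum length, exactly multiplicative across tensor factors.
* **Mean-subtraction bound**: centering the data is a rank-one
  perturbation of the covariance, so (by Weyl interlacing)
  L_centered ≥ L_raw − 1; checked on every simulated fixture.

## Analytic spectra

* **1D circulant route**: even periodic center grids give circulant
  covariances; eigenvalues are the DFT of the correlation profile.
  `circulant_eigenvalues` reports the matrix spectrum exactly as the
  dense eigendecomposition would (including small negative values for
  non-positive-definite idealized profiles — see above), which keeps the
  FFT and dense routes interchangeable to 1e−8 relative.
* **Multi-D lattice route**: eigenvalues exp(−4π²σ²m) at integer squared
  radii m = |p|², with multiplicities obtained by D-fold convolution of
  the per-dimension histogram of p_d² (frequencies follow the standard
  DFT convention, Nyquist counted once for even N_d) — never by
  enumerating the N_d^D lattice.  Multiplicities stay below 2^53, so
  float64 convolution is exact; the expansion to an explicit multiset is
  available below 10⁷ eigenvalues for oracle tests.
* **Whole-shell counting**: the shell crossing the 1−ϵ threshold is
  counted in full.  Eigenvalues within a shell are exactly degenerate, so
  a minimal-L rule would split ties arbitrarily; whole-shell counting is
  deterministic and overshoots by less than one shell's multiplicity
  (recorded in the report's `extras`).
* **Truncation guard**: using a finite lattice for the infinite-frequency
  theory requires the largest dropped eigenvalue below 1e−12 (counting
  error ≪ 1 eigenvalue for ϵ ≥ 0.01).  The guard is enforced where it
  matters — in `linear_dimension_lattice` — not in `radial_spectrum`,
  whose output is exact for the finite population as such;
  `min_lattice_size(sigma)` returns the smallest compliant N_d.
* **Chi bounds**: the Fourier-space Gaussian has width s = 1/(2√2 πσ)
  per axis; the radius enclosing a mass fraction q is s·√(χ²_D(q)).
  The median (q = 1/2) gives a true lower bound on L for ϵ ≤ 0.5 and
  D > 1; q = 1−ϵ gives the semianalytic fit.  Quantiles use the exact
  chi-squared quantile function, not the (D − 2/3) approximation.
* **Smooth interpolation**: rank p maps to radius r(p) = (p/V_D)^{1/D}
  (V_D the unit-ball volume) and λ(p) = exp(−4π²σ²r(p)²); at shell
  boundaries the curve lies within a factor two of the bracketing step
  values for D ≤ 4.  The interpolation is derived from this inverse
  ball-volume construction directly.

## Product-code machinery

* **Factor covariances** use fixed-order Gauss–Legendre quadrature on
  [0, 1] (default order 512; the Gram form F·diag(w)·Fᵀ is PSD by
  construction and the integrands are smooth, so quadrature error is far
  below eigenvalue tolerances).
* **Tensor spectra** are explicit multisets up to 10⁶ eigenvalues;
  beyond that, log₂-domain histograms (bin width 0.01 bits) of factor
  eigenvalues are convolved D times, carrying per-bin counts and masses
  (mass convolution is exact for products of factor masses).  Zero
  eigenvalues are excluded from the histograms with their count tracked
  separately.  Linear dimension in histogram mode counts the crossing
  bin in full, mirroring whole-shell counting; cross-checks against
  explicit enumeration agree within ≤ 2% in L (< 0.003 bits).
* **Binomial bound** (two-eigenvalue factors {1−γ, γ}): computed in the
  log₂ domain with ρ = max(γ − (1+ln 2)/D, 10⁻⁶); the 10⁻⁶ floor keeps
  the prefactor finite in the degenerate regime where
  H_b(ρ) < log₂(D)/(2D) and the trivial bound 1 is returned anyway.
  The exact comparator enumerates binomial outcome classes directly.
* **AEP estimates**: 2^{DH} with the plotted lower-bound variant
  2^{D(H−0.05)}; mixed factors use the average factor entropy.  The
  finite-D excess of log₂L/D over H is the varentropy (CLT) correction,
  of order σ_V·z_{1−ϵ}/√D: for Dirichlet(1) factors over 8 states it
  measures +0.02 to +0.22 bits at D = 12 depending on the draw, is not
  monotone in D for low-varentropy draws, and only vanishes
  asymptotically.  Tests therefore assert a verified band
  (offset ∈ (−0.05, 0.35) bits) and the 2^{D(H−0.05)} inequality rather
  than a fixed convergence rate.

## Synthetic data: what it does and does not emulate

The simulator reproduces the idealized study conditions: 50 neurons on an
even periodic grid with 10⁴ uniform latent samples for 1D analyses;
8–10 centers per dimension for multi-D lattices; 8 factors per dimension
for product codes; all rates noise-free in [0, K₁] with K₁ = 1 (spectra
are reported as variance fractions, so the rate scales K₁, K₂, K₃ are
nuisance constants).  It does not emulate spiking or Poisson
variability, trial structure, calcium dynamics, non-uniform latent
distributions, heterogeneous tuning shapes within a population, or
inhomogeneous center densities.  Passing tests therefore certify the
geometry of ideal rate manifolds — the theory's object — not robustness
of the statistics to biological noise.

## Numerical conventions

Covariance divisor is T (plain expectation), not T−1.  Empirical
eigenvalues more negative than 1e−10·λ_max raise (a non-PSD construction
is a bug, not noise); smaller negatives clip to zero.  Eigenvalue ties
are left in arbitrary order among equals — L depends only on sorted
magnitudes.  Threshold comparisons subtract a 1e−12 relative guard so
exact ties (e.g. ten equal eigenvalues at ϵ = 0.05) resolve
deterministically.  Center grids refuse N_d^D > 10⁷.  All randomness
flows through `numpy.random.default_rng(seed)`; experiments are
byte-identical under a fixed (config, seed).

## Problem sizes

Default experiment tables run in seconds on one core: T = 10⁴ latent
samples, N ≤ 50 neurons empirically; lattice theory to D = 8 with N_d up
to 32 (multiplicity convolutions of length ≲ 2·10³); product codes to
D ≈ 14 via histograms (≲ 10⁵ bins).  These sizes suffice because every
analytic route is exact and the empirical routes converge at the
Monte-Carlo rate with errors ~1% at T = 10⁴.

## Known limitations

Open-boundary (Toeplitz) spectra are handled only numerically; no
wrapped-Gaussian/von Mises closed forms; the Fourier-Gaussian closed
forms degrade for σ ≳ 0.1 as described; Dirichlet concentration defaults
{0.1, 1, 10} are configuration, not calibrated values; the
supraexponential D^{D(1−ϵ)} statement for compact-support tuning is an
asymptotic order, not a sharp finite-D bound.
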