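# popdim — linear dimensionality of neural population codes

`popdim` is a small scientific Python package for a question at the heart
of neural population geometry: **if a population of N neurons encodes a
D-dimensional latent variable through common tuning-curve families, how
many principal components does PCA need to capture most of the response
variance?**  The answer — derived analytically here and checked against
brute-force simulation — is "exponentially many in D": the manifolds
produced by the most common population codes are extremely nonlinear, and
linear dimensionality-reduction methods will drastically overestimate
their dimension.

The package is aimed at computational neuroscientists who want to
reproduce, probe, or extend these results: it contains the full synthetic
population simulator, the empirical spectral pipeline, and the analytic
theory, each independently testable against the others.

## The quantities and models

For an N×T activity matrix A (neurons × latent samples) with singular
values σ_k, the **(1−ϵ)-linear dimension** is the smallest L with

    Σ_{k≤L} σ_k² ≥ (1−ϵ) Σ_k σ_k²,

i.e. the number of PCs explaining a (1−ϵ) fraction of variance; the
**participation ratio** PR = (Σλ)²/Σλ² is the smooth alternative.
Eigenvalues λ_k = σ_k² come from the (non-mean-subtracted) covariance
C = AAᵀ/T; the centered variant obeys L_centered ≥ L_raw − 1.

Two code families are analyzed:

* **Translation-symmetric Gaussian tuning** on the periodic unit domain:
  y_n(t) = K₁ exp(−‖x(t)−α_n‖²/2σ²).  On an even center grid the
  covariance is circulant, so its eigenvalues are the Fourier transform
  of the correlation profile; for Gaussian tuning
  λ_p = K₃ exp(−4π²σ²|p|²) at the integer frequency lattice p ∈ ℤᴰ.
  In 1D this gives L_{1−ϵ} = erf⁻¹(1−ϵ)/(πσ) — e.g. 1.96/(√2 πσ) at
  ϵ = 0.05 — and in D dimensions, counting lattice points inside the
  Fourier-space sphere holding a 1−ϵ eigenvalue mass (radius set by
  chi-distribution quantiles of width s = 1/(2√2 πσ)) gives exponential
  growth of L with D.
* **Multiplicative (product) tuning**: y_n = Π_d f_d(x_d, α_nd).  The
  covariance is a tensor product of per-dimension factor covariances, so
  its eigenvalues are all products of factor eigenvalues; normalized,
  they are outcome probabilities of D i.i.d. categorical variables and
  the asymptotic equipartition property gives L ≈ 2^{DH}, H the Shannon
  entropy of the factor spectrum, with the nonasymptotic binomial bound
  L_{1−ϵ} ≥ (1/(8ρ(1−ρ))) 2^{(H_b(ρ)−log₂(D)/2D)D} for two-eigenvalue
  factors.

## Worked example

```python
>>> import popdim as P
# analytic lattice spectrum: Gaussian tuning, width 0.075, 8-D latent,
# 32 frequency indices per dimension (a 32^8-neuron ideal population)
>>> rs = P.radial_spectrum(sigma=0.075, D=8, N_d=32)
>>> rep = P.linear_dimension_lattice(rs, epsilon=0.05)
>>> rep.L
6399345
# the chi-median lower bound, valid whenever eps <= 0.5:
>>> P.chi_bounds(0.075, 8, 0.05, "median_lower_bound").value
2178271.0
# simulate the 1D analogue and recover the same statistic empirically
>>> grid = P.make_center_grid(D=1, N_d=50)
>>> tuning = P.TuningSpec("gaussian_translation", sigma=0.075,
...                       space=P.LatentSpace(D=1))
>>> sim = P.simulate_population(tuning, grid, T=10_000, seed=7)
>>> P.linear_dimension(P.eigen_spectrum(P.covariance(sim)), 0.05).L
7
>>> P.closed_form_L_1d(0.075, 0.05).value
5.881958514539014
```

A population with broad (σ = 0.075) Gaussian tuning to an 8-dimensional
latent variable needs ~6.4 million principal components to reach 95% of
the variance — versus an intrinsic dimension of 8 — while the 1D analogue
needs 7, matching the ~5.9 of the continuum formula once whole degenerate
frequency pairs are counted.

## Analysis scripts

The numbered drivers under `analysis/` regenerate every results table
into `results/` and print a short narrative:

| script | contents |
| --- | --- |
| `01_width_scaling.py` | 1D spectra vs theory; 1/σ law (slope 2.004 vs predicted 1.96); saturation of L with N |
| `02_lattice_dimension.py` | multi-D lattice spectra, interpolation, exponential growth, chi bounds |
| `03_product_codes.py` | sigmoid/Gaussian/hybrid product models, Dirichlet factors, AEP scaling |
| `04_bound_suite.py` | all 59 asserted inequalities checked against exact computations |

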