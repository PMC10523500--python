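#!/usr/bin/env python
"""Multi-dimensional Gaussian codes: lattice spectra and exponential growth.

Builds the analytic lattice eigenvalue spectra of D-dimensional
translation-symmetric Gaussian codes (eigenvalues at integer Fourier
lattice points, grouped by squared radius), their smooth ball-volume
interpolation, and the growth of the 95%-variance linear dimension with
intrinsic dimension D, alongside the chi-distribution lower bound and
semianalytic fit.

Writes: results/lattice_spectrum.csv, results/lattice_scaling.csv
"""

import logging

import numpy as np

import popdim as P

logging.basicConfig(level=logging.INFO)
OUT = "results"

spectrum = P.run_experiment(
    P.ExperimentConfig("lattice_spectrum", seed=0, output_dir=OUT)
)
print("step-like lattice spectra with smooth interpolation written for "
      f"{spectrum[['D', 'N_d']].drop_duplicates().shape[0]} configurations")

scaling = P.run_experiment(
    P.ExperimentConfig("lattice_scaling", seed=0, output_dir=OUT)
)
for sigma, g in scaling.groupby("sigma"):
    g = g.sort_values("D")
    growth = np.diff(np.log(g["L"].to_numpy()))
    print(f"sigma={sigma}: L grows from {g['L'].iloc[0]} (D=2) to "
          f"{g['L'].iloc[-1]:.3g} (D=8); log-increments {np.round(growth, 2)}")
assert (scaling["chi_median_bound"] <= scaling["L"]).all()
print("chi-median lower bound holds on the full grid")

head = scaling[(scaling["sigma"] == 0.075) & (scaling["D"] == 8)]["L"].iloc[0]
print(f"headline: broad tuning (sigma=0.075) to an 8-D latent variable "
      f"needs {head:.4g} > 6e5 principal components for 95% variance")
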