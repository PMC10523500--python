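#!/usr/bin/env python
"""Multiplicative codes: tensor spectra and entropy-rate (AEP) scaling.

Runs the three product-tuning models (sigmoidal factors, variable-width
Gaussian factors, and their hybrid), computing exact product-spectrum
linear dimensions per intrinsic dimension D together with the asymptotic
2^(D(H-0.05)) lower bound, then repeats the analysis for model-agnostic
Dirichlet-sampled factor spectra.

Writes: results/product_scaling.csv, results/aep_dirichlet.csv
"""

import logging
import math
from pathlib import Path

import pandas as pd

import popdim as P

logging.basicConfig(level=logging.INFO)
OUT = Path("results")
OUT.mkdir(exist_ok=True)

table = P.run_experiment(
    P.ExperimentConfig("product_scaling", seed=0, output_dir=str(OUT))
)
for model, g in table.groupby("model"):
    g = g.sort_values("D")
    H = g["entropy"].iloc[0]
    print(f"{model}: factor entropy H={H:.3f} bits; L_0.9 grows "
          f"{g['L'].iloc[0]} (D=2) -> {g['L'].iloc[-1]:.3g} (D=10); "
          f"2^(D(H-0.05)) bound holds: {(g['aep_lower_bound'] <= g['L']).all()}")

rows = []
for seed in range(5):
    fac = P.dirichlet_factor(1.0, 8, seed=seed)
    for D in (4, 8, 12):
        L = P.linear_dimension_product(P.tensor_spectrum(fac, D), 0.1).L
        rows.append(dict(seed=seed, D=D, entropy=fac.entropy, L=float(L),
                         log2L_per_D=math.log2(L) / D,
                         offset_bits=math.log2(L) / D - fac.entropy))
diri = pd.DataFrame(rows)
diri.to_csv(OUT / "aep_dirichlet.csv", index=False)
at12 = diri[diri["D"] == 12]
print("Dirichlet(1) factors, D=12: per-dimension log2 L exceeds the factor "
      f"entropy by {at12['offset_bits'].min():+.3f}..{at12['offset_bits'].max():+.3f} "
      "bits across seeds (the finite-D varentropy correction)")
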