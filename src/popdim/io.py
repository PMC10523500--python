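"""Plain-text serialization of spectra, reports and bounds.

Spectra are single-column CSV; radial and product spectra are CSV tables
with their multiplicities/counts; dimension reports and theory bounds are
JSON records.  Everything round-trips losslessly at float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .products import ProductSpectrum
from .spectra import DimensionReport, EigenSpectrum
from .translation import RadialSpectrum, TheoryBound

__all__ = [
    "save_spectrum",
    "load_spectrum",
    "save_report",
    "load_report",
    "save_radial_spectrum",
    "load_radial_spectrum",
    "save_bound",
    "load_bound",
    "save_product_spectrum",
]


def save_spectrum(spec: EigenSpectrum, path: str | Path) -> None:
    np.savetxt(path, spec.values, fmt="%.17g", header="eigenvalue", comments="")


def load_spectrum(path: str | Path) -> EigenSpectrum:
    return EigenSpectrum(values=np.loadtxt(path, skiprows=1, ndmin=1))


def save_report(
    report: DimensionReport, path: str | Path, spectrum_path: str | None = None
) -> None:
    record = {
        "epsilon": report.epsilon,
        "L": report.L,
        "L_conservative": report.L_conservative,
        "PR": report.participation_ratio,
        "source": report.source,
        "spectrum_path": spectrum_path,
        "extras": report.extras,
    }
    Path(path).write_text(json.dumps(record, indent=1))


def load_report(path: str | Path) -> DimensionReport:
    d = json.loads(Path(path).read_text())
    return DimensionReport(
        epsilon=d["epsilon"],
        L=d["L"],
        participation_ratio=d["PR"],
        source=d["source"],
        extras=d.get("extras", {}),
    )


def save_radial_spectrum(rs: RadialSpectrum, path: str | Path) -> None:
    path = Path(path)
    rows = np.column_stack([rs.m, rs.lam, rs.multiplicity])
    np.savetxt(path, rows, fmt=("%d", "%.17g", "%.17g"), delimiter=",",
               header="m,lambda,multiplicity", comments="")
    meta = {"D": rs.D, "sigma": rs.sigma, "N_d": rs.N_d}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_radial_spectrum(path: str | Path) -> RadialSpectrum:
    path = Path(path)
    rows = np.loadtxt(path, skiprows=1, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RadialSpectrum(
        m=rows[:, 0].astype(np.int64), lam=rows[:, 1], multiplicity=rows[:, 2],
        D=meta["D"], sigma=meta["sigma"], N_d=meta["N_d"],
    )


def save_bound(bound: TheoryBound, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"kind": bound.kind, "value": bound.value,
             "validity": bound.validity, "params": bound.params},
            indent=1,
        )
    )


def load_bound(path: str | Path) -> TheoryBound:
    d = json.loads(Path(path).read_text())
    return TheoryBound(**d)


def save_product_spectrum(ps: ProductSpectrum, path: str | Path) -> None:
    path = Path(path)
    if ps.mode == "explicit":
        rows = np.column_stack([ps.values, np.ones_like(ps.values)])
        header = "value,count"
    else:
        rows = np.column_stack([ps.bin_log2, ps.counts, ps.masses])
        header = "log2_value,count,mass"
    np.savetxt(path, rows, fmt="%.17g", delimiter=",", header=header, comments="")
    meta = {"D": ps.D, "mode": ps.mode, "zero_mass_count": ps.zero_mass_count,
            **ps.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
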