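"""Equilibrium ligand binding from intrinsic-fluorescence quenching.

Binding of NAD+ to the enzyme quenches tryptophan emission (excitation
295 nm, emission 335 nm).  The fractional quench (F0−F)/F0 follows a
single-site hyperbola Q(L) = Qmax·L/(K_D+L) when free ligand ≈ total
ligand; with enzyme and K_D of comparable magnitude the depletion-aware
quadratic form is available via ``depletion=True``.

Also houses the NADH fluorescence calibration line (intensity → μM) used
by the low-temperature rate assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ._fitting import FitError, LsqFit, fit_least_squares

__all__ = [
    "QuenchTitration",
    "BindingFit",
    "eval_quench",
    "fit_kd",
    "nadh_fluorescence_calibration",
    "CalibrationLine",
]


@dataclass
class QuenchTitration:
    """Ligand-concentration vs. fractional-quench titration."""

    ligand_um: np.ndarray
    quench: np.ndarray
    enzyme_um: float = 0.1
    ph: float = 8.0
    buffer: str = "potassium phosphate"

    def __post_init__(self):
        self.ligand_um = np.asarray(self.ligand_um, dtype=float)
        self.quench = np.asarray(self.quench, dtype=float)
        if self.ligand_um.shape != self.quench.shape:
            raise ValueError("length mismatch")
        if np.any(self.ligand_um < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if np.any(np.diff(self.ligand_um) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")
        if np.any((self.quench < 0) | (self.quench > 1)):
            raise ValueError("quench must lie in [0, 1]")


@dataclass
class BindingFit:
    """Hyperbolic binding-fit result: K_D and maximal quench."""

    kd: float
    qmax: float
    stderr: dict
    rss: float
    n: int
    converged: bool
    warnings: list

    def to_dict(self) -> dict:
        return {
            "params": {"kd": self.kd, "qmax": self.qmax},
            "stderr": dict(self.stderr),
            "rss": float(self.rss),
            "n": int(self.n),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
        }


def eval_quench(l, kd: float, qmax: float, enzyme_um: float = 0.0,
                depletion: bool = False):
    """Fractional quench at ligand concentration ``l``.

    Default is the free≈total hyperbola Qmax·L/(K_D+L).  With
    ``depletion=True`` the quadratic single-site form is used, treating
    ``l`` as total ligand and ``enzyme_um`` as total binding sites.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("ligand concentration must be non-negative")
    if not depletion:
        out = qmax * l / (kd + l)
        return out if out.ndim else float(out)
    e = enzyme_um
    if e <= 0:
        raise ValueError("enzyme_um required for the depletion form")
    s = l + e + kd
    bound = (s - np.sqrt(s * s - 4.0 * l * e)) / 2.0
    out = qmax * bound / e
    return out if out.ndim else float(out)


def fit_kd(t: QuenchTitration, depletion: bool = False) -> BindingFit:
    """Fit (K_D, Qmax) to a quench titration by least squares.

    Warns when the fitted K_D exceeds half the top ligand concentration
    (the plateau is then unsampled and K_D poorly identified).
    """
    l, q = t.ligand_um, t.quench
    if l.size < 6:
        raise ValueError("need at least 6 titration points")
    if np.all(q == 0):
        raise ValueError("all-zero quench: nothing to fit")

    qmax0 = float(np.max(q)) * 1.1
    half = qmax0 / 2.0
    above = l[q >= half]
    kd0 = float(above[0]) if above.size else float(np.median(l))

    def residual(theta):
        kd, qmax = theta
        return eval_quench(l, kd, qmax, enzyme_um=t.enzyme_um,
                           depletion=depletion) - q

    fit = fit_least_squares(residual, [max(kd0, 1e-6), min(qmax0, 1.0)],
                            ["kd", "qmax"],
                            bounds=([1e-9, 1e-6], [np.inf, 1.0]))
    if not fit.converged:
        raise FitError("binding fit did not converge", best=fit.to_dict())
    warnings = list(fit.warnings)
    if fit.params["kd"] > float(np.max(l)) / 2.0:
        warnings.append("kd above half the titration range: poorly identified")
    return BindingFit(
        kd=fit.params["kd"],
        qmax=fit.params["qmax"],
        stderr=fit.stderr,
        rss=fit.rss,
        n=fit.n,
        converged=fit.converged,
        warnings=warnings,
    )


@dataclass(frozen=True)
class CalibrationLine:
    """Fluorescence-to-NADH calibration: intensity = slope·conc + intercept."""

    slope: float
    intercept: float
    r2: float

    def to_conc(self, intensity):
        """Invert the line: map intensity (AU) to NADH concentration (μM)."""
        intensity = np.asarray(intensity, dtype=float)
        out = (intensity - self.intercept) / self.slope
        return out if out.ndim else float(out)


def nadh_fluorescence_calibration(conc_um, intensity) -> CalibrationLine:
    """Ordinary least-squares line through NADH-standard fluorescence data."""
    conc = np.asarray(conc_um, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    res = stats.linregress(conc, inten)
    return CalibrationLine(slope=float(res.slope),
                           intercept=float(res.intercept),
                           r2=float(res.rvalue ** 2))
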