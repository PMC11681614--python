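"""pH-ionization models for kinetic and binding parameters.

Three standard diprotic-model reductions are covered:

* a single-ionization titration of an equilibrium constant,
  K(pH) = C / (1 + 10^(pKa − pH)), used for the pH dependence of the
  NAD+ dissociation constant;
* the log-plateau form log k_cat(pH) = log[C / (1 + 10^(pKa − pH))],
  rising through pKa to a plateau log C at basic pH;
* the Cleland bell, log(k_cat/K_m)(pH) =
  log[C / (1 + 10^(pKa1 − pH) + 10^(pH − pKa2))], with acidic and basic
  limbs bracketing a plateau.

K_D series are fitted on the linear scale; kcat and kcat/Km series on the
log10 scale, matching how the models are written.  Fits are ordinary
least squares via scipy with Jacobian-based asymptotic standard errors.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._fitting import FitError, LsqFit, fit_least_squares

__all__ = [
    "PHSeries",
    "SingleIonizationParams",
    "BellParams",
    "eval_single_ionization",
    "eval_log_plateau_acidic",
    "eval_log_bell",
    "fit_single_ionization",
    "fit_bell",
]

#: pH values of the experimental series emulated by the synthetic generator.
PH_GRID = (5.4, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0)


@dataclass
class PHSeries:
    """A kinetic or binding parameter measured across pH.

    ``kind`` selects the fitting scale: ``"kd"`` (linear), ``"kcat"`` or
    ``"kcat_over_km"`` (log10).
    """

    ph: np.ndarray
    value: np.ndarray
    sd: Optional[np.ndarray] = None
    kind: str = "kd"

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.ph.shape:
                raise ValueError("sd length mismatch")
        if self.ph.shape != self.value.shape:
            raise ValueError("ph and value must have equal length")
        if np.any((self.ph < 4.0) | (self.ph > 12.0)):
            raise ValueError("ph outside [4, 12]")
        if self.kind not in ("kd", "kcat", "kcat_over_km"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("kd", "kcat") and np.any(self.value <= 0):
            raise ValueError("values must be positive for this kind")


@dataclass(frozen=True)
class SingleIonizationParams:
    """Plateau value C and the single apparent pKa."""

    c: float
    pka: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        if not (2.0 <= self.pka <= 12.0):
            raise ValueError("pka outside [2, 12]")


@dataclass(frozen=True)
class BellParams:
    """Plateau C with acidic (pKa1) and basic (pKa2) ionizations."""

    c: float
    pka1: float
    pka2: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        if not self.pka1 < self.pka2:
            raise ValueError("pka1 must be below pka2")


def eval_single_ionization(ph, p: SingleIonizationParams,
                           direction: str = "as_printed"):
    """Single-ionization titration of an equilibrium constant.

    ``direction="as_printed"`` gives C/(1+10^(pKa−pH)) (rising with pH);
    ``"decreasing"`` gives the mirrored C/(1+10^(pH−pKa)).
    """
    ph = np.asarray(ph, dtype=float)
    if direction == "as_printed":
        out = p.c / (1.0 + 10.0 ** (p.pka - ph))
    elif direction == "decreasing":
        out = p.c / (1.0 + 10.0 ** (ph - p.pka))
    else:
        raise ValueError("direction must be 'as_printed' or 'decreasing'")
    return out if out.ndim else float(out)


def eval_log_plateau_acidic(ph, p: SingleIonizationParams):
    """log10 of the single-ionization form: rises to log10(C) above pKa."""
    ph = np.asarray(ph, dtype=float)
    out = np.log10(p.c) - np.log10(1.0 + 10.0 ** (p.pka - ph))
    return out if out.ndim else float(out)


def eval_log_bell(ph, p: BellParams, bell_form: str = "standard"):
    """log10 bell-shaped pH profile.

    ``bell_form="standard"`` is the Cleland form
    log10[C/(1+10^(pKa1−pH)+10^(pH−pKa2))]; ``"literal"`` adds a second
    unity term in the denominator (the flattened printed rendering).
    """
    ph = np.asarray(ph, dtype=float)
    denom = 10.0 ** (p.pka1 - ph) + 10.0 ** (ph - p.pka2)
    if bell_form == "standard":
        denom = 1.0 + denom
    elif bell_form == "literal":
        denom = 2.0 + denom
    else:
        raise ValueError("bell_form must be 'standard' or 'literal'")
    out = np.log10(p.c) - np.log10(denom)
    return out if out.ndim else float(out)


def _dynamic_range_warning(values: np.ndarray, warnings: list, label: str):
    vmax, vmin = float(np.max(values)), float(np.min(values))
    if vmin <= 0 or vmax / vmin < 1.25:
        warnings.append(f"{label} unidentifiable: series nearly flat")


def fit_single_ionization(series: PHSeries,
                          direction: str = "as_printed") -> LsqFit:
    """Fit the single-ionization model to a pH series.

    K_D series (kind="kd") are fitted on the linear scale; kcat series on
    the log10 scale.  Returns parameters ``c`` and ``pka`` with asymptotic
    standard errors.  A nearly flat series sets a 'pka unidentifiable'
    warning; a pH span under 2 units around the transition sets a
    'narrow pH span' warning.
    """
    ph, y = series.ph, series.value
    if ph.size < 5:
        raise ValueError("need at least 5 pH points")
    log_scale = series.kind in ("kcat", "kcat_over_km")
    obs = np.log10(y) if log_scale else y

    pka0 = float(np.clip(np.median(ph), 3.0, 11.0))
    c0 = float(np.max(y))

    def residual(theta):
        c, pka = theta
        if log_scale:
            model = np.log10(c) - np.log10(1.0 + 10.0 ** (pka - ph))
        else:
            p = SingleIonizationParams(c=c, pka=np.clip(pka, 2, 12))
            model = eval_single_ionization(ph, p, direction=direction)
        return model - obs

    fit = fit_least_squares(residual, [c0, pka0], ["c", "pka"],
                            bounds=([1e-12, 2.0], [np.inf, 12.0]))
    if not fit.converged:
        raise FitError("single-ionization fit did not converge",
                       best=fit.to_dict())
    _dynamic_range_warning(y, fit.warnings, "pka")
    pka = fit.params["pka"]
    if ph.max() - ph.min() < 2.0 or not (ph.min() - 1 < pka < ph.max() + 1):
        fit.warnings.append("narrow pH span: pKa poorly bracketed")
    return fit


def fit_bell(series: PHSeries, bell_form: str = "standard") -> LsqFit:
    """Fit the bell model on the log10 scale.

    Requires ≥ 7 pH points.  Flags pKa2 as unidentifiable when the fitted
    basic limb lies outside the sampled pH range (an acidic-limb-only
    series).  Raises :class:`FitError` if the optimum has pKa1 ≥ pKa2.
    """
    ph, y = series.ph, series.value
    if ph.size < 7:
        raise ValueError("need at least 7 pH points")
    obs = np.log10(y) if series.kind in ("kcat", "kcat_over_km") else y
    # obs is log10 of the parameter in either case: a kd-kind bell series
    # is not meaningful, but accept pre-logged values for flexibility.
    if series.kind == "kd":
        obs = np.log10(y)

    c0 = 10.0 ** float(np.max(obs))
    lo, hi = float(ph.min()), float(ph.max())

    def residual(theta):
        c, pka1, pka2 = theta
        denom = 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2)
        denom = (1.0 if bell_form == "standard" else 2.0) + denom
        return (np.log10(c) - np.log10(denom)) - obs

    starts = [
        [c0, lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo)],
        [c0, lo + 1.0, hi - 1.0],
        [2 * c0, lo, hi],
    ]
    best = None
    for x0 in starts:
        try:
            fit = fit_least_squares(residual, x0, ["c", "pka1", "pka2"],
                                    bounds=([1e-12, 2.0, 2.0],
                                            [np.inf, 14.0, 14.0]))
        except ValueError:
            continue
        if fit.converged and (best is None or fit.rss < best.rss):
            best = fit
    if best is None:
        raise FitError("bell fit did not converge")
    pka1, pka2 = best.params["pka1"], best.params["pka2"]
    if pka1 >= pka2:
        raise FitError("identifiability failure: pka1 >= pka2 at optimum",
                       best=best.to_dict())
    if pka2 > hi + 0.5 or (np.isfinite(best.stderr["pka2"])
                           and best.stderr["pka2"] > 1.0):
        best.warnings.append("pka2 unidentifiable: basic limb not sampled")
    if pka1 < lo - 0.5 or (np.isfinite(best.stderr["pka1"])
                           and best.stderr["pka1"] > 1.0):
        best.warnings.append("pka1 unidentifiable: acidic limb not sampled")
    return best
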