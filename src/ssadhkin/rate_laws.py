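"""Steady-state rate laws for a two-substrate dehydrogenase.

The reaction is the NAD+-dependent oxidation of succinic semialdehyde (SSA)
to succinate.  Substrate A is NAD+ (binds first), substrate B is SSA
(binds second and, at high concentration, inhibits).  Five nested rate
equations are provided:

* single-substrate Michaelis–Menten (apparent parameters at one fixed
  cosubstrate level),
* Michaelis–Menten with complete substrate inhibition,
* the ordered bi–bi rate law (no inhibition),
* an inhibitory-regime model with slope (K_is) and intercept (K_ix, K_ii)
  inhibition constants,
* partial non-competitive substrate inhibition: SSA combines dead-end with
  the enzyme–NADH complex, which still turns over at a fraction ``b`` of
  Vmax.  As B → ∞ the rate tends to b·Vmax rather than zero.

All evaluators are vectorised over concentrations.  Rates are carried in
s⁻¹ per tetramer, so Vmax is the turnover number kcat once enzyme
concentration has been normalised out (see :func:`kcat_from_vmax`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NADH_EXTINCTION_MM_CM",
    "RateObservation",
    "MMParams",
    "SubstrateInhibitionParams",
    "OrderedBiBiParams",
    "InhibitoryRegimeParams",
    "PartialSubstrateInhibitionParams",
    "eval_mm",
    "eval_mm_substrate_inhibition",
    "eval_ordered_bibi",
    "eval_inhibitory_regime",
    "eval_partial_substrate_inhibition",
    "nadh_from_a340",
    "kcat_from_vmax",
]

#: Molar extinction coefficient of NADH at 340 nm, mM^-1 cm^-1.
NADH_EXTINCTION_MM_CM = 6.22


def _check_nonneg(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


@dataclass
class RateObservation:
    """One initial-rate measurement.

    Parameters
    ----------
    ssa_um : float
        SSA concentration (substrate B), μM.
    nad_um : float
        NAD+ concentration (substrate A), μM.
    rate : float
        Initial rate; s⁻¹ per tetramer if ``rate_units == "per_s"``,
        μM·s⁻¹ if ``rate_units == "um_per_s"``.
    ph, temperature_c : float
        Assay conditions (metadata; no Arrhenius correction is applied).
    enzyme_um : float
        Tetramer concentration, μM.
    replicate_id : str
        Free-form label.
    blank_subtracted : bool
        If True, slightly negative rates are tolerated (blank noise).
    """

    ssa_um: float
    nad_um: float
    rate: float
    rate_units: str = "per_s"
    ph: float = 8.0
    temperature_c: float = 25.0
    enzyme_um: float = 0.008
    replicate_id: str = ""
    blank_subtracted: bool = False

    def __post_init__(self):
        if self.ssa_um < 0 or self.nad_um < 0:
            raise ValueError("concentrations must be non-negative")
        if self.enzyme_um <= 0:
            raise ValueError("enzyme_um must be positive")
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError("ph outside [0, 14]")
        if self.rate_units not in ("per_s", "um_per_s"):
            raise ValueError("rate_units must be 'per_s' or 'um_per_s'")
        if self.rate < 0 and not self.blank_subtracted:
            raise ValueError("negative rate without blank_subtracted flag")

    @property
    def rate_per_s(self) -> float:
        """Rate as turnover per tetramer (s⁻¹)."""
        if self.rate_units == "per_s":
            return self.rate
        return self.rate / self.enzyme_um


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class MMParams:
    """Apparent Michaelis–Menten parameters (Vmax, Km)."""

    vmax: float
    km: float

    def __post_init__(self):
        _require_positive(vmax=self.vmax, km=self.km)


@dataclass(frozen=True)
class SubstrateInhibitionParams:
    """Michaelis–Menten with complete substrate inhibition (Vmax, Km, Ki)."""

    vmax: float
    km: float
    ki: float

    def __post_init__(self):
        _require_positive(vmax=self.vmax, km=self.km, ki=self.ki)

    @property
    def optimum(self) -> float:
        """Substrate concentration of the rate maximum, sqrt(Km·Ki)."""
        return float(np.sqrt(self.km * self.ki))


@dataclass(frozen=True)
class OrderedBiBiParams:
    """Ordered bi–bi parameters: Vmax, K_A, K_B Michaelis constants and
    K_iA, the dissociation constant of A from the binary complex."""

    vmax: float
    k_a: float
    k_b: float
    k_ia: float

    def __post_init__(self):
        _require_positive(vmax=self.vmax, k_a=self.k_a, k_b=self.k_b,
                          k_ia=self.k_ia)


@dataclass(frozen=True)
class InhibitoryRegimeParams:
    """Inhibitory-regime model: K_is slope constant, K_ix / K_ii intercept
    constants for substrate B acting as inhibitor."""

    vmax: float
    k_a: float
    k_is: float
    k_ix: float
    k_ii: float

    def __post_init__(self):
        _require_positive(vmax=self.vmax, k_a=self.k_a, k_is=self.k_is,
                          k_ix=self.k_ix, k_ii=self.k_ii)


@dataclass(frozen=True)
class PartialSubstrateInhibitionParams:
    """Ordered bi–bi with partial non-competitive substrate inhibition.

    ``b`` is the residual fraction of Vmax at saturating inhibitory
    substrate: the dead-end E–NADH–SSA complex still turns over at b·Vmax.
    b = 0 recovers complete inhibition, b = 1 (with K_is → ∞) recovers the
    plain ordered bi–bi law.
    """

    vmax: float
    k_a: float
    k_b: float
    k_ia: float
    k_is: float
    b: float

    def __post_init__(self):
        _require_positive(vmax=self.vmax, k_a=self.k_a, k_b=self.k_b,
                          k_ia=self.k_ia, k_is=self.k_is)
        if not (0.0 <= self.b <= 1.0):
            raise ValueError(f"b must lie in [0, 1], got {self.b!r}")


def eval_mm(s, p: MMParams):
    """Michaelis–Menten rate Vmax·S/(Km+S)."""
    s = _check_nonneg(s, "s")
    out = p.vmax * s / (p.km + s)
    return out if out.ndim else float(out)


def eval_mm_substrate_inhibition(s, p: SubstrateInhibitionParams):
    """Substrate-inhibited rate Vmax·S/(Km + S·(1+S/Ki)).

    Has a unique interior maximum at S* = sqrt(Km·Ki).
    """
    s = _check_nonneg(s, "s")
    out = p.vmax * s / (p.km + s * (1.0 + s / p.ki))
    return out if out.ndim else float(out)


def eval_ordered_bibi(a, b, p: OrderedBiBiParams):
    """Ordered bi–bi rate Vmax·A·B/(K_iA·K_B + K_B·A + K_A·B + A·B)."""
    a = _check_nonneg(a, "a")
    b = _check_nonneg(b, "b")
    denom = p.k_ia * p.k_b + p.k_b * a + p.k_a * b + a * b
    out = p.vmax * a * b / denom
    return out if out.ndim else float(out)


def eval_inhibitory_regime(a, b, p: InhibitoryRegimeParams):
    """Inhibitory-regime rate
    Vmax·A·(1+B/K_ix) / [K_A·(1+B/K_is) + A·(1+B/K_ii)]."""
    a = _check_nonneg(a, "a")
    b = _check_nonneg(b, "b")
    num = p.vmax * a * (1.0 + b / p.k_ix)
    denom = p.k_a * (1.0 + b / p.k_is) + a * (1.0 + b / p.k_ii)
    out = num / denom
    return out if out.ndim else float(out)


def eval_partial_substrate_inhibition(a, b_conc,
                                      p: PartialSubstrateInhibitionParams):
    """Partial non-competitive substrate-inhibition rate

    Vmax·A·B·(1+b·B/K_is) /
        [K_iA·K_B + K_B·A + K_A·B + A·B·(1+B/K_is)]

    As B → ∞ at fixed A > 0 the rate tends to b·Vmax; with K_is → ∞ the
    law reduces to the plain ordered bi–bi equation.
    """
    a = _check_nonneg(a, "a")
    b_conc = _check_nonneg(b_conc, "b_conc")
    num = p.vmax * a * b_conc * (1.0 + p.b * b_conc / p.k_is)
    denom = (p.k_ia * p.k_b + p.k_b * a + p.k_a * b_conc
             + a * b_conc * (1.0 + b_conc / p.k_is))
    out = num / denom
    return out if out.ndim else float(out)


def nadh_from_a340(a340, path_cm: float = 1.0):
    """Convert absorbance at 340 nm to NADH concentration in μM.

    Uses ε = 6.22 mM⁻¹ cm⁻¹; the factor 1000 converts mM to μM.
    """
    if path_cm <= 0:
        raise ValueError("path_cm must be positive")
    a340 = np.asarray(a340, dtype=float)
    out = 1000.0 * a340 / (NADH_EXTINCTION_MM_CM * path_cm)
    return out if out.ndim else float(out)


def kcat_from_vmax(vmax_um_per_s: float, enzyme_um: float) -> float:
    """Turnover number kcat = Vmax/[E], per tetramer of enzyme."""
    if enzyme_um <= 0:
        raise ValueError("enzyme_um must be positive")
    return vmax_um_per_s / enzyme_um
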