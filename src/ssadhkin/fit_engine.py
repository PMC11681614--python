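"""Steady-state fitting machinery.

Covers the full workflow used to characterise the enzyme:

* partition of a rate dataset into subinhibitory (SSA ≤ 10 μM) and
  inhibitory (SSA ≥ 12 μM) regimes, with the open gap (10, 12) μM
  assigned to neither;
* apparent Michaelis–Menten (or substrate-inhibition) fits at each fixed
  cosubstrate level;
* the classical double-reciprocal secondary-replot estimate of the
  ordered bi–bi constants;
* seeded multistart global fits of the bi–bi, inhibitory-regime, and
  partial-substrate-inhibition rate laws over two-dimensional
  cosubstrate grids, with AIC for model comparison;
* product-inhibition pattern diagnosis from per-inhibitor-level
  double-reciprocal lines and slope replots;
* Jacobian-covariance and residual-bootstrap uncertainty.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._fitting import (FitError, LsqFit, bootstrap_stderr, fit_least_squares,
                       multistart_least_squares)
from .rate_laws import (InhibitoryRegimeParams, MMParams, OrderedBiBiParams,
                        PartialSubstrateInhibitionParams, RateObservation,
                        SubstrateInhibitionParams, eval_inhibitory_regime,
                        eval_mm, eval_mm_substrate_inhibition,
                        eval_ordered_bibi, eval_partial_substrate_inhibition)

__all__ = [
    "RateDataset",
    "GlobalFitResult",
    "ProductInhibitionResult",
    "SUBINHIBITORY_MAX_UM",
    "INHIBITORY_MIN_UM",
    "partition_regimes",
    "fit_apparent",
    "replot_secondary",
    "global_fit",
    "select_model",
    "product_inhibition_analysis",
    "uncertainty",
]

#: Regime thresholds on SSA: the experimental designs use 1–10 μM as the
#: subinhibitory range and 12–200 μM as the inhibitory range; 10–12 μM is
#: a gap assigned to neither regime.
SUBINHIBITORY_MAX_UM = 10.0
INHIBITORY_MIN_UM = 12.0

_PARAM_TYPES = {
    "eq1": MMParams,
    "eq2": SubstrateInhibitionParams,
    "eq3": OrderedBiBiParams,
    "eq4": InhibitoryRegimeParams,
    "eq5": PartialSubstrateInhibitionParams,
}


@dataclass
class RateDataset:
    """A collection of initial-rate observations plus design metadata."""

    observations: List[RateObservation]
    design: dict = field(default_factory=dict)
    nadh_um: Optional[np.ndarray] = None  # product-inhibitor level per obs

    def __post_init__(self):
        if self.nadh_um is not None:
            self.nadh_um = np.asarray(self.nadh_um, dtype=float)
            if self.nadh_um.size != len(self.observations):
                raise ValueError("nadh_um length mismatch")

    def __len__(self):
        return len(self.observations)

    @property
    def ssa(self) -> np.ndarray:
        return np.array([o.ssa_um for o in self.observations])

    @property
    def nad(self) -> np.ndarray:
        return np.array([o.nad_um for o in self.observations])

    @property
    def rates(self) -> np.ndarray:
        """Rates normalised to turnover per tetramer (s⁻¹)."""
        return np.array([o.rate_per_s for o in self.observations])

    def subset(self, mask: np.ndarray) -> "RateDataset":
        obs = [o for o, m in zip(self.observations, mask) if m]
        nadh = self.nadh_um[mask] if self.nadh_um is not None else None
        return RateDataset(obs, dict(self.design), nadh)


@dataclass
class GlobalFitResult:
    """Result of a global rate-law fit."""

    model: str
    params: object
    stderr: dict
    rss: float
    n: int
    aic: float
    converged: bool
    warnings: list = field(default_factory=list)
    bic: float = float("nan")
    _lsq: Optional[LsqFit] = None
    _dataset: Optional[RateDataset] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in vars(self.params).items()},
            "stderr": dict(self.stderr),
            "rss": float(self.rss),
            "n": int(self.n),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
        }


def partition_regimes(
    d: RateDataset,
    sub_max: float = SUBINHIBITORY_MAX_UM,
    inhib_min: float = INHIBITORY_MIN_UM,
) -> Dict[str, RateDataset]:
    """Split a dataset on SSA concentration into kinetic regimes.

    Observations with SSA ≤ ``sub_max`` are subinhibitory, SSA ≥
    ``inhib_min`` inhibitory; SSA strictly inside the gap belongs to
    neither.  Empty subsets produce a warning entry in the design
    metadata rather than an error.
    """
    if not sub_max < inhib_min:
        raise ValueError("sub_max must be below inhib_min")
    ssa = d.ssa
    sub = d.subset(ssa <= sub_max)
    inhib = d.subset(ssa >= inhib_min)
    for name, part in (("subinhibitory", sub), ("inhibitory", inhib)):
        part.design["regime"] = name
        if len(part) == 0:
            part.design["warning"] = f"{name} subset empty"
            _warnings.warn(f"{name} subset is empty", stacklevel=2)
    return {"subinhibitory": sub, "inhibitory": inhib}


def _fit_mm_1d(conc, rate) -> LsqFit:
    vmax0 = 1.2 * float(np.max(rate))
    half = conc[rate >= np.max(rate) / 2]
    km0 = float(half[0]) if half.size else float(np.median(conc))

    def residual(theta):
        return theta[0] * conc / (theta[1] + conc) - rate

    return fit_least_squares(residual, [vmax0, max(km0, 1e-9)],
                             ["vmax", "km"], bounds=([1e-12, 1e-12],
                                                     [np.inf, np.inf]))


def _fit_si_1d(conc, rate) -> LsqFit:
    vmax0 = 1.5 * float(np.max(rate))
    peak = float(conc[np.argmax(rate)])
    km0, ki0 = max(peak / 2, 1e-6), max(peak * 2, 1e-6)

    def residual(theta):
        v, km, ki = theta
        return v * conc / (km + conc * (1 + conc / ki)) - rate

    return fit_least_squares(residual, [vmax0, km0, ki0],
                             ["vmax", "km", "ki"],
                             bounds=([1e-12] * 3, [np.inf] * 3))


def fit_apparent(d: RateDataset, fixed: str = "ssa",
                 model: str = "eq1") -> Dict[float, object]:
    """Apparent parameters at each level of the fixed cosubstrate.

    ``fixed="ssa"`` varies NAD+ at each SSA level and vice versa.  Levels
    with fewer than four varied concentrations are skipped with a warning.
    Returns a mapping fixed-level → :class:`MMParams` (model="eq1") or
    :class:`SubstrateInhibitionParams` (model="eq2"); per-level fit
    details are kept on the returned dict under the attribute-free key
    convention is avoided — use :func:`global_fit` for uncertainties.
    """
    if fixed not in ("ssa", "nad"):
        raise ValueError("fixed must be 'ssa' or 'nad'")
    if model not in ("eq1", "eq2"):
        raise ValueError("model must be 'eq1' or 'eq2'")
    fixed_vals = d.ssa if fixed == "ssa" else d.nad
    varied_vals = d.nad if fixed == "ssa" else d.ssa
    rates = d.rates
    out: Dict[float, object] = {}
    for level in np.unique(fixed_vals):
        mask = fixed_vals == level
        conc, rate = varied_vals[mask], rates[mask]
        order = np.argsort(conc)
        conc, rate = conc[order], rate[order]
        if np.unique(conc).size < 4:
            _warnings.warn(
                f"level {level}: fewer than 4 varied concentrations, skipped",
                stacklevel=2)
            continue
        fit = _fit_mm_1d(conc, rate) if model == "eq1" else _fit_si_1d(conc, rate)
        if model == "eq1":
            out[float(level)] = MMParams(vmax=fit.params["vmax"],
                                         km=fit.params["km"])
        else:
            out[float(level)] = SubstrateInhibitionParams(
                vmax=fit.params["vmax"], km=fit.params["km"],
                ki=fit.params["ki"])
    return out


def replot_secondary(apparent: Dict[float, MMParams]) -> Tuple[OrderedBiBiParams, dict]:
    """Ordered bi–bi constants from double-reciprocal secondary replots.

    ``apparent`` maps the fixed SSA concentration B to the apparent
    Michaelis–Menten parameters of the NAD+ saturation curve at that B.
    For the ordered bi–bi law,

        1/appVmax(B) = 1/Vmax + (K_B/Vmax)·(1/B)
        appKm(B)/appVmax(B) = K_A/Vmax + (K_iA·K_B/Vmax)·(1/B)

    so two linear replots against 1/B give Vmax, K_B (intercept replot)
    and K_A, K_iA (slope replot).  Returns the parameter estimate and a
    flags dict; graphical estimates are marked lower-precision, and a
    non-positive replot slope flags the estimate unreliable.
    """
    if len(apparent) < 3:
        raise ValueError("need apparent fits at >= 3 fixed levels")
    b_levels = np.array(sorted(apparent))
    vmax_app = np.array([apparent[b].vmax for b in b_levels])
    km_app = np.array([apparent[b].km for b in b_levels])
    inv_b = 1.0 / b_levels

    ir = stats.linregress(inv_b, 1.0 / vmax_app)       # intercept replot
    sr = stats.linregress(inv_b, km_app / vmax_app)    # slope replot
    flags = {"method": "double-reciprocal secondary replot",
             "precision": "graphical (lower than global fit)",
             "reliable": True}
    if ir.intercept <= 0 or ir.slope <= 0 or sr.intercept <= 0 or sr.slope <= 0:
        flags["reliable"] = False
        flags["reason"] = "non-positive replot slope or intercept"
        # fall back to magnitudes so a params object can still be built
    vmax = 1.0 / abs(ir.intercept)
    k_b = abs(ir.slope) * vmax
    k_a = abs(sr.intercept) * vmax
    k_ia = abs(sr.slope) * vmax / k_b
    return OrderedBiBiParams(vmax=vmax, k_a=k_a, k_b=k_b, k_ia=k_ia), flags


# ---------------------------------------------------------------------------
# Global fits

def _heuristic_init(model: str, a, b, rate) -> np.ndarray:
    vmax0 = 1.2 * float(np.max(rate))
    # half-max concentrations as Michaelis-constant guesses
    ka0 = float(np.median(a))
    kb0 = float(np.median(b))
    if model == "eq3":
        return np.array([vmax0, ka0, kb0, ka0])
    if model == "eq4":
        peak_b = float(b[np.argmax(rate)])
        return np.array([vmax0, ka0, max(peak_b, 1e-3),
                         max(2 * peak_b, 1e-3), max(peak_b, 1e-3)])
    # eq5: K_is from the SSA of the rate peak; b0 from residual rate at top SSA
    peak_b = float(b[np.argmax(rate)])
    top = b == np.max(b)
    b0 = float(np.max(rate[top]) / np.max(rate))
    return np.array([vmax0, ka0, kb0, ka0, max(peak_b, 1e-3),
                     float(np.clip(b0, 1e-3, 1.0))])


_MODEL_NAMES = {
    "eq3": ["vmax", "k_a", "k_b", "k_ia"],
    "eq4": ["vmax", "k_a", "k_is", "k_ix", "k_ii"],
    "eq5": ["vmax", "k_a", "k_b", "k_ia", "k_is", "b"],
}


def _model_eval(model: str, a, b, theta):
    if model == "eq3":
        v, ka, kb, kia = theta
        return v * a * b / (kia * kb + kb * a + ka * b + a * b)
    if model == "eq4":
        v, ka, kis, kix, kii = theta
        return (v * a * (1 + b / kix)) / (ka * (1 + b / kis) + a * (1 + b / kii))
    v, ka, kb, kia, kis, bb = theta
    num = v * a * b * (1 + bb * b / kis)
    den = kia * kb + kb * a + ka * b + a * b * (1 + b / kis)
    return num / den


def _params_object(model: str, params: dict):
    cls = _PARAM_TYPES[model]
    return cls(**params)


def global_fit(d: RateDataset, model: str = "eq5",
               init: Optional[Sequence[float]] = None,
               n_starts: int = 10, seed: int = 0,
               weighting: str = "none",
               sub_max: float = SUBINHIBITORY_MAX_UM,
               inhib_min: float = INHIBITORY_MIN_UM) -> GlobalFitResult:
    """Global least-squares fit of a two-substrate rate law.

    The dataset regime must match the model: the plain bi–bi law (eq3)
    only applies below the inhibitory SSA range, the inhibitory-regime
    model (eq4) only above it, and the partial-inhibition law (eq5)
    spans the full range.  Multistart initialisation uses the heuristic
    start plus seeded log-uniform perturbations; the best (lowest-RSS)
    converged start wins, ties broken by the smaller parameter norm.

    ``weighting="relative"`` divides residuals by the observed rate
    (proportional-error model); the default is unweighted.
    """
    if model not in ("eq3", "eq4", "eq5"):
        raise ValueError("model must be one of eq3, eq4, eq5")
    a, b, rate = d.nad, d.ssa, d.rates
    if model == "eq3" and np.any(b > sub_max):
        raise ValueError(
            "regime mismatch: eq3 requires subinhibitory SSA only")
    if model == "eq4" and np.any(b < inhib_min):
        raise ValueError(
            "regime mismatch: eq4 requires inhibitory SSA only")
    names = _MODEL_NAMES[model]
    k = len(names)
    if len(d) < k + 2:
        raise ValueError("need at least 2 more observations than parameters")
    for conc, label in ((a, "NAD+"), (b, "SSA")):
        if np.unique(conc).size < 4:
            raise ValueError(f"need >= 4 distinct {label} concentrations")

    if weighting == "relative":
        w = 1.0 / np.where(rate > 0, rate, np.max(rate))
    elif weighting == "none":
        w = np.ones_like(rate)
    else:
        raise ValueError("weighting must be 'none' or 'relative'")

    def residual(theta):
        return w * (_model_eval(model, a, b, theta) - rate)

    x0 = np.asarray(init, float) if init is not None else _heuristic_init(
        model, a, b, rate)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(x0 * np.exp(rng.uniform(-1.0, 1.0, size=k)))
    lo = np.full(k, 1e-12)
    hi = np.full(k, np.inf)
    if model == "eq5":
        lo[-1], hi[-1] = 0.0, 1.0
        starts = [np.clip(s, lo + 1e-15, np.where(np.isfinite(hi), hi, s))
                  for s in starts]
    fit = multistart_least_squares(residual, starts, names,
                                   bounds=(lo, hi), max_nfev=5000)
    warnings = list(fit.warnings)
    if model == "eq5":
        warnings.append("k_ia estimate is rough; prefer the spectroscopic K_D")
    params = _params_object(model, fit.params)
    result = GlobalFitResult(
        model=model, params=params, stderr=fit.stderr, rss=fit.rss,
        n=fit.n, aic=fit.aic, bic=fit.bic, converged=fit.converged,
        warnings=warnings, _lsq=fit, _dataset=d)
    return result


def select_model(d: RateDataset, candidates: Sequence[str] = ("eq3", "eq5"),
                 criterion: str = "bic", n_starts: int = 5,
                 seed: int = 0) -> Tuple[str, Dict[str, GlobalFitResult]]:
    """Fit each candidate rate law to the same dataset and pick one.

    Candidate models are fitted with the regime thresholds relaxed (the
    comparison is only meaningful on common data).  The default criterion
    is BIC: with nested models two parameters apart, AIC's fixed +2 per
    parameter is exceeded by chance fit improvement in ~14% of on-model
    datasets (P(χ²₂ > 4)), whereas BIC's ln(n) penalty keeps the
    false-selection rate near 1% at typical grid sizes.  Both criteria
    are available on each returned fit.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    fits = {m: global_fit(d, model=m, n_starts=n_starts, seed=seed,
                          sub_max=np.inf, inhib_min=0.0 if m == "eq4"
                          else INHIBITORY_MIN_UM)
            for m in candidates}
    best = min(fits, key=lambda m: getattr(fits[m], criterion))
    return best, fits


# ---------------------------------------------------------------------------
# Product inhibition

@dataclass
class ProductInhibitionResult:
    """Double-reciprocal product-inhibition diagnosis."""

    inhibitor_um: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    convergence_point: Tuple[float, float]
    pattern: str
    ki_um: Optional[float]

    def to_dict(self) -> dict:
        return {
            "inhibitor_um": self.inhibitor_um.tolist(),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "convergence_point": [float(self.convergence_point[0]),
                                  float(self.convergence_point[1])],
            "pattern": self.pattern,
            "ki_um": None if self.ki_um is None else float(self.ki_um),
        }


def product_inhibition_analysis(d: RateDataset,
                                rel_tol: float = 0.15) -> ProductInhibitionResult:
    """Classify the product-inhibition pattern of NADH versus NAD+.

    Fits a double-reciprocal line 1/v vs 1/[NAD+] at each NADH level.
    Pairwise line intersections whose abscissae all lie within
    ``rel_tol`` of zero (relative to the sampled 1/[NAD+] range) indicate
    lines converging on the y-axis — the competitive signature.  Parallel
    lines (equal slopes, distinct intercepts) are uncompetitive; a common
    intersection at negative abscissa is noncompetitive.  K_i comes from
    the linear replot of slopes versus [NADH] (K_i = −x-intercept).
    """
    if d.nadh_um is None:
        raise ValueError("dataset carries no NADH (product) levels")
    levels = np.unique(d.nadh_um)
    if levels.size < 3:
        raise ValueError("need >= 3 NADH levels")
    slopes, intercepts = [], []
    inv_a_all = []
    for lev in levels:
        mask = d.nadh_um == lev
        a = d.nad[mask]
        v = d.rates[mask]
        if np.unique(a).size < 4:
            raise ValueError(f"need >= 4 NAD+ concentrations at NADH={lev}")
        inv_a, inv_v = 1.0 / a, 1.0 / v
        res = stats.linregress(inv_a, inv_v)
        slopes.append(res.slope)
        intercepts.append(res.intercept)
        inv_a_all.append(inv_a)
    slopes = np.array(slopes)
    intercepts = np.array(intercepts)
    inv_a_scale = float(np.max(np.concatenate(inv_a_all)))

    slope_spread = np.ptp(slopes) / np.mean(np.abs(slopes))
    intercept_spread = np.ptp(intercepts) / np.mean(np.abs(intercepts))

    xs, ys = [], []
    for i in range(levels.size):
        for j in range(i + 1, levels.size):
            dm = slopes[i] - slopes[j]
            if abs(dm) < 1e-12 * max(abs(slopes[i]), abs(slopes[j])):
                continue
            x = (intercepts[j] - intercepts[i]) / dm
            xs.append(x)
            ys.append(slopes[i] * x + intercepts[i])

    if slope_spread < 0.02 and intercept_spread < 0.02:
        pattern = "ambiguous"  # collinear lines: no inhibition signal
        cp = (np.nan, np.nan)
    elif not xs:
        pattern = "uncompetitive"  # parallel lines never intersect
        cp = (np.nan, np.nan)
    else:
        xs, ys = np.array(xs), np.array(ys)
        cp = (float(np.mean(xs)), float(np.mean(ys)))
        if np.all(np.abs(xs) <= rel_tol * inv_a_scale):
            pattern = "competitive"
        elif slope_spread < 0.02:
            pattern = "uncompetitive"
        elif np.all(xs < 0) and np.ptp(xs) <= rel_tol * inv_a_scale:
            pattern = "noncompetitive"
        else:
            pattern = "ambiguous"

    ki = None
    rep = stats.linregress(levels, slopes)
    if rep.slope > 0 and rep.intercept > 0:
        ki = float(rep.intercept / rep.slope)  # −x-intercept of slope replot
    return ProductInhibitionResult(
        inhibitor_um=levels, slopes=slopes, intercepts=intercepts,
        convergence_point=cp, pattern=pattern, ki_um=ki)


# ---------------------------------------------------------------------------
# Uncertainty

def uncertainty(fit: GlobalFitResult, method: str = "covariance",
                n_boot: int = 500, seed: int = 0) -> dict:
    """Per-parameter standard errors for a converged global fit.

    ``method="covariance"`` returns the Jacobian-based asymptotic SEs
    already computed at the optimum; ``"bootstrap"`` re-estimates them by
    residual resampling (seeded, ``n_boot`` replicates).
    """
    if not fit.converged:
        raise ValueError("uncertainty requires a converged fit")
    if method == "covariance":
        if any(not np.isfinite(v) for v in fit.stderr.values()):
            raise FitError("singular Jacobian: covariance unavailable; "
                           "use method='bootstrap'")
        return dict(fit.stderr)
    if method != "bootstrap":
        raise ValueError("method must be 'covariance' or 'bootstrap'")
    d = fit._dataset
    lsq = fit._lsq
    if d is None or lsq is None:
        raise ValueError("fit does not carry its dataset; refit first")
    a, b = d.nad, d.ssa
    theta_hat = lsq.values()
    model_vals = _model_eval(fit.model, a, b, theta_hat)
    residuals = d.rates - model_vals
    names = _MODEL_NAMES[fit.model]
    k = len(names)
    lo = np.full(k, 1e-12)
    hi = np.full(k, np.inf)
    if fit.model == "eq5":
        lo[-1], hi[-1] = 0.0, 1.0

    def refit(y):
        def res(theta):
            return _model_eval(fit.model, a, b, theta) - y
        f = fit_least_squares(res, theta_hat, names, bounds=(lo, hi))
        return f.values()

    return bootstrap_stderr(lsq, refit, model_vals, residuals,
                            n_boot=n_boot, seed=seed)
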