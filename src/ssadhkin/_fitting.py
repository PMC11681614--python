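"""Shared nonlinear least-squares plumbing.

Thin wrappers around :func:`scipy.optimize.least_squares` that return a
uniform result record (parameters, asymptotic standard errors from the
Jacobian, RSS, AIC, convergence flag, warnings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a fit cannot be completed; carries the best iterate."""

    def __init__(self, message: str, best: Optional[dict] = None):
        super().__init__(message)
        self.best = best


@dataclass
class LsqFit:
    """Result of a least-squares fit.

    ``params``/``stderr`` map parameter names to values; ``stderr`` entries
    are NaN when the Jacobian is singular at the optimum.
    """

    params: dict
    stderr: dict
    rss: float
    n: int
    converged: bool
    warnings: list = field(default_factory=list)
    jac: Optional[np.ndarray] = None
    residual_fn: Optional[Callable] = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        """AIC under iid-Gaussian residuals: n·ln(RSS/n) + 2k."""
        rss = max(self.rss, 1e-300)
        return self.n * np.log(rss / self.n) + 2 * self.n_params

    @property
    def bic(self) -> float:
        """BIC under iid-Gaussian residuals: n·ln(RSS/n) + ln(n)·k."""
        rss = max(self.rss, 1e-300)
        return self.n * np.log(rss / self.n) + np.log(self.n) * self.n_params

    def values(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "rss": float(self.rss),
            "n": int(self.n),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "warnings": list(self.warnings),
        }


def _stderr_from_jac(jac: np.ndarray, rss: float, n: int, k: int) -> np.ndarray:
    dof = max(n - k, 1)
    s2 = rss / dof
    try:
        jtj = jac.T @ jac
        cov = s2 * np.linalg.inv(jtj)
        diag = np.diag(cov)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.where(diag >= 0, diag, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


def fit_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    x0: Sequence[float],
    names: Sequence[str],
    bounds=(-np.inf, np.inf),
    n_obs: Optional[int] = None,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    max_nfev: int = 5000,
) -> LsqFit:
    """Single bounded least-squares solve with uniform reporting."""
    x0 = np.asarray(x0, dtype=float)
    sol = least_squares(residual, x0, bounds=bounds, xtol=xtol, ftol=ftol,
                        gtol=1e-12, max_nfev=max_nfev, method="trf")
    n = n_obs if n_obs is not None else sol.fun.size
    rss = float(sol.fun @ sol.fun)
    se = _stderr_from_jac(sol.jac, rss, n, x0.size)
    warnings = []
    lo, hi = np.broadcast_to(bounds[0], x0.shape), np.broadcast_to(bounds[1], x0.shape)
    at_bound = (np.isfinite(lo) & np.isclose(sol.x, lo, rtol=1e-6, atol=1e-12)) | (
        np.isfinite(hi) & np.isclose(sol.x, hi, rtol=1e-6, atol=0)
    )
    for name, flag in zip(names, at_bound):
        if flag:
            warnings.append(f"parameter {name} at bound")
    return LsqFit(
        params=dict(zip(names, map(float, sol.x))),
        stderr=dict(zip(names, map(float, se))),
        rss=rss,
        n=n,
        converged=bool(sol.success),
        warnings=warnings,
        jac=sol.jac,
        residual_fn=residual,
    )


def multistart_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[Sequence[float]],
    names: Sequence[str],
    bounds=(-np.inf, np.inf),
    **kwargs,
) -> LsqFit:
    """Run several starts; keep the lowest RSS (ties: smallest ‖θ‖)."""
    best: Optional[LsqFit] = None
    n_ok = 0
    for x0 in starts:
        try:
            fit = fit_least_squares(residual, x0, names, bounds=bounds, **kwargs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.converged:
            continue
        n_ok += 1
        if best is None or fit.rss < best.rss - 1e-9 or (
            abs(fit.rss - best.rss) < 1e-9
            and np.linalg.norm(fit.values()) < np.linalg.norm(best.values())
        ):
            best = fit
    if best is None:
        raise FitError("no multistart converged")
    return best


def bootstrap_stderr(
    fit: LsqFit,
    refit: Callable[[np.ndarray], np.ndarray],
    fitted: np.ndarray,
    residuals: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Residual-resampling bootstrap standard errors.

    ``refit(y)`` must return the parameter vector fitted to synthetic
    response ``y``; ``fitted`` are model values at the optimum and
    ``residuals`` the observed minus fitted values.
    """
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        resampled = rng.choice(residuals, size=residuals.size, replace=True)
        try:
            draws.append(refit(fitted + resampled))
        except (FitError, ValueError):
            continue
    draws = np.asarray(draws)
    se = draws.std(axis=0, ddof=1) if len(draws) > 1 else np.zeros(fit.n_params)
    return dict(zip(fit.params.keys(), map(float, se)))
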