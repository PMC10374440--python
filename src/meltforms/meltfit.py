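"""Sigmoid melting-curve model: fitting, melting point and melting AUC.

Thermal denaturation of a proteoform is modeled by the three-parameter
sigmoid

    f(T) = (1 - p) / (1 + exp(b - a/T)) + p,

with temperature T in degrees Celsius, a plateau p in [0, 1) and shape
parameters a, b controlling slope and inflection.  The melting point Tm is
the temperature at which the fitted curve crosses 0.5 and has the closed
form Tm = a / (b - ln(0.5 / (0.5 - p))), defined only for p < 0.5.  The
melting AUC is the integral of the fitted curve over the experimental
temperature window and serves as a per-cell-line thermal-stability summary
robust to curves that never cross 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "SigmoidFit",
    "sigmoid",
    "fit_sigmoid",
    "melting_point",
    "melting_auc",
]

#: residual standard deviation above which a fit is flagged rejected
S_RES_MAX_DEFAULT = 0.1


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters plus quality measures for one melting curve."""

    a: float
    b: float
    p: float
    rss: float
    s_res: float
    n_points: int
    converged: bool
    accepted: bool  # converged and s_res below the acceptance cut
    tm: float | None = None
    auc: float | None = None


def sigmoid(T, a: float, b: float, p: float):
    """Evaluate f(T) = (1 - p) / (1 + exp(b - a/T)) + p at T > 0 (Celsius)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    z = np.clip(b - a / T, -700.0, 700.0)
    out = (1.0 - p) / (1.0 + np.exp(z)) + p
    return float(out) if out.ndim == 0 else out


def _residuals(theta, T, y):
    a, b, p = theta
    z = np.clip(b - a / T, -700.0, 700.0)
    return (1.0 - p) / (1.0 + np.exp(z)) + p - y


_P_MAX = 1.0 - 1e-9


def fit_sigmoid(
    temps: np.ndarray,
    values: np.ndarray,
    s_res_max: float = S_RES_MAX_DEFAULT,
) -> SigmoidFit:
    """Least-squares fit of the melting sigmoid to one (temperature, value) series.

    Missing values are dropped; at least 4 points are required, otherwise the
    returned fit is marked non-converged and must be excluded downstream.
    The objective is non-convex, so optimization starts from a grid of
    candidate midpoints T0 in 44..60 C (b = b0, a = b0 * T0 so that the
    initial half-melt sits near T0, for a few slope scales b0) with
    p0 = min(last observed value, 0.3); the best grid start by residual sum
    of squares seeds a bounded trust-region refinement with p in [0, 1).
    """
    temps = np.asarray(temps, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(temps) & np.isfinite(values)
    T, y = temps[ok], values[ok]
    n = len(T)
    if n < 4:
        return SigmoidFit(
            a=np.nan, b=np.nan, p=np.nan, rss=np.nan, s_res=np.nan,
            n_points=n, converged=False, accepted=False,
        )

    p0 = float(min(max(y[np.argsort(T)][-1], 0.0), 0.3))
    starts = []
    for t0 in range(44, 61, 2):
        for b0 in (15.0, 50.0, 150.0):
            starts.append((b0 * t0, b0, p0))
    best = min(starts, key=lambda th: float(np.sum(_residuals(th, T, y) ** 2)))

    try:
        sol = optimize.least_squares(
            _residuals,
            x0=np.array(best),
            args=(T, y),
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, _P_MAX]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        converged = bool(sol.success) and np.all(np.isfinite(sol.x))
        a, b, p = (float(v) for v in sol.x)
        rss = float(np.sum(sol.fun**2))
    except Exception:
        converged, a, b, p, rss = False, np.nan, np.nan, np.nan, np.nan

    s_res = math.sqrt(rss / (n - 3)) if converged and n > 3 else np.nan
    fit = SigmoidFit(
        a=a, b=b, p=p, rss=rss, s_res=s_res, n_points=n,
        converged=converged,
        accepted=bool(converged and s_res < s_res_max),
    )
    if converged:
        fit.tm = melting_point(fit)
    return fit


def melting_point(fit: SigmoidFit) -> float | None:
    """Temperature at which the fitted curve crosses 0.5, or None.

    Undefined when the plateau p >= 0.5 (the curve never reaches 0.5) or
    when the closed form falls outside (0, inf).
    """
    if not fit.converged:
        return None
    if fit.p >= 0.5:
        return None
    denom = fit.b - math.log(0.5 / (0.5 - fit.p))
    if denom <= 0:
        return None
    tm = fit.a / denom
    return tm if tm > 0 and math.isfinite(tm) else None


def melting_auc(fit: SigmoidFit, t_min: float = 41.0, t_max: float = 63.0) -> float:
    """Integral of the fitted sigmoid over [t_min, t_max] (degC x fold change)."""
    if t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    if not fit.converged:
        raise ValueError("cannot integrate a non-converged fit")
    val, _ = integrate.quad(
        lambda T: sigmoid(T, fit.a, fit.b, fit.p), t_min, t_max, epsabs=1e-8,
        limit=200,
    )
    return float(val)
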