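"""Differential melting across cell lines (NPARC-style F-test).

For each proteoform group quantified in enough cell lines, an *alternative*
model fits one sigmoid per cell line and a *null* model fits a single shared
sigmoid to the pooled points of all cell lines whose alternative fit was
accepted (residual standard deviation S_res < 0.1).  The statistic

    F = (RSS0 - RSS1) / RSS0 * d2 / d1,
    d1 = nu1 - nu0,   d2 = p_i - nu0,

compares the null residual sum of squares RSS0 against the summed per-line
alternative RSS1, with nu0 = 3 shared parameters, nu1 = 3 per kept cell line
and p_i the total number of kept observations.  This is the statistic as
published; the classical partial-F (denominator RSS1, d2 = p_i - nu1) is
available behind ``f_variant='classical'``.  Because cell-line heterogeneity
inflates the F distribution relative to its theoretical null, hits are
called by rank: proteoforms above the 90th percentile of observed F values
are flagged as differentially melting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import FoldChangeTensor
from .meltfit import SigmoidFit, fit_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "NparcResult",
    "compute_f_statistic",
    "nparc_test",
    "run_nparc",
    "call_differential",
]


@dataclass
class NparcResult:
    proteoform_id: str
    n_cell_lines_used: int
    rss0: float
    rss1: float
    f_statistic: float
    d1: int
    d2: int
    n_obs: int  # p_i: total kept observations
    nu0: int
    nu1: int
    testable: bool
    is_hit: bool = False
    cell_lines_used: tuple[str, ...] = ()
    line_fits: dict[str, SigmoidFit] | None = None
    null_fit: SigmoidFit | None = None


def compute_f_statistic(
    rss0: float,
    rss1: float,
    n_obs: int,
    nu0: int,
    nu1: int,
    f_variant: str = "as_published",
) -> tuple[float, int, int]:
    """F statistic with degrees of freedom for the null/alternative comparison.

    Returns (F, d1, d2).  'as_published' uses F = (RSS0-RSS1)/RSS0 * d2/d1
    with d2 = n_obs - nu0; 'classical' uses the partial-F
    ((RSS0-RSS1)/d1) / (RSS1/d2) with d2 = n_obs - nu1.
    """
    d1 = nu1 - nu0
    if d1 <= 0:
        raise ValueError("alternative model must have more parameters than null")
    if f_variant == "as_published":
        d2 = n_obs - nu0
        if d2 <= 0:
            raise ValueError("not enough observations")
        f = (rss0 - rss1) / rss0 * d2 / d1 if rss0 > 0 else 0.0
    elif f_variant == "classical":
        d2 = n_obs - nu1
        if d2 <= 0:
            raise ValueError("not enough observations")
        f = ((rss0 - rss1) / d1) / (rss1 / d2) if rss1 > 0 else np.inf
    else:
        raise ValueError(f"unknown f_variant: {f_variant!r}")
    return float(f), d1, d2


def nparc_test(
    profile: np.ndarray,
    temperatures: np.ndarray,
    cell_lines: list[str],
    proteoform_id: str = "",
    min_cell_lines: int = 10,
    s_res_max: float = 0.1,
    f_variant: str = "as_published",
) -> NparcResult:
    """Null-vs-alternative sigmoid comparison for one proteoform.

    ``profile`` has shape (cell lines, temperatures) with NaN for missing.
    Cell lines with fewer than 4 points, non-converged fits or
    S_res >= ``s_res_max`` are dropped; the result is flagged not-testable if
    fewer than ``min_cell_lines`` remain.
    """
    profile = np.asarray(profile, dtype=float)
    temps = np.asarray(temperatures, dtype=float)

    line_fits: dict[str, SigmoidFit] = {}
    kept: list[str] = []
    rss1 = 0.0
    pooled_T: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    for n, cl in enumerate(cell_lines):
        y = profile[n]
        if np.isfinite(y).sum() < 4:
            continue
        fit = fit_sigmoid(temps, y, s_res_max=s_res_max)
        line_fits[cl] = fit
        if not fit.accepted:
            continue
        kept.append(cl)
        rss1 += fit.rss
        ok = np.isfinite(y)
        pooled_T.append(temps[ok])
        pooled_y.append(y[ok])

    m = len(kept)
    nu0, nu1 = 3, 3 * m
    if m < min_cell_lines:
        return NparcResult(
            proteoform_id=proteoform_id, n_cell_lines_used=m,
            rss0=np.nan, rss1=np.nan, f_statistic=np.nan,
            d1=0, d2=0, n_obs=0, nu0=nu0, nu1=nu1, testable=False,
            cell_lines_used=tuple(kept), line_fits=line_fits,
        )

    T_all = np.concatenate(pooled_T)
    y_all = np.concatenate(pooled_y)
    null_fit = fit_sigmoid(T_all, y_all, s_res_max=np.inf)
    n_obs = len(T_all)
    if not null_fit.converged:
        logger.warning("null fit failed for %s", proteoform_id)
        return NparcResult(
            proteoform_id=proteoform_id, n_cell_lines_used=m,
            rss0=np.nan, rss1=rss1, f_statistic=np.nan,
            d1=nu1 - nu0, d2=0, n_obs=n_obs, nu0=nu0, nu1=nu1, testable=False,
            cell_lines_used=tuple(kept), line_fits=line_fits,
        )
    rss0 = null_fit.rss
    f, d1, d2 = compute_f_statistic(rss0, rss1, n_obs, nu0, nu1, f_variant)
    return NparcResult(
        proteoform_id=proteoform_id, n_cell_lines_used=m,
        rss0=rss0, rss1=rss1, f_statistic=f, d1=d1, d2=d2,
        n_obs=n_obs, nu0=nu0, nu1=nu1, testable=True,
        cell_lines_used=tuple(kept), line_fits=line_fits, null_fit=null_fit,
    )


def run_nparc(
    profiles: FoldChangeTensor,
    min_cell_lines: int = 10,
    s_res_max: float = 0.1,
    f_variant: str = "as_published",
    percentile: float = 90.0,
) -> list[NparcResult]:
    """NPARC test for every proteoform in the tensor, with hit calling."""
    results = []
    for i, pid in enumerate(profiles.ids):
        results.append(
            nparc_test(
                profiles.x[i], profiles.temperatures, profiles.cell_lines,
                proteoform_id=pid, min_cell_lines=min_cell_lines,
                s_res_max=s_res_max, f_variant=f_variant,
            )
        )
    return call_differential(results, percentile=percentile)


def call_differential(
    results: list[NparcResult],
    percentile: float = 90.0,
) -> list[NparcResult]:
    """Flag proteoforms whose F reaches the given percentile of testable F values.

    The percentile uses linear interpolation between order statistics; ties
    at the threshold count as hits.
    """
    testable = [r for r in results if r.testable and np.isfinite(r.f_statistic)]
    if not testable:
        logger.warning("no testable NPARC results; empty hit list")
        return results
    if len(testable) < 10:
        logger.warning("only %d testable NPARC results; percentile unstable",
                       len(testable))
    threshold = float(np.percentile([r.f_statistic for r in testable], percentile))
    for r in results:
        r.is_hit = bool(
            r.testable and np.isfinite(r.f_statistic) and r.f_statistic >= threshold
        )
    return results


def nparc_to_frame(results: list[NparcResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "proteoform_id": r.proteoform_id,
                "n_lines": r.n_cell_lines_used,
                "rss0": r.rss0,
                "rss1": r.rss1,
                "d1": r.d1,
                "d2": r.d2,
                "F": r.f_statistic,
                "testable": r.testable,
                "is_hit": r.is_hit,
            }
            for r in results
        ]
    )
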