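"""Wound contraction/closure percentages and one-phase-decay fits.

Two per-timepoint percentages:

- contraction (%) = (IW_D0 − IW_t)/IW_D0 × 100, where IW_t is the area
  inside the initial wound edge — positive and growing as the inner area
  shrinks, 100 at full closure;
- closure (%) = area_t/area_D0 × 100 — 100 at day 0, falling toward 0.

Healing kinetics follow the one-phase exponential decay
Y(t) = plateau + (Y0 − plateau)·e^{−kt}, fitted by bounded trust-region
nonlinear least squares; half-life = ln2/k. Fits on ≤6 points are
sensitive to initialization, so starting values come from the data: Y0
from the first observation, plateau from the minimum, k from a log-linear
regression of the plateau-subtracted signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulate import WoundSeries

__all__ = [
    "DecayFit",
    "wound_contraction",
    "wound_closure",
    "fit_one_phase_decay",
    "WoundSeries",
]

FIT_VARIABLES = ("area", "contraction_complement")


@dataclass(frozen=True)
class DecayFit:
    """Fitted one-phase-decay parameters for a wound series."""

    Y0: float
    plateau: float
    k: float
    half_life: float
    rss: float
    converged: bool
    fit_variable: str = "area"


def wound_contraction(iw_t: float, iw_d0: float) -> float:
    """Wound contraction (%) = ΔIW_t / IW_D0 × 100, Δ = IW_D0 − IW_t."""
    if iw_d0 <= 0:
        raise ValueError("baseline inner-wound area IW_D0 must be > 0")
    if iw_t < 0:
        raise ValueError("inner-wound area must be ≥ 0")
    return (iw_d0 - iw_t) / iw_d0 * 100.0


def wound_closure(area_t: float, area_d0: float) -> float:
    """Wound closure (%) = area_t / area_D0 × 100."""
    if area_d0 <= 0:
        raise ValueError("baseline wound area must be > 0")
    if area_t < 0:
        raise ValueError("wound area must be ≥ 0")
    return area_t / area_d0 * 100.0


def _model(t: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return plateau + (y0 - plateau) * np.exp(-k * t)


def _init_k(t: np.ndarray, y: np.ndarray, plateau0: float) -> float:
    # log-linear slope of (Y − 0.99·plateau_init); 0.99 keeps the minimum
    # observation strictly positive after subtraction
    shifted = y - 0.99 * plateau0
    pos = shifted > 0
    if pos.sum() < 2:
        return 1.0
    slope = np.polyfit(t[pos], np.log(shifted[pos]), 1)[0]
    return max(-slope, 1e-6)


def fit_one_phase_decay(
    series: WoundSeries,
    fit_variable: str = "area",
    fix_plateau: float | None = None,
) -> DecayFit:
    """Fit Y(t) = plateau + (Y0 − plateau)·e^{−kt} to a wound series.

    Parameters
    ----------
    series
        Timepoints (days) and inner-wound areas; ≥3 points required.
    fit_variable
        ``"area"`` fits the raw areas; ``"contraction_complement"`` fits
        100 − contraction% (equals 100·IW_t/IW_D0, a decay from 100).
    fix_plateau
        If given, the plateau is held at this value instead of fitted.

    Bounds k ≥ 0 and plateau ≥ 0 are enforced; tolerance 1e-8 on the
    parameters. Non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    if fit_variable not in FIT_VARIABLES:
        raise ValueError(f"fit_variable must be one of {FIT_VARIABLES}")
    t = np.asarray(series.times, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints for a decay fit")
    if t[-1] - t[0] <= 0:
        raise ValueError("times must span a positive interval")
    if fit_variable == "area":
        y = np.asarray(series.areas, dtype=float)
    else:
        y = np.array(
            [100.0 - wound_contraction(a, series.areas[0]) for a in series.areas]
        )

    y0_init = y[0]
    plateau_init = fix_plateau if fix_plateau is not None else float(y.min())
    k_init = _init_k(t, y, plateau_init)

    if fix_plateau is None:
        def resid(p):
            return _model(t, p[0], p[1], p[2]) - y
        x0 = [y0_init, plateau_init, k_init]
        lb = [-np.inf, 0.0, 0.0]
        ub = [np.inf, np.inf, np.inf]
    else:
        def resid(p):
            return _model(t, p[0], fix_plateau, p[1]) - y
        x0 = [y0_init, k_init]
        lb = [-np.inf, 0.0]
        ub = [np.inf, np.inf]
    x0 = np.clip(x0, lb, ub)

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-8, ftol=1e-8,
                        gtol=1e-8, max_nfev=2000)
    if fix_plateau is None:
        y0_hat, plateau_hat, k_hat = sol.x
    else:
        (y0_hat, k_hat), plateau_hat = sol.x, fix_plateau
    rss = float(np.sum(sol.fun ** 2))
    half_life = np.inf if k_hat == 0 else float(np.log(2.0) / k_hat)
    return DecayFit(Y0=float(y0_hat), plateau=float(plateau_hat),
                    k=float(k_hat), half_life=half_life, rss=rss,
                    converged=bool(sol.success), fit_variable=fit_variable)
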