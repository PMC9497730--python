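"""Washout kinetics: simulated decay curves, exponential fits, washout time.

After immersion the retained contrast leaves the cartilage into a clean
bath; the retained concentration is modelled as a single exponential decay

    c(t) = a_w * exp(-b_w * t),

with ``a_w`` the initial (post-immersion) concentration in mgI/mL and
``b_w`` the washout rate in 1/h. The washout time is the time for the
retained signal to fall to 5% of a reference level: ``t_w = ln(a_w /
(0.05 * reference)) / b_w``, which reduces to ``ln(20)/b_w`` when the
reference is the fitted initial value itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import FitConvergenceError

__all__ = [
    "WashoutFit",
    "simulate_washout_curve",
    "fit_washout",
    "washout_time",
    "WASHOUT_TIMES_H",
]

#: Default washout sampling: baseline, 24 h and 48 h rinses.
WASHOUT_TIMES_H: tuple[float, ...] = (0.0, 24.0, 48.0)


@dataclass(frozen=True)
class WashoutFit:
    """Exponential washout fit. ``degenerate`` marks a non-decaying input
    (b_w at the zero boundary, washout time infinite)."""

    aw: float  # mgI/mL
    bw: float  # 1/h
    r2: float
    tw: float  # h, ln(20)/bw
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.aw <= 0:
            raise ValueError("aw must be positive")
        if not self.degenerate and self.bw <= 0:
            raise ValueError("bw must be positive for a non-degenerate fit")

    def predict(self, t):
        return self.aw * np.exp(-self.bw * np.asarray(t, dtype=float))


def simulate_washout_curve(
    c0: float,
    bw: float,
    times=WASHOUT_TIMES_H,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate a washout curve ``c0 * exp(-bw * t)`` plus noise."""
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if bw <= 0:
        raise ValueError("bw must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    c = c0 * np.exp(-bw * t)
    if noise_sd > 0:
        c = c + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return t, c


def fit_washout(times, concentrations) -> WashoutFit:
    """Nonlinear least-squares fit of ``c(t) = a_w exp(-b_w t)``.

    Initialized by log-linear regression (exact on noiseless data); if any
    concentration is non-positive the initialization falls back to
    ``a0 = max(c)``, ``b0 = 1/span`` and the fit proceeds directly in the
    nonlinear model. Inputs with no decaying trend return a fit flagged
    ``degenerate`` (b_w = 0, t_w = inf) with a warning.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concentrations must have the same length")
    if t.size < 3:
        raise ValueError("need at least 3 points for a washout fit")
    if np.ptp(c) == 0:
        warnings.warn("constant concentrations: washout rate at the zero boundary",
                      stacklevel=2)
        return WashoutFit(aw=float(c[0]), bw=0.0, r2=1.0, tw=np.inf, degenerate=True)

    if np.all(c > 0):
        res = linregress(t, np.log(c))
        a0, b0 = float(np.exp(res.intercept)), float(-res.slope)
    else:
        a0, b0 = float(c.max()), 1.0 / float(np.ptp(t) or 1.0)
    if b0 <= 0:
        warnings.warn("no decaying trend in concentrations; degenerate washout fit",
                      stacklevel=2)
        return WashoutFit(aw=float(np.mean(c[c > 0]) if np.any(c > 0) else 1.0),
                          bw=0.0, r2=0.0, tw=np.inf, degenerate=True)

    def model(tt, aw, bw):
        return aw * np.exp(-bw * tt)

    attempts = []
    for scale in (1.0, 0.5, 2.0):
        p0 = (a0, b0 * scale)
        try:
            popt, _ = curve_fit(
                model, t, c, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:
            attempts.append((p0, str(exc)))
            continue
        resid = c - model(t, *popt)
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        bw = float(popt[1])
        return WashoutFit(aw=float(popt[0]), bw=bw, r2=r2, tw=float(np.log(20.0) / bw))
    raise FitConvergenceError(
        f"washout fit failed after {len(attempts)} restarts", attempts=attempts
    )


def washout_time(fit: WashoutFit, reference: float) -> float:
    """Time for the fitted decay to fall to 5% of ``reference`` (h).

    ``t = ln(a_w / (0.05 * reference)) / b_w``; with ``reference = a_w``
    this is ``ln(20)/b_w``. If the fit already starts below the 5% level the
    time is undefined and a ValueError is raised; exactly at the level the
    time is 0.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    if fit.degenerate:
        return np.inf
    level = 0.05 * reference
    if level > fit.aw:
        raise ValueError(
            f"fit starts at {fit.aw:.4g} mgI/mL, already below the 5% level "
            f"{level:.4g}; washout time undefined"
        )
    return float(np.log(fit.aw / level) / fit.bw)
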