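"""Single-exponential fitting of kinetic traces and quality-control filtering.

Each trace is fitted with the three-parameter exponential decay

    y(t) = A * exp(-k * t) + y0

by unbounded Levenberg-Marquardt least squares (t in minutes, k in
min^-1; equivalently A * exp(-t/tau) + y0 with tau = 1/k).  k is left
unbounded so that rising traces fit with k < 0 and can be removed by the
sign filter rather than being silently clamped.  The per-cell rate
constant k_efflux, its standard error (from the scaled covariance) and
the relative standard error RSE = 100 * SE(k) / |k| feed the acceptance
rule: keep converged fits with k > 0 and RSE <= 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["ExpFit", "fit_expdec1", "fit_traces", "qc_filter"]

FIT_COLUMNS = [
    "cell_id",
    "k_per_min",
    "se_k",
    "rse_percent",
    "amplitude",
    "y0",
    "tau_min",
    "rss",
    "n_points",
    "converged",
]


@dataclass
class ExpFit:
    """Result of one single-exponential fit.

    k_per_min is the efflux rate constant (min^-1); se_k its standard
    error; rse_percent = 100 * se_k / |k|; tau_min = 1/k the decay time.
    Non-convergence is reported (converged=False, NaN estimates), never
    raised.
    """

    cell_id: int | str
    k_per_min: float
    se_k: float
    rse_percent: float
    amplitude: float
    y0: float
    rss: float
    n_points: int
    converged: bool

    @property
    def tau_min(self) -> float:
        return 1.0 / self.k_per_min if self.k_per_min != 0 else np.inf


def _model(t, a, k, y0):
    return a * np.exp(-k * t) + y0


def _initial_guess(t_min: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Data-driven start: offset from the trace minimum, amplitude from the
    first point, rate from a log-linear regression over the first half."""
    y0 = float(y.min())
    a = float(y[0] - y0)
    if a <= 0:
        a = max(float(y.max() - y.min()), 1.0)
    half = max(len(t_min) // 2, 2)
    shifted = y[:half] - y0
    pos = shifted > 0
    k0 = None
    if pos.sum() >= 2:
        slope = np.polyfit(t_min[:half][pos], np.log(shifted[pos]), 1)[0]
        if np.isfinite(slope) and slope != 0:
            k0 = -slope  # positive log-slope = rising trace = negative k start
    if k0 is None:
        k0 = 3.0 / max(t_min[-1] - t_min[0], 1e-9)  # tau ~ duration / 3
    return a, k0, y0


def fit_expdec1(times_s: np.ndarray, intensities: np.ndarray, cell_id: int | str = 0) -> ExpFit:
    """Fit one trace with y(t) = A exp(-k t) + y0; k in min^-1.

    Requires >= 5 finite points.  SE(k) comes from the residual-scaled
    covariance (the convention of common fitting software); a singular or
    non-finite covariance yields SE = inf, so the fit is rejected by the
    RSE rule downstream rather than raising.
    """
    t = np.asarray(times_s, dtype=float) / 60.0
    y = np.asarray(intensities, dtype=float)
    if len(t) < 5:
        raise ValueError("trace needs at least 5 points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trace")

    # normalize so the optimization is exactly invariant to intensity scaling
    # and to the time unit: u in [0, 1], y of order 1
    t0, span = t[0], t[-1] - t[0]
    if span <= 0:
        raise ValueError("times must span a positive interval")
    u = (t - t0) / span
    y_scale = float(np.max(np.abs(y))) or 1.0
    yn = y / y_scale

    a0, k0, y00 = _initial_guess(u, yn)
    try:
        with warnings.catch_warnings():
            # singular covariance is handled below via se_k = inf
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                _model, u, yn, p0=(a0, k0, y00), method="lm", maxfev=1000, xtol=1e-8, ftol=1e-8
            )
        converged = True
    except RuntimeError:
        return ExpFit(cell_id, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, len(t), False)
    an, kn, y0n = popt
    k = kn / span
    with np.errstate(invalid="ignore", over="ignore"):
        se_k = float(np.sqrt(pcov[1, 1]) / span) if np.all(np.isfinite(pcov)) else np.inf
        a = float(an * y_scale * np.exp(-kn * (-t0 / span)))  # amplitude referred to t = 0
    if not np.isfinite(se_k):
        se_k = np.inf
    rse = 100.0 * se_k / abs(k) if k != 0 else np.inf
    rss = float(np.sum((_model(u, *popt) - yn) ** 2)) * y_scale**2
    if not np.isfinite(a):
        a = np.nan
    return ExpFit(cell_id, float(k), se_k, rse, a, float(y0n * y_scale), rss, len(t), converged)


def fit_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Fit every cell's trace in a long table (cell_id, t_seconds, intensity)."""
    rows = []
    for cell_id, sub in traces.groupby("cell_id"):
        sub = sub.sort_values("t_seconds")
        fit = fit_expdec1(sub["t_seconds"].to_numpy(), sub["intensity"].to_numpy(), cell_id)
        rows.append(
            {
                "cell_id": fit.cell_id,
                "k_per_min": fit.k_per_min,
                "se_k": fit.se_k,
                "rse_percent": fit.rse_percent,
                "amplitude": fit.amplitude,
                "y0": fit.y0,
                "tau_min": fit.tau_min,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def qc_filter(fits: pd.DataFrame) -> pd.DataFrame:
    """Apply the acceptance rule: converged, k_efflux > 0, RSE <= 100%.

    Returns the table with two added columns: ``accepted`` and
    ``reject_reason`` ("" | "not_converged" | "negative_k" | "high_rse").
    RSE of exactly 100% is kept (the cut is strictly "> 100%").
    """
    fits = fits.copy()
    reason = np.full(len(fits), "", dtype=object)
    conv = fits["converged"].to_numpy(dtype=bool) if len(fits) else np.array([], bool)
    k = fits["k_per_min"].to_numpy(dtype=float) if len(fits) else np.array([])
    rse = fits["rse_percent"].to_numpy(dtype=float) if len(fits) else np.array([])
    with np.errstate(invalid="ignore"):
        reason[~conv] = "not_converged"
        bad_k = conv & ~(k > 0)
        reason[bad_k] = "negative_k"
        bad_rse = conv & (k > 0) & ~(rse <= 100.0)
        reason[bad_rse] = "high_rse"
    fits["accepted"] = reason == ""
    fits["reject_reason"] = reason
    return fits


def accepted_k(fits: pd.DataFrame) -> np.ndarray:
    """Accepted k_efflux values (min^-1) after qc_filter (applied if needed)."""
    if "accepted" not in fits.columns:
        fits = qc_filter(fits)
    return fits.loc[fits["accepted"], "k_per_min"].to_numpy(dtype=float)
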