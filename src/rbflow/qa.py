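"""Injection quality assurance via gamma-variate fits to the blood TAC.

A first-pass bolus through the blood pool is well described by a
gamma-variate.  We use the peak-normalized parameterization

    C(t) = A * ((t - t0) / (alpha * tau))^alpha * exp(alpha - (t - t0)/tau)

for t > t0 (zero before onset), so that ``A`` is the peak value, reached at
``t = t0 + alpha * tau``.  Fitted shape parameters yield simple transit
metrics; scans whose metrics are cohort outliers are flagged for exclusion
(inconsistent tracer injection profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import TAC, ContinuousCurve, frame_average

__all__ = [
    "GammaVariateFit",
    "TransitMetrics",
    "gamma_variate",
    "fit_gamma_variate",
    "transit_metrics",
    "flag_outlier_scans",
]


class NoPeakError(ValueError):
    """The TAC has no interior maximum to anchor a bolus fit."""


@dataclass(frozen=True)
class GammaVariateFit:
    amplitude: float  # peak value, kBq/mL
    t0: float  # onset, s
    alpha: float  # shape, unitless
    tau: float  # timescale, s
    rss: float

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.tau


@dataclass(frozen=True)
class TransitMetrics:
    t_rise: float  # onset-to-peak time, alpha * tau
    t_clearance: float  # exponential tail timescale, tau
    t_mean_transit: float  # mean of the gamma density from onset, (alpha + 1) * tau


def gamma_variate(t, amplitude: float, t0: float, alpha: float, tau: float) -> np.ndarray:
    """Evaluate the peak-normalized gamma-variate at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    x = np.maximum(t - t0, 0.0) / (alpha * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = amplitude * np.power(x, alpha) * np.exp(alpha * (1.0 - x))
    return np.where(t > t0, out, 0.0)


def fit_gamma_variate(
    blood: TAC,
    step: float = 0.1,
    n_multistart: int = 4,
    seed: int = 0,
    window_s: float | None = 90.0,
) -> GammaVariateFit:
    """Bounded least squares of a frame-averaged gamma-variate to a blood TAC.

    Only frames starting before ``window_s`` enter the fit: the gamma-variate
    describes the first pass, and including recirculation-dominated late
    frames drags the shape parameters away from the bolus.
    """
    vals = blood.values
    ipk = int(np.argmax(vals))
    if ipk == 0 or ipk == vals.size - 1 or vals[ipk] <= 0:
        raise NoPeakError("blood TAC has no interior peak; cannot fit a bolus shape")

    grid = blood.grid
    keep = (
        grid.frame_start < window_s if window_s is not None else np.ones(vals.size, bool)
    )
    if keep.sum() <= ipk + 1:
        keep = grid.frame_start <= grid.frame_start[min(ipk + 2, vals.size - 1)]
    t_fine = np.arange(int(round(grid.end / step)) + 1) * step
    peak_guess = float(vals[ipk])
    tpk_guess = float(grid.frame_mid[ipk])

    def residuals(theta):
        a, t0, alpha, tau = theta
        fine = gamma_variate(t_fine, a, t0, alpha, tau)
        model = frame_average(ContinuousCurve(step, fine), grid).values
        return (model - vals)[keep]

    lo = np.array([1e-6, 0.0, 0.1, 0.5])
    hi = np.array([10.0 * peak_guess, grid.end / 2.0, 20.0, grid.end])
    base = np.array([peak_guess, max(tpk_guess - 24.0, 1.0), 3.0, 8.0])
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_multistart - 1):
        jitter = rng.uniform(0.5, 1.5, size=4)
        starts.append(np.clip(base * jitter, lo + 1e-9, hi - 1e-9))

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, np.clip(s, lo, hi), bounds=(lo, hi), xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("gamma-variate fit failed from every start")
    a, t0, alpha, tau = best.x
    return GammaVariateFit(float(a), float(t0), float(alpha), float(tau), 2.0 * best.cost)


def transit_metrics(fit: GammaVariateFit) -> TransitMetrics:
    """Transit metrics implied by the fitted bolus shape."""
    return TransitMetrics(
        t_rise=fit.alpha * fit.tau,
        t_clearance=fit.tau,
        t_mean_transit=(fit.alpha + 1.0) * fit.tau,
    )


def flag_outlier_scans(
    metrics: pd.DataFrame, threshold: float = 3.0, rel_floor: float = 0.5
) -> pd.Series:
    """Flag scans whose transit metrics are cohort outliers.

    ``metrics`` holds one row per scan and one column per metric.  A scan is
    flagged when any metric deviates from the cohort median by more than
    ``threshold`` times the scaled median absolute deviation (MAD * 1.4826)
    AND by more than ``rel_floor`` of the median itself.  The relative floor
    keeps tightly clustered cohorts (where the MAD is tiny) from flagging
    materially unremarkable scans; injection failures produce deviations far
    beyond both.  Deterministic, order- and scale-invariant.
    """
    if len(metrics) < 4:
        raise ValueError("outlier screening needs at least 4 scans")
    flags = pd.Series(False, index=metrics.index)
    for col in metrics.columns:
        x = metrics[col].to_numpy(dtype=float)
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        cut = max(threshold * mad, rel_floor * abs(med))
        if cut == 0:
            flags |= pd.Series(x != med, index=metrics.index)
        else:
            flags |= pd.Series(np.abs(x - med) > cut, index=metrics.index)
    return flags
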