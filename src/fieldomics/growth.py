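"""Thermal-time growth-curve phenotyping.

Plant height trajectories are modelled on a growing-degree-day (GDD) clock
with a beta-sigmoid curve

    h(t) = h0 + (hmax - h0) * (1 + (te - t)/(te - tm)) * (t/te)^(te/(te-tm))

for t < te, and h(t) = hmax for t >= te, where h0 and hmax are the initial
and final heights, tm the age (GDD) of maximal growth and te the age at the
end of growth.  Derived summary phenotypes are the maximum shoot growth rate
(dh/dt at tm, cm/GDD) and tm/te converted back to days after sowing (DAS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TemperatureSeries",
    "GrowthParams",
    "gdd_transform",
    "beta_sigmoid_height",
    "beta_sigmoid_rate",
    "fit_growth_curve",
    "growth_summary",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily mean air temperatures on a contiguous day grid.

    ``days`` are day-of-year indices that may run past 365 for trials
    spanning a year boundary; ``t_base`` is the base temperature (degC)
    below which no growth is assumed to occur.
    """

    days: np.ndarray
    temps: np.ndarray
    t_base: float = 5.0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        temps = np.asarray(self.temps, dtype=float)
        if days.shape != temps.shape or days.ndim != 1:
            raise ValueError("days and temps must be 1-D arrays of equal length")
        if len(days) and np.any(np.diff(days) != 1):
            raise ValueError("temperature series must cover contiguous days")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "temps", temps)

    def cumulative_gdd(self) -> np.ndarray:
        """Cumulative growing degree days at the end of each covered day."""
        return np.cumsum(np.maximum(self.temps - self.t_base, 0.0))


@dataclass
class GrowthParams:
    """Fitted beta-sigmoid parameters with fit diagnostics."""

    h0: float
    hmax: float
    tm: float
    te: float
    rss: float = np.nan
    converged: bool = True

    def validate(self) -> None:
        if not (0 <= self.h0 < self.hmax):
            raise ValueError("require 0 <= h0 < hmax")
        if not (0 < self.tm < self.te):
            raise ValueError("require 0 < tm < te")


def gdd_transform(days, temps: TemperatureSeries) -> np.ndarray:
    """Convert day-of-year indices to plant ages in growing degree days.

    The age at day i is the sum of max(T_j - T_b, 0) over all covered days
    j up to and including i, counted from the start of the series.
    """
    days = np.asarray(days, dtype=int)
    if days.size and (days.min() < temps.days[0] or days.max() > temps.days[-1]):
        raise ValueError("temperature series does not cover all requested days")
    cum = temps.cumulative_gdd()
    idx = days - temps.days[0]
    return cum[idx]


def beta_sigmoid_height(t, params: GrowthParams) -> np.ndarray:
    """Evaluate the beta-sigmoid height curve at ages t (GDD)."""
    params.validate()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    h0, hmax, tm, te = params.h0, params.hmax, params.tm, params.te
    exponent = te / (te - tm)
    tt = np.minimum(t, te)
    with np.errstate(divide="ignore"):
        h = h0 + (hmax - h0) * (1 + (te - tt) / (te - tm)) * (tt / te) ** exponent
    return np.where(t >= te, hmax, h)


def beta_sigmoid_rate(t: float, params: GrowthParams) -> float:
    """Analytic growth rate dh/dt (cm/GDD) of the beta-sigmoid at age t < te."""
    params.validate()
    if not 0 < t < params.te:
        raise ValueError("rate defined on (0, te)")
    h0, hmax, tm, te = params.h0, params.hmax, params.tm, params.te
    a = hmax - h0
    m = te / (te - tm)
    u = t / te
    # product rule on (1 + (te-t)/(te-tm)) * u^m
    return a * (-1.0 / (te - tm) * u**m + (1 + (te - t) / (te - tm)) * m * u ** (m - 1) / te)


def _residuals(theta: np.ndarray, ages: np.ndarray, heights: np.ndarray) -> np.ndarray:
    h0, hmax, tm, dte = theta
    p = GrowthParams(h0=h0, hmax=max(hmax, h0 + 1e-9), tm=tm, te=tm + dte)
    return beta_sigmoid_height(ages, p) - heights


def fit_growth_curve(ages, heights) -> GrowthParams:
    """Fit the beta-sigmoid curve to (age, height) pairs.

    Bounded trust-region nonlinear least squares; te is parametrized as
    tm + dte with dte > 0 so the tm < te constraint always holds.  Starting
    values: h0 = min height, hmax = max height, tm = age of the largest
    observed increment, te = 1.1x the last observed age.  A fit is flagged
    not-converged when the optimizer fails or the fitted curve degenerates
    (hmax ~ h0, or parameters pinned at their bounds).
    """
    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if len(ages) < 5:
        raise ValueError("need at least 5 (age, height) pairs")
    if len(ages) != len(heights):
        raise ValueError("ages and heights must have equal length")

    order = np.argsort(ages)
    ages, heights = ages[order], heights[order]
    incr = np.diff(heights)
    tm0 = ages[1:][np.argmax(incr)] if np.any(incr > 0) else np.median(ages)
    tm0 = max(tm0, 1e-3)
    te0 = 1.1 * ages[-1]
    h00 = max(heights.min(), 0.0)
    hm0 = max(heights.max(), h00 + 1.0)
    x0 = np.array([h00, hm0, tm0, max(te0 - tm0, 1.0)])

    lower = np.array([0.0, 1e-6, 1e-6, 1e-6])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    try:
        sol = least_squares(
            _residuals, x0, args=(ages, heights), bounds=(lower, upper), method="trf"
        )
    except Exception:
        return GrowthParams(np.nan, np.nan, np.nan, np.nan, rss=np.nan, converged=False)

    h0, hmax, tm, dte = sol.x
    rss = float(2 * sol.cost)
    degenerate = (
        not sol.success
        or hmax - h0 < 1e-6
        or tm <= 1e-6
        or dte <= 1e-5
        or not np.isfinite(sol.x).all()
    )
    return GrowthParams(
        h0=float(h0),
        hmax=float(max(hmax, h0 + 1e-9)),
        tm=float(tm),
        te=float(tm + dte),
        rss=rss,
        converged=not degenerate,
    )


@dataclass(frozen=True)
class GrowthSummary:
    max_rate: float  # cm per GDD, at tm
    tm_das: float
    te_das: float


def _gdd_to_doy(gdd: float, temps: TemperatureSeries) -> float:
    """Invert the cumulative GDD sum with linear interpolation within days."""
    cum = temps.cumulative_gdd()
    if gdd > cum[-1] or gdd < 0:
        raise ValueError("GDD value outside the temperature-series span")
    i = int(np.searchsorted(cum, gdd))
    if i == 0:
        prev = 0.0
    else:
        prev = cum[i - 1]
    day_gain = cum[i] - prev
    frac = 0.0 if day_gain <= 0 else (gdd - prev) / day_gain
    return float(temps.days[i] - 1 + frac)


def growth_summary(
    params: GrowthParams, temps: TemperatureSeries, sowing_doy: int
) -> GrowthSummary:
    """Derive (max shoot growth rate, tm in DAS, te in DAS) from a fit.

    tm and te are converted from GDD back to day-of-year by inverting the
    cumulative GDD sum (linear interpolation within days), then to days
    after sowing.  Day indices past 365 represent the year rollover.
    """
    params.validate()
    rate = beta_sigmoid_rate(params.tm, params)
    tm_doy = _gdd_to_doy(params.tm, temps)
    te_doy = _gdd_to_doy(params.te, temps)
    return GrowthSummary(
        max_rate=float(rate),
        tm_das=tm_doy - sowing_doy,
        te_das=te_doy - sowing_doy,
    )
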