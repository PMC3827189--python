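"""Growth-rate histories from dated slices, period summaries and ANOVA.

A stem's dated slices give radius-versus-time points (mean calendar year,
distance from pith).  A cubic spline through those points, differentiated
at each slice date and scaled by 2*pi (the stem treated as circular),
gives the circumference increment rate in mm/yr.  Rate uncertainty is a
curve-level refit: all slice ages shifted jointly to their upper, then
lower, 68.2% limits; the reported uncertainty is the larger deviation of
the refit gradient from the mean-age gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline, PchipInterpolator

from .climate import RegressionResult, ols

__all__ = [
    "GrowthEstimate",
    "PeriodSummary",
    "fit_growth_curve",
    "growth_rates",
    "summarize_periods",
    "anova_periods",
    "density_growth_relation",
    "years_to_reach_circumference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthEstimate:
    stem_id: str
    distance_mm: float
    year: float  # mean calendar year of the slice
    rate: float  # circumference increment, mm/yr
    rate_uncertainty: float  # mm/yr


@dataclass(frozen=True)
class PeriodSummary:
    label: str
    start_year: int
    end_year: int  # inclusive
    mean_rate: float
    sd_rate: float  # sample (n-1) SD
    n: int


def fit_growth_curve(years, distances_mm, kind: str = "monotone"):
    """Cubic spline radius(t) through (year, distance) points.

    ``monotone`` (default) uses a shape-preserving cubic (PCHIP), which
    cannot produce negative radial growth; ``natural_cubic`` is a natural
    cubic spline.  Years must be strictly increasing with distance.
    """
    years = np.asarray(years, dtype=float)
    distances_mm = np.asarray(distances_mm, dtype=float)
    if len(years) < 3:
        raise ValueError("growth curve needs >= 3 dated points")
    if np.any(np.diff(years) < 0) or np.any(np.diff(distances_mm) < 0):
        raise ValueError("slice years must be non-decreasing with distance from pith")
    years = _strictly_increasing(years)
    if kind == "monotone":
        return PchipInterpolator(years, distances_mm)
    if kind == "natural_cubic":
        return CubicSpline(years, distances_mm, bc_type="natural")
    raise ValueError(f"unknown spline kind {kind!r}")


def _strictly_increasing(t: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Break exact ties by a forward nudge so spline abscissae are valid."""
    out = t.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def growth_rates(
    stem_id: str,
    years,
    sigmas,
    distances_mm,
    kind: str = "monotone",
    joint_shift: bool = True,
) -> list[GrowthEstimate]:
    """Per-slice circumference growth rates with refit uncertainty.

    ``years``/``sigmas``/``distances_mm`` cover every slice including the
    undated outermost one (entered at the collection date with sigma 0).
    rate_i = 2*pi * d(distance)/dt at year_i.  With ``joint_shift`` the
    uncertainty shifts every age to its upper (then lower) limit at once;
    otherwise each slice is perturbed alone and the largest deviation of
    its own rate is kept.
    """
    years = np.asarray(years, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    distances_mm = np.asarray(distances_mm, dtype=float)

    def rates_for(shifted_years: np.ndarray) -> np.ndarray:
        t = _strictly_increasing(np.maximum.accumulate(shifted_years))
        spl = fit_growth_curve(t, distances_mm, kind=kind)
        r = 2.0 * np.pi * spl.derivative()(t)
        if kind == "natural_cubic" and np.any(r < 0):
            log.warning("stem %s: negative gradient under natural cubic; refit monotone", stem_id)
            spl = fit_growth_curve(t, distances_mm, kind="monotone")
            r = 2.0 * np.pi * spl.derivative()(t)
        return r

    base = rates_for(years)
    if joint_shift:
        up = rates_for(years + sigmas)
        lo = rates_for(years - sigmas)
        unc = np.maximum(np.abs(up - base), np.abs(lo - base))
    else:
        unc = np.zeros_like(base)
        for i in range(len(years)):
            for sign in (+1, -1):
                shifted = years.copy()
                shifted[i] += sign * sigmas[i]
                unc[i] = max(unc[i], abs(rates_for(shifted)[i] - base[i]))
    return [
        GrowthEstimate(stem_id, float(d), float(y), float(r), float(u))
        for d, y, r, u in zip(distances_mm, years, base, unc)
    ]


def summarize_periods(estimates, periods) -> tuple[list[PeriodSummary], PeriodSummary]:
    """Mean, sample SD and count of growth rates in each calendar period.

    ``periods`` is a list of (label, start_year, end_year) with inclusive
    bounds; membership uses the integer reported year.  Estimates falling
    in no period are excluded with a log entry.  Also returns an overall
    summary over the union of the periods.
    """
    out = []
    in_any = []
    for label, start, end in periods:
        vals = [e.rate for e in estimates if start <= int(round(e.year)) <= end]
        arr = np.array(vals)
        out.append(
            PeriodSummary(
                label,
                int(start),
                int(end),
                float(arr.mean()) if len(arr) else np.nan,
                float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
                len(arr),
            )
        )
    lo = min(p[1] for p in periods)
    hi = max(p[2] for p in periods)
    for e in estimates:
        if any(start <= int(round(e.year)) <= end for _, start, end in periods):
            in_any.append(e.rate)
        else:
            log.info("estimate %s@%gmm (year %d) falls in no period; excluded",
                     e.stem_id, e.distance_mm, int(round(e.year)))
    arr = np.array(in_any)
    overall = PeriodSummary(
        f"{lo}-{hi}", lo, hi, float(arr.mean()), float(arr.std(ddof=1)), len(arr)
    )
    return out, overall


def anova_periods(estimates, periods) -> tuple[float, float]:
    """One-way ANOVA (F, p) of growth rates across calendar periods."""
    groups = []
    for _, start, end in periods:
        vals = [e.rate for e in estimates if start <= int(round(e.year)) <= end]
        if len(vals) < 2:
            raise ValueError(f"period {start}-{end} has < 2 growth estimates")
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 periods")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def density_growth_relation(rates, densities) -> RegressionResult:
    """OLS of growth rate on wood density at the dated slices."""
    return ols(densities, rates)


def years_to_reach_circumference(circumference_mm: float, rate_mm_yr: float) -> float:
    """Time to grow to a given stem circumference at a constant rate."""
    if rate_mm_yr <= 0:
        raise ValueError("rate must be positive")
    return circumference_mm / rate_mm_yr
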