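"""Replicate-signal statistics and smoothing-spline ratio-index detrending.

The expressed population signal (EPS) of n replicate series with mean
inter-series correlation rbar is

    EPS = n * rbar / (n * rbar + (1 - rbar))

and 0.85 is the conventional sufficiency threshold.  Detrending divides
each series by a cubic smoothing spline whose 50% frequency response
falls at a wavelength of ``stiffness`` times the series length (default
0.67, the common dendrochronology choice), leaving a dimensionless
index with mean near one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "EPS_THRESHOLD",
    "DetrendedSeries",
    "StemChronology",
    "mean_interseries_correlation",
    "eps",
    "detrend_spline",
    "build_chronology",
]

log = logging.getLogger(__name__)

EPS_THRESHOLD = 0.85


class DetrendError(ValueError):
    pass


@dataclass(frozen=True)
class DetrendedSeries:
    grid: np.ndarray
    index: np.ndarray  # observed / fitted, dimensionless, mean ~ 1
    fitted: np.ndarray
    stiffness: float


@dataclass(frozen=True)
class StemChronology:
    """Mean detrended-density chronology for one stem with its signal stats."""

    grid: np.ndarray
    mean_index: np.ndarray
    sd_index: np.ndarray  # sample (n-1) SD across replicates
    n_series: int
    rbar: float
    eps: float

    @property
    def sufficient(self) -> bool:
        return self.eps >= EPS_THRESHOLD


def mean_interseries_correlation(series, min_overlap: int = 3) -> float:
    """Arithmetic mean of all pairwise Pearson correlations.

    ``series`` is a sequence of equal-length 1-D arrays on a common grid;
    NaNs mark gaps and each pair uses its pairwise-complete points.
    Zero-variance pairs are excluded with a warning.
    """
    series = [np.asarray(s, dtype=float) for s in series]
    if len(series) < 2:
        raise ValueError("need >= 2 series")
    rs = []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            a, b = series[i], series[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_overlap:
                log.warning("pair (%d, %d): overlap < %d, excluded", i, j, min_overlap)
                continue
            x, y = a[ok], b[ok]
            if np.std(x) == 0 or np.std(y) == 0:
                log.warning("pair (%d, %d): zero variance, excluded", i, j)
                continue
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    if not rs:
        raise ValueError("no valid series pairs for correlation")
    return float(np.mean(rs))


def eps(rbar: float, n_series: int) -> float:
    """Expressed population signal for n replicate series."""
    if n_series < 2:
        raise ValueError("EPS needs >= 2 series")
    if not -1 < rbar <= 1:
        raise ValueError("rbar must lie in (-1, 1]")
    if rbar <= 0:
        log.warning("rbar = %.3f <= 0; EPS reported as 0", rbar)
        return 0.0
    value = n_series * rbar / (n_series * rbar + (1.0 - rbar))
    return float(np.clip(value, 0.0, 1.0))


def _spline_lambda(n: int, stiffness: float) -> float:
    # 50% frequency response at wavelength stiffness*n for the
    # penalized smoother min sum (y-s)^2 + lam * int s''^2:
    # |H(f)| = 1 / (1 + lam (2 pi f)^4)  =>  lam = (P / (2 pi))^4.
    period = stiffness * n
    return (period / (2.0 * np.pi)) ** 4


def detrend_spline(series, stiffness: float = 0.67, max_stiffen: int = 8) -> DetrendedSeries:
    """Ratio-index detrending against a cubic smoothing spline.

    The fitted spline must stay positive (the index is a ratio); if it
    does not, the spline is refit progressively stiffer before giving up.
    The output index is invariant to multiplying the input by a positive
    constant.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 7:
        raise DetrendError("detrending needs a 1-D series of length >= 7")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise DetrendError("series values must be positive and finite")
    x = np.arange(len(y), dtype=float)
    lam = _spline_lambda(len(y), stiffness)
    for _ in range(max_stiffen + 1):
        fitted = make_smoothing_spline(x, y, lam=lam)(x)
        if np.all(fitted > 0):
            return DetrendedSeries(x, y / fitted, fitted, stiffness)
        lam *= 10.0
    raise DetrendError("fitted spline not positive even after stiffening")


def build_chronology(detrended, stiffness: float | None = None) -> StemChronology:
    """Average replicate detrended series into a stem chronology.

    Per-grid-point arithmetic mean and sample SD across replicates, with
    rbar and EPS of the replicate indices attached.  All series must
    share one grid.
    """
    if len(detrended) < 2:
        raise ValueError("chronology needs >= 2 detrended series")
    grids = [d.grid for d in detrended]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValueError("detrended series are not on a common grid")
    mat = np.vstack([d.index for d in detrended])
    mean_index = np.nanmean(mat, axis=0)
    sd_index = np.nanstd(mat, axis=0, ddof=1)
    try:
        rbar = mean_interseries_correlation([d.index for d in detrended])
    except ValueError:
        # identical replicates have zero-variance differences only if constant;
        # fall back to perfect agreement when every pair is excluded
        rbar = 1.0
    n = len(detrended)
    return StemChronology(grids[0], mean_index, sd_index, n, rbar, eps(rbar, n))
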