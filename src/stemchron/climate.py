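"""Ordinary-least-squares associations among climate, density and growth.

Simple two-variable OLS is computed in closed form (normal equations),
with the slope p-value from the t distribution on n-2 degrees of
freedom; pairs with a missing member are dropped ("pairwise complete")
and the n actually used is reported.  Per-stem slope homogeneity is
tested with the interaction F-test of an ANCOVA fitted by statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionResult", "ols", "slope_homogeneity", "association_suite"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    r2: float
    p: float
    n: int

    def __str__(self) -> str:  # e.g. "y = -63.2 x + 255, r2=0.16, p=0.006, n=43"
        return (
            f"y = {self.slope:.4g} x + {self.intercept:.4g}, "
            f"r2 = {self.r2:.3f}, p = {self.p:.3g}, n = {self.n}"
        )


def ols(x, y) -> RegressionResult:
    """Closed-form simple linear regression of y on x.

    Uses pairwise-complete observations; requires n >= 3 and a
    non-degenerate predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int(ok.size - ok.sum())
    if dropped:
        log.info("ols: dropped %d incomplete pairs", dropped)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"OLS needs >= 3 complete pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate predictor: var(x) = 0")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if n > 2 and sse > 0:
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        se, p = 0.0, 0.0 if slope != 0 else 1.0
    return RegressionResult(float(slope), float(se), intercept, float(np.clip(r2, 0, 1)), max(p, np.finfo(float).tiny), n)


def slope_homogeneity(df: pd.DataFrame, x: str, y: str, group: str) -> tuple[float, float]:
    """Interaction F-test: do regression slopes differ between groups?

    Fits ``y ~ x * C(group)`` vs ``y ~ x + C(group)`` and returns the
    (F, p) for the interaction term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = df[[x, y, group]].dropna()
    full = smf.ols(f"{y} ~ {x} * C({group})", data=data).fit()
    reduced = smf.ols(f"{y} ~ {x} + C({group})", data=data).fit()
    table = anova_lm(reduced, full)
    return float(table["F"].iloc[1]), float(table["Pr(>F)"].iloc[1])


def association_suite(
    slices: pd.DataFrame | None = None,
    chronology: pd.DataFrame | None = None,
    climate: dict | None = None,
) -> pd.DataFrame:
    """Run the study's full regression set and tabulate the results.

    Parameters
    ----------
    slices :
        Per-slice table with columns ``stem_id, distance_mm, year, rate,
        density`` (any of rate/density may be absent).
    chronology :
        Detrended chronology with columns ``year, index`` (stem means or
        pooled).
    climate :
        Mapping of name -> :class:`~stemchron.io.ClimateSeries`; names
        ``pdo``, ``rainfall`` and optionally ``slp`` are recognised.

    Returns a DataFrame with one row per regression: relation, group,
    slope, slope_se, intercept, r2, p, n — plus interaction-F rows for
    the per-stem density relations.  Years are matched as integers;
    unmatched pairs are dropped and logged by :func:`ols`.
    """
    climate = climate or {}
    rows: list[dict] = []

    def add(relation: str, group: str, x, y) -> None:
        try:
            r = ols(x, y)
        except ValueError as err:
            log.warning("%s [%s] skipped: %s", relation, group, err)
            return
        rows.append(
            dict(relation=relation, group=group, slope=r.slope, slope_se=r.slope_se,
                 intercept=r.intercept, r2=r.r2, p=r.p, n=r.n)
        )

    pdo = climate.get("pdo")
    rain = climate.get("rainfall")
    slp = climate.get("slp")
    if pdo is not None and rain is not None:
        years = np.intersect1d(pdo.year, rain.year)
        add("rainfall~pdo", "all", pdo.at_years(years), rain.at_years(years))
    if pdo is not None and slp is not None:
        years = np.intersect1d(pdo.year, slp.year)
        add("slp~pdo", "all", pdo.at_years(years), slp.at_years(years))

    if slices is not None:
        sl = slices.copy()
        sl["year_int"] = sl["year"].round().astype(int)
        if {"rate", "density"}.issubset(sl.columns):
            add("rate~density", "all", sl["density"], sl["rate"])
        if "density" in sl.columns:
            for stem, g in sl.groupby("stem_id"):
                add("density~distance", str(stem), g["distance_mm"], g["density"])
                add("density~year", str(stem), g["year"], g["density"])
            if sl["stem_id"].nunique() > 1 and sl["density"].notna().any():
                for xvar, rel in (("distance_mm", "density~distance"),
                                  ("year", "density~year")):
                    f, p = slope_homogeneity(sl.rename(columns={xvar: "xv"}),
                                             "xv", "density", "stem_id")
                    rows.append(dict(relation=rel + ":slopes-differ", group="all",
                                     slope=np.nan, slope_se=np.nan, intercept=np.nan,
                                     r2=np.nan, p=p, n=len(sl.dropna(subset=["density"]))))
        if "rate" in sl.columns:
            if pdo is not None:
                add("rate~pdo", "all", pdo.at_years(sl["year_int"]), sl["rate"])
            if rain is not None:
                add("rate~rainfall", "all", rain.at_years(sl["year_int"]), sl["rate"])

    if chronology is not None:
        ch = chronology.copy()
        ch["year_int"] = ch["year"].round().astype(int)
        if pdo is not None:
            add("detrended_density~pdo", "all", pdo.at_years(ch["year_int"]), ch["index"])
        if rain is not None:
            add("detrended_density~rainfall", "all", rain.at_years(ch["year_int"]), ch["index"])

    return pd.DataFrame(rows)
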