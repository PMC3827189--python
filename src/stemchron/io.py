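"""Readers, writers and radiocarbon reporting conventions.

All calendar time is decimal years AD (e.g. October 2008 -> 2008.79).
All radiocarbon activities are carried internally as percent Modern
Carbon (pMC); fraction modern F14C = pMC / 100, and a conventional
radiocarbon age relates to F14C through the Libby mean life:
``age = -8033 * ln(F14C)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalCurve",
    "C14Measurement",
    "ClimateSeries",
    "LIBBY_MEAN_LIFE",
    "convert_age_to_pmc",
    "convert_pmc_to_age",
    "read_curve",
    "read_measurements",
    "read_profiles",
    "read_climate",
    "write_tucson",
    "read_tucson",
]

log = logging.getLogger(__name__)

#: Libby mean life of 14C in years, the constant behind conventional ages.
LIBBY_MEAN_LIFE = 8033.0


class FormatError(ValueError):
    """Raised when an input file violates its declared schema."""


@dataclass(frozen=True)
class CalCurve:
    """Atmospheric calibration curve on a strictly increasing year grid.

    Attributes
    ----------
    year : ndarray
        Decimal calendar years AD, strictly increasing.
    pmc : ndarray
        Curve mean in percent Modern Carbon.
    sigma_pmc : ndarray
        1-sigma curve uncertainty in pMC.
    """

    year: np.ndarray
    pmc: np.ndarray
    sigma_pmc: np.ndarray

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=float)
        pmc = np.asarray(self.pmc, dtype=float)
        sig = np.asarray(self.sigma_pmc, dtype=float)
        if year.ndim != 1 or len(year) < 2:
            raise FormatError("calibration curve needs >= 2 grid points")
        if not np.all(np.diff(year) > 0):
            raise FormatError("calibration curve years must be strictly increasing")
        if np.any(pmc <= 0):
            raise FormatError("curve pMC values must be positive")
        if np.any(sig < 0):
            raise FormatError("curve sigma must be non-negative")
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "pmc", pmc)
        object.__setattr__(self, "sigma_pmc", sig)

    def interp(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (mean, sigma) at decimal years ``t``."""
        t = np.asarray(t, dtype=float)
        return (
            np.interp(t, self.year, self.pmc),
            np.interp(t, self.year, self.sigma_pmc),
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.year[0]), float(self.year[-1])


@dataclass(frozen=True)
class C14Measurement:
    """One AMS measurement on a wood slice at a known radial position."""

    stem_id: str
    distance_mm: float
    pmc: float
    sigma_pmc: float

    def __post_init__(self) -> None:
        if self.pmc <= 0:
            raise FormatError(f"pMC must be positive, got {self.pmc}")
        if self.sigma_pmc <= 0:
            raise FormatError(f"sigma_pmc must be positive, got {self.sigma_pmc}")


@dataclass
class ClimateSeries:
    """Annual climate series with explicit missing values (NaN), never dropped."""

    name: str
    year: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if len(np.unique(self.year)) != len(self.year):
            raise FormatError(f"duplicate years in climate series {self.name!r}")

    def at_years(self, years) -> np.ndarray:
        """Values matched by integer year; NaN where the year is absent."""
        years = np.asarray(years, dtype=int)
        lookup = dict(zip(self.year.tolist(), self.value.tolist()))
        return np.array([lookup.get(int(y), np.nan) for y in years])


# ---------------------------------------------------------------------------
# radiocarbon reporting conventions


def convert_age_to_pmc(c14_age_bp):
    """Convert a conventional radiocarbon age (yr BP) to percent Modern Carbon."""
    return 100.0 * np.exp(-np.asarray(c14_age_bp, dtype=float) / LIBBY_MEAN_LIFE)


def convert_pmc_to_age(pmc):
    """Inverse of :func:`convert_age_to_pmc`; round-trips to machine precision."""
    return -LIBBY_MEAN_LIFE * np.log(np.asarray(pmc, dtype=float) / 100.0)


# ---------------------------------------------------------------------------
# file readers

_CURVE_DIALECTS = ("pmc_csv", "f14c_csv", "intcal_14c_age")


def read_curve(path, dialect: str = "pmc_csv") -> CalCurve:
    """Read a calibration curve.

    Dialects
    --------
    ``pmc_csv``
        Columns ``year_ad, pmc, sigma_pmc``.
    ``f14c_csv``
        Columns ``year_ad, f14c, sigma_f14c``; multiplied by 100.
    ``intcal_14c_age``
        IntCal-style 5-column file (cal BP, 14C age BP, sigma, ...),
        comma or whitespace separated, ``#`` comments.  Converted via
        ``year_AD = 1950 - calBP`` and the F14C transform; the age sigma
        is propagated as ``sigma_pmc = pmc * sigma_age / 8033``.
    """
    if dialect not in _CURVE_DIALECTS:
        raise ValueError(f"unknown curve dialect {dialect!r}; choose from {_CURVE_DIALECTS}")
    path = Path(path)
    if dialect == "intcal_14c_age":
        df = pd.read_csv(path, comment="#", sep=r"[,\s]+", engine="python", header=None)
        cal_bp = df.iloc[:, 0].to_numpy(float)
        age = df.iloc[:, 1].to_numpy(float)
        sigma_age = df.iloc[:, 2].to_numpy(float)
        if np.any(sigma_age < 0):
            raise FormatError("negative sigma in curve file")
        year = 1950.0 - cal_bp
        pmc = convert_age_to_pmc(age)
        sigma_pmc = pmc * sigma_age / LIBBY_MEAN_LIFE
    else:
        df = pd.read_csv(path, comment="#", header=None if _headerless(path) else 0)
        arr = df.to_numpy(float)
        year, val, sig = arr[:, 0], arr[:, 1], arr[:, 2]
        if np.any(sig < 0):
            raise FormatError("negative sigma in curve file")
        scale = 100.0 if dialect == "f14c_csv" else 1.0
        pmc, sigma_pmc = val * scale, sig * scale
    order = np.argsort(year)
    year, pmc, sigma_pmc = year[order], pmc[order], sigma_pmc[order]
    if np.any(np.diff(year) <= 0):
        raise FormatError("curve grid is not strictly monotonic")
    if len(year) == 1:  # pragma: no cover - guarded by CalCurve anyway
        raise FormatError("curve needs >= 2 points")
    return CalCurve(year, pmc, sigma_pmc)


def _headerless(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                first = line.split(",")[0]
                try:
                    float(first)
                    return True
                except ValueError:
                    return False
    return True


def read_measurements(path) -> list[C14Measurement]:
    """Read slice measurements (``stem_id, distance_mm, pmc, sigma_pmc``).

    Rows come back grouped by stem and sorted by increasing distance from
    the pith, which is the order the sequence calibration requires.
    """
    df = pd.read_csv(path, dtype={"stem_id": str})
    if df.empty:
        log.warning("measurement file %s is empty", path)
        return []
    required = {"stem_id", "distance_mm", "pmc", "sigma_pmc"}
    if not required.issubset(df.columns):
        raise FormatError(f"measurement file must have columns {sorted(required)}")
    if df.duplicated(subset=["stem_id", "distance_mm"]).any():
        raise FormatError("duplicate (stem_id, distance_mm) in measurement file")
    df = df.sort_values(["stem_id", "distance_mm"], kind="stable")
    return [
        C14Measurement(str(r.stem_id), float(r.distance_mm), float(r.pmc), float(r.sigma_pmc))
        for r in df.itertuples()
    ]


def read_profiles(path) -> pd.DataFrame:
    """Read grey-value profiles (``stem_id, profile_id, position_mm, grey``)."""
    df = pd.read_csv(path, dtype={"stem_id": str})
    required = {"stem_id", "profile_id", "position_mm", "grey"}
    if not required.issubset(df.columns):
        raise FormatError(f"profile file must have columns {sorted(required)}")
    return df.sort_values(["stem_id", "profile_id", "position_mm"], kind="stable")


def read_climate(path, name: str | None = None) -> ClimateSeries:
    """Read an annual climate series (``year, value``); blanks stay as NaN."""
    df = pd.read_csv(path)
    if not {"year", "value"}.issubset(df.columns):
        raise FormatError("climate file must have columns year,value")
    return ClimateSeries(name or Path(path).stem, df["year"].to_numpy(int), df["value"].to_numpy(float))


# ---------------------------------------------------------------------------
# Tucson (.rwl-style) export, for interoperability with ring-width archives

_TUCSON_STOP = -9999


def write_tucson(values, start_year: int, series_id: str, path, scale: int = 1000) -> None:
    """Write one annual series as decadal-line Tucson/rwl text.

    Values are multiplied by ``scale`` and rounded to integers; the scale
    is recorded in a header comment so the payload round-trips at the
    declared precision.  Only annual-resolution series are representable.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise FormatError("write_tucson needs a non-empty 1-D annual series")
    start_year = int(start_year)
    sid = f"{series_id:<8.8s}"
    lines = [f"# stemchron tucson export; scale={scale}"]
    ints = np.round(values * scale).astype(int).tolist() + [_TUCSON_STOP]
    year = start_year
    i = 0
    while i < len(ints):
        decade_end = (year // 10 + 1) * 10
        take = min(decade_end - year, len(ints) - i)
        chunk = ints[i : i + take]
        lines.append(sid + f"{year:6d}" + "".join(f"{v:6d}" for v in chunk))
        year += take
        i += take
    Path(path).write_text("\n".join(lines) + "\n")


def read_tucson(path):
    """Read a file written by :func:`write_tucson`. Returns (values, start_year, id)."""
    scale = 1000
    rows: list[tuple[int, list[int]]] = []
    sid = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "scale=" in line:
                scale = int(line.split("scale=")[1])
            continue
        sid = line[:8].strip()
        body = line[8:]
        year = int(body[:6])
        vals = [int(body[i : i + 6]) for i in range(6, len(body), 6)]
        rows.append((year, vals))
    flat: list[int] = []
    start = rows[0][0]
    for _, vals in rows:
        flat.extend(vals)
    if flat and flat[-1] == _TUCSON_STOP:
        flat = flat[:-1]
    return np.array(flat, dtype=float) / scale, start, sid
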