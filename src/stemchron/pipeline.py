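"""End-to-end orchestration: density -> chronology -> dates -> growth -> climate.

Every stage boundary is a plain CSV so any stage can be replaced by an
external tool's output, and a JSON manifest records the seed, the echoed
configuration and SHA-256 hashes of the inputs so a run can be audited
and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chronology import build_chronology, detrend_spline, eps, mean_interseries_correlation
from .densitometry import GreyProfile, bin_per_mm, calibrate_grey, density_at_positions
from .growth import anova_periods, growth_rates, summarize_periods
from .io import read_climate, read_curve, read_measurements, read_profiles
from .radiocarbon import calibrate_sequence, format_table_style
from .climate import association_suite
from .reference import PERIODS

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    curve_path: str | None = None
    curve_dialect: str = "pmc_csv"
    profiles_path: str | None = None
    measurements_path: str | None = None
    climate_paths: dict = field(default_factory=dict)  # name -> path
    fresh_density: float = 1.0  # g/cm3, per-stem reference for calibration
    calibration_form: str = "inverse"
    collection_year: float = 2008.79
    grid_step: float = 0.2
    stiffness: float = 0.67
    engine: str = "dp"
    seed: int = 0
    periods: list = field(default_factory=lambda: list(PERIODS))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every configured stage and write its outputs under ``out_dir``.

    Stages with missing inputs are skipped; the returned dict maps stage
    name to its output DataFrame (or summary object).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    inputs: dict[str, str] = {}

    profiles_df = None
    if config.profiles_path:
        inputs["profiles"] = _sha256(Path(config.profiles_path))
        profiles_df = read_profiles(config.profiles_path)
        dens_rows, chron_rows, eps_rows = [], [], []
        for stem, g in profiles_df.groupby("stem_id"):
            binned, raw_binned = [], []
            for _, gp in g.groupby("profile_id"):
                prof = GreyProfile(str(stem), int(gp["profile_id"].iloc[0]),
                                   gp["position_mm"].to_numpy(), gp["grey"].to_numpy())
                dens = calibrate_grey(prof, config.fresh_density, form=config.calibration_form)
                binned.append(bin_per_mm(dens))
            n = min(len(b.density) for b in binned)
            series = [b.density[:n] for b in binned]
            grid = binned[0].position_mm[:n]
            for b, s in zip(binned, series):
                for p, v in zip(grid, s):
                    dens_rows.append(dict(stem_id=stem, profile_id=b.profile_id,
                                          position_mm=p, density=v))
            detr = [detrend_spline(np.asarray(s), stiffness=config.stiffness) for s in series]
            chron = build_chronology(detr, stiffness=config.stiffness)
            raw_rbar = mean_interseries_correlation(series)
            eps_rows.append(dict(stem_id=stem, rbar_raw=raw_rbar,
                                 eps_raw=eps(raw_rbar, len(series)),
                                 rbar_detrended=chron.rbar, eps_detrended=chron.eps,
                                 n_series=chron.n_series))
            for p, m, s in zip(grid, chron.mean_index, chron.sd_index):
                chron_rows.append(dict(stem_id=stem, position_mm=p,
                                       mean_index=m, sd_index=s))
        results["density"] = pd.DataFrame(dens_rows)
        results["density"].to_csv(out / "density.csv", index=False)
        results["chronology"] = pd.DataFrame(chron_rows)
        results["chronology"].to_csv(out / "chronology.csv", index=False)
        results["eps"] = pd.DataFrame(eps_rows)
        results["eps"].to_csv(out / "eps.csv", index=False)

    dates_df = None
    if config.curve_path and config.measurements_path:
        inputs["curve"] = _sha256(Path(config.curve_path))
        inputs["measurements"] = _sha256(Path(config.measurements_path))
        curve = read_curve(config.curve_path, config.curve_dialect)
        measurements = read_measurements(config.measurements_path)
        rows = []
        by_stem: dict[str, list] = {}
        for m in measurements:
            by_stem.setdefault(m.stem_id, []).append(m)
        for stem, ms in by_stem.items():
            dates = calibrate_sequence(ms, curve, collection_year=config.collection_year,
                                       grid_step=config.grid_step, engine=config.engine,
                                       seed=config.seed)
            for d in dates:
                yr, sig = format_table_style(d)
                rows.append(dict(stem_id=stem, distance_mm=d.distance_mm,
                                 mean_year=d.mean_year, sigma_year=d.sigma_year,
                                 year=yr, sigma=sig,
                                 hpd68=";".join(f"{a:.1f}-{b:.1f}" for a, b in d.hpd68),
                                 engine=config.engine, seed=config.seed))
        dates_df = pd.DataFrame(rows)
        dates_df.to_csv(out / "dates.csv", index=False)
        results["dates"] = dates_df

    if dates_df is not None:
        rate_rows = []
        for stem, g in dates_df.groupby("stem_id"):
            g = g.sort_values("distance_mm")
            years = np.r_[g["mean_year"].to_numpy(), config.collection_year]
            sigmas = np.r_[g["sigma_year"].to_numpy(), 0.0]
            dist = np.r_[g["distance_mm"].to_numpy(), g["distance_mm"].max() + 2.0]
            for e in growth_rates(str(stem), years, sigmas, dist):
                rate_rows.append(dataclasses.asdict(e))
        rates_df = pd.DataFrame(rate_rows)
        rates_df.to_csv(out / "rates.csv", index=False)
        results["rates"] = rates_df
        per, overall = summarize_periods(
            [_Rec(**r) for r in rate_rows], config.periods
        )
        summary = pd.DataFrame([dataclasses.asdict(p) for p in per + [overall]])
        summary.to_csv(out / "summary.csv", index=False)
        results["summary"] = summary
        try:
            f, p = anova_periods([_Rec(**r) for r in rate_rows], config.periods)
            results["anova"] = {"F": f, "p": p}
        except ValueError as err:
            log.warning("period ANOVA skipped: %s", err)

    climate = {}
    for name, path in config.climate_paths.items():
        inputs[f"climate:{name}"] = _sha256(Path(path))
        climate[name] = read_climate(path, name)
    if climate and "rates" in results:
        slices = results["rates"].rename(columns={"stem_id": "stem_id"})
        assoc = association_suite(slices=slices.assign(density=np.nan), climate=climate)
        assoc.to_csv(out / "regressions.csv", index=False)
        results["regressions"] = assoc

    manifest = dict(
        package="stemchron", version=__version__, seed=config.seed,
        config={k: (v if not isinstance(v, list) else [list(t) for t in v])
                for k, v in dataclasses.asdict(config).items()},
        input_sha256=inputs,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


@dataclass(frozen=True)
class _Rec:
    stem_id: str
    distance_mm: float
    year: float
    rate: float
    rate_uncertainty: float
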