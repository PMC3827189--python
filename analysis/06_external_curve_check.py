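"""Optional check against real Southern Hemisphere calibration curves.

If the user supplies real curve files (SH bomb-era pMC data merged with
a pre-bomb SH curve, neither shipped here), this script sequence-
calibrates the published pMC measurements for the four Exmouth Gulf
stems and compares the modelled dates with the published ones.  Without
the exact curve compilation and smoothing the original analysis used,
agreement is expected within about one reported sigma for post-1952
slices, not bit-exactly.

Usage::

    python analysis/06_external_curve_check.py --curve sh_curve.csv \
        [--dialect pmc_csv|f14c_csv|intcal_14c_age]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from stemchron.io import C14Measurement, read_curve
from stemchron.radiocarbon import calibrate_sequence, format_table_style
from stemchron.reference import COLLECTION_DECIMAL_YEAR, slice_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--curve", type=Path, required=True,
                    help="calendar-year vs pMC calibration curve file")
    ap.add_argument("--dialect", default="pmc_csv",
                    choices=["pmc_csv", "f14c_csv", "intcal_14c_age"])
    args = ap.parse_args()
    if not args.curve.exists():
        sys.exit(f"curve file {args.curve} not found; supply a real SH curve")

    curve = read_curve(args.curve, args.dialect)
    df = slice_table().dropna(subset=["pmc"])
    rows = []
    for sid, g in df.groupby("stem_id"):
        ms = [C14Measurement(sid, float(r.distance_mm), float(r.pmc), float(r.sigma_pmc))
              for r in g.itertuples()]
        dates = calibrate_sequence(ms, curve, collection_year=COLLECTION_DECIMAL_YEAR)
        for d, r in zip(dates, g.itertuples()):
            yr, sig = format_table_style(d)
            ok = abs(yr - r.year) <= max(sig, r.sigma_year)
            rows.append(dict(stem_id=sid, distance_mm=r.distance_mm,
                             published=f"{r.year}±{r.sigma_year}",
                             modelled=f"{yr}±{sig}",
                             within_1sigma=ok, post_1952=r.year >= 1952))
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "results" / "external_curve_check.csv", index=False)
    post = out[out.post_1952]
    print(out.to_string(index=False))
    print(f"post-1952 slices within ±1 reported sigma: "
          f"{post.within_1sigma.sum()}/{len(post)}")


if __name__ == "__main__":
    main()
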