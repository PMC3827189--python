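"""Published reference dataset for the four Exmouth Gulf *A. marina* stems.

Thirty wood slices from four ~10 cm diameter stems collected in Giralia
Bay (Exmouth Gulf, Western Australia) in October 2008: distance from the
pith, AMS radiocarbon activity (pMC +- 1 sigma) where measured,
sequence-modelled calendar date (year AD +- 1 sigma at 68.2%), and the
spline-gradient circumference growth rate (mm/yr) with its refit
uncertainty.  The outermost slice of each stem was not measured for 14C
and carries the collection year with zero dating uncertainty.

These rows are inputs for the arithmetic reproductions (period
summaries, stem ages, ANOVA); they are not recomputed here.
"""

from __future__ import annotations

import io as _io

import pandas as pd

__all__ = ["slice_table", "PERIODS", "COLLECTION_YEAR", "COLLECTION_DECIMAL_YEAR"]

#: calendar periods used to group growth rates (inclusive bounds),
#: chosen around the major phase changes of the Pacific Decadal Oscillation
PERIODS = [("1952-1976", 1952, 1976), ("1977-1998", 1977, 1998), ("1999-2008", 1999, 2008)]

COLLECTION_YEAR = 2008
COLLECTION_DECIMAL_YEAR = 2008.79  # October 2008

_TABLE = """\
stem_id,distance_mm,pmc,sigma_pmc,year,sigma_year,rate,sigma_rate
1,1,117.20,0.36,1960,1,7.18,0.66
1,8,141.12,0.39,1964,1,12.03,4.65
1,15,151.92,0.44,1970,1,8.47,2.57
1,22,139.72,0.40,1975,1,9.64,1.82
1,36,125.53,0.34,1982,1,5.65,2.26
1,43,113.36,0.33,1994,1,5.66,0.06
1,50,109.37,0.40,2000,2,5.71,0.94
1,57,,,2008,0,7.65,1.16
2,7,98.06,0.69,1936,17,3.42,0.76
2,13,101.36,0.31,1947,9,4.85,0.17
2,19,97.51,0.28,1951,6,6.69,0.89
2,25,104.05,0.54,1957,1,6.38,0.19
2,31,119.50,0.51,1961,1,3.49,1.12
2,37,133.48,0.53,1976,1,2.36,0.14
2,43,110.52,0.50,1999,2,1.83,0.45
2,47,,,2008,0,1.40,1.44
3,1,99.04,0.37,1919,23,1.79,4.82
3,11,98.24,0.40,1936,18,1.94,2.15
3,16,107.66,0.48,1958,1,2.13,3.62
3,21,145.32,0.46,1971,1,2.56,1.08
3,26,120.67,0.52,1985,1,3.11,1.51
3,36,112.02,0.47,1996,2,3.52,2.20
3,41,,,2008,0,3.62,2.51
4,1,99.67,0.32,1945,10,2.79,3.62
4,6,99.01,0.40,1952,2,2.80,0.99
4,11,133.72,0.43,1964,1,3.01,1.10
4,16,143.48,0.59,1972,1,3.66,1.66
4,21,127.98,0.46,1980,1,4.66,1.07
4,41,115.22,0.36,1991,2,5.38,1.72
4,51,,,2008,0,4.31,0.10
"""


def slice_table() -> pd.DataFrame:
    """The reference slice table as a DataFrame (stem_id as string)."""
    return pd.read_csv(_io.StringIO(_TABLE), dtype={"stem_id": str})
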