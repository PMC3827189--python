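# stemchron

Stem chronologies for trees without reliable annual rings — built around
the mangrove *Avicennia marina* in the arid Exmouth Gulf (Western
Australia), where ring counting fails and recent wood must be dated with
the atmospheric bomb pulse of radiocarbon.

The package implements the full analysis chain for a set of ~10 cm
diameter stems collected in October 2008:

1. **Densitometry** — CT grey-value profiles (0–256, ~22 samples/mm) are
   calibrated to fresh wood density via `A = k / B` with
   `k = mean(B) · ρ̄`, where `ρ̄` is the measured mean fresh density of
   the block, then averaged per mm of radius and over 1-mm windows at
   dated slice positions.
2. **Replicate signal and detrending** — four replicate profiles per stem
   are scored with the expressed population signal,
   `EPS = n·r̄ / (n·r̄ + (1 − r̄))` (≥ 0.85 is the conventional
   sufficiency threshold), and detrended by the ratio index to a cubic
   smoothing spline with 50% frequency response at 0.67 × series length.
3. **Bomb-pulse sequence dating** — each slice's activity `pMC ± σ`
   yields a Gaussian likelihood against a calibration curve
   `μ(t) ± σ_curve(t)`; a stem's slices are jointly calibrated under the
   chronological-ordering ("simple sequence") prior
   `t₁ ≤ t₂ ≤ … ≤ tₙ ≤ t_collection`, with exact grid marginals from a
   forward–backward prefix-sum dynamic program (a Gibbs sampler is the
   cross-check engine).
4. **Growth rates** — a shape-preserving cubic spline through
   (calendar year, distance from pith) is differentiated at each slice
   and scaled by 2π to give circumference increment rates (mm/yr);
   uncertainty comes from refitting with all ages at their 68.2% limits.
   Rates are grouped into the PDO-phase periods 1952–1976 / 1977–1998 /
   1999–2008 and compared by one-way ANOVA.
5. **Climate associations** — closed-form OLS regressions among rainfall,
   the Pacific Decadal Oscillation index, wood density, detrended
   density and growth rate, with per-stem slope homogeneity tested by an
   interaction F-test.

A synthetic-data module generates stems with known formation-year
fields, a bomb-pulse-shaped curve, replicate density profiles and an
AR(1) PDO with linearly coupled rainfall, so every stage can be tested
against ground truth without downloading any data.

## Worked example

```sh
python analysis/01_simulate_stems.py --seed 0   # synthetic stems + curve + climate
python analysis/02_calibrate_ages.py            # sequence-calibrate the slices
python analysis/03_growth_periods.py            # published growth-rate arithmetic
```

The calibration step prints (seed 0):

```
24 slices calibrated; 100% of true years within 2 sigma
median dating sigma: 15.9 yr pre-1952 (n=4) vs 0.6 yr post-1955 (n=20) - the bomb pulse at work
```

— the flat pre-bomb curve spreads a ±0.4 pMC measurement over decades
while the steep bomb limbs pin it to well under a year, which is exactly
why bomb-pulse dating makes ring-less mangroves datable. The period
summary prints:

```
1952-1976: 5.31±3.34 mm/yr (n=12)   [published 5.30±3.33 (12)]
1977-1998: 4.66±1.11 mm/yr (n=6)   [published 4.66±1.11 (6)]
1999-2008: 4.09±2.36 mm/yr (n=6)   [published 4.08±2.36 (6)]
overall: 4.84±2.66 mm/yr (n=24)   [published 4.84±2.66 (24)]
period ANOVA: F=0.42, p=0.66 -> periods not significantly different
stem 1: 48±1 yr old
...
cross-stem age range: 47 - 112 yr
a 650 mm circumference stem: ~160 yr at 4.08 mm/yr, ~120 yr at 5.30 mm/yr
```

recovering the published period table (to the last printed digit, which
the published source rates round), the stem ages, and the
circumference-extrapolation ages. `analysis/04_density_chronology.py`
and `analysis/05_climate_regressions.py` continue the chain through EPS,
detrending and the regression suite;
`analysis/06_external_curve_check.py` repeats the dating with a real
Southern Hemisphere calibration curve if the user supplies one.

A `stemchron` CLI exposes the same stages (`simulate`, `density`,
`chronology`, `calibrate`, `growth`, `associate`, `run-all`).

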