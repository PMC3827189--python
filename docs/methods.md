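# Methods

## The measurement model

A wood slice cut at distance `d` from the pith formed in some calendar
year `t(d)`; cellulose laid down in that year carries the atmospheric
¹⁴C activity of that year. Activities are carried as percent Modern
Carbon (pMC = 100 · F14C); a conventional radiocarbon age relates to
F14C by `age = −8033 · ln(F14C)` (Libby mean life), and all file
dialects are converted to pMC on read. Calendar time is decimal years AD
(October 2008 → 2008.79) because the bomb-era curve has sub-annual
structure.

Against a calibration curve `μ(t) ± σ_curve(t)` the likelihood of a
measured `m ± σ` is Gaussian with the curve and measurement variances
added in quadrature, evaluated on a regular calendar grid (default
Δt = 0.2 yr) with linear interpolation of the curve. The prior is
uniform on the grid.

## Sequence calibration

Slices of one stem are ordered: inner wood formed no later than outer
wood, and everything predates the collection date. The joint posterior

    p(t₁…tₙ) ∝ ∏ᵢ Lᵢ(tᵢ) · 1[t₁ ≤ … ≤ tₙ ≤ t_collection]

is a "simple sequence" deposition model — ordering only, no
deposition-rate prior. Ordering is non-strict because two slices can
form within one grid cell. Exact marginals are computed by a
forward–backward prefix-sum dynamic program: with `F₀ ≡ 1`,
`Fᵢ(t) = Lᵢ(t) · Σ_{s≤t} Fᵢ₋₁(s)`, a mirrored backward pass, and
`marginalᵢ(t) ∝ Lᵢ(t) · cumsum(Fᵢ₋₁)(t) · revcumsum(Bᵢ₊₁)(t)`. Each
pass is renormalized, so the computation is stable for any sequence
length; the collection date is enforced by truncating the grid. The
marginals agree with brute-force enumeration of the ordered joint to
10⁻⁹ total variation (tested for n ≤ 3 on grids up to 60 points). An
independent Metropolis-within-Gibbs sampler over the same discrete grid
(each tᵢ resampled exactly from its conditional between its neighbours)
serves as a cross-check engine, never as the default.

Posterior summaries are the mean, SD and the 68.2% highest-density
region, accumulated over grid points in descending density until the
target mass is reached. On coarse grids this greedy rule overshoots
68.2% by up to one point's mass, and a reported interval ends on grid
points; validation therefore scores HPD coverage with half-bin edges and
a 0.1-yr grid. Table-style output rounds the mean to an integer year and
reports σ as max(1, round(σ)).

## Densitometry

Transmission CT maps denser (saturated) wood to lower grey values, so
the calibration is inverse: `density = k / grey` with
`k = mean(grey) · ρ̄`, anchoring the profile so that the mean grey value
maps to the measured fresh (green) wood density ρ̄ of the block. The
result is invariant to rescaling the grey values; by Jensen's
inequality the mean calibrated density slightly exceeds ρ̄ unless the
profile is constant (the calibration anchors at the mean grey, not the
mean density). A `direct` proportional form is available for sensitivity
analysis. ρ̄ is treated as an opaque reference scalar — whether it is
dry-mass/green-volume or green-mass/green-volume does not affect any
downstream statistic, which are all ratios or regressions.

Per-mm averaging uses half-open [i, i+1) bins reported at i+0.5; slice
densities are 1-mm window means matching the physical slice thickness.

## Replicate signal and detrending

The mean inter-series Pearson correlation r̄ over pairwise-complete
points feeds `EPS = n·r̄/(n·r̄ + (1−r̄))`; 0.85 is the conventional
sufficiency threshold. Detrending divides each series by a cubic
smoothing spline whose 50% frequency response falls at a wavelength of
0.67 × series length — the common dendrochronology default; the
penalized-smoother parameter is `λ = (P/2π)⁴` for cutoff wavelength P.
The fitted spline must stay positive (the index is a ratio); if not, it
is refit an order of magnitude stiffer. Replicates are detrended first
and then averaged into the stem chronology (the alternative — average
then detrend — differs only at the noise level of four replicates and
is not implemented). Note that per-mm binning averages ~22 raw samples,
so r̄ computed on binned series runs higher than on raw-resolution
profiles; the generator's correlation target applies at raw resolution.

## Growth rates

Dated slices give (mean year, distance) knots, plus the undated
outermost slice pinned at the collection date with zero age uncertainty.
The default spline is shape-preserving (PCHIP) so radial growth is never
negative; a natural cubic option exists and falls back to monotone with
a warning if its gradient goes negative. Circumference rate is
`2π · d(distance)/dt` — the stem treated as circular, which is what
makes the published per-slice rates (≈ 2π × radial extent / age)
consistent. Rate uncertainty refits the spline with *all* ages moved to
their upper, then lower, 68.2% limits (a curve-level perturbation; a
per-slice mode is available behind a flag) and takes the larger
deviation. Period summaries use the integer reported year, inclusive
bounds, and sample (n−1) standard deviations — the convention that
reproduces the published period table from the published slice table.

## Synthetic data: what it emulates and what it does not

The generator defines the test conditions: four stems born 1920–1955,
logistic radius (asymptote 60 mm, rate 0.09/yr) collected October 2008;
density `1.0 − 0.0043·mm + (−0.02)·PDO(year(mm))` g/cm³ replicated ×4
with independent noise set from the target inter-profile correlation
(0.9); grey values generated by inverting the package's own calibration
so densitometry round-trips exactly; a bomb curve flat at 97.5 pMC
(±0.15 wiggle) before 1955, peaking at 152 pMC in 1965 and relaxing
toward 105 pMC (τ = 18 yr), spanning every published activity
(97.51–151.92 pMC); slice activities drawn with σ = 0.4 pMC, matching
the published 0.28–0.69 range; an AR(1) PDO (φ = 0.6, unit variance)
with rainfall `255 − 63.2·PDO` plus noise (SD 145 mm/yr) giving the
weak observed coupling (r² ≈ 0.16 over a 43-yr window). The radial
density slope is 10× shallower than the published per-mm regression
slopes, which as printed would drive density negative within ~25 mm;
the sign and the analysis are unaffected.

Not emulated: cyclone disturbance, heartwood formation, the real SH
curve's pre-bomb Suess wiggles (the synthetic pre-bomb curve is nearly
flat, so pre-bomb dating uncertainty lands at the wide end of the
published 6–23 yr range), and any spatial forest structure. Passing
recovery tests therefore demonstrate the statistical machinery, not the
ecology.

## Known limitations

- **Pre-bomb dating bias.** On the flat pre-bomb curve a slice's
  posterior is nearly uniform between the curve start and its first
  bomb-limb neighbour, so its posterior *mean* is biased early. Spline
  gradients at adjacent knots inherit the bias: in synthetic recovery
  the 1952–1976 period mean rate runs ~10–25% low, while post-1977
  periods recover within 15%. This is a property of mean-age spline
  dating itself, not of this implementation.
- **Common-mode climate aliasing.** All stems share one climate
  realization, so the climate-linked density component adds a common
  radial slope of up to ~15% of the aging trend in any one realization;
  recovery is therefore validated against each stem's *realized*
  generating slope, which it matches well within 2 SE.
- **Regression inference.** OLS p-values assume independent errors; the
  study's series are autocorrelated, and no correction is applied (the
  output table carries all p-values so users can adjust).
- **Validation scales.** Coverage experiments use 200 synthetic slices
  on a 0.1-yr grid and recovery experiments three seeded replicates of
  the four-stem design — the package's chosen validation sizes, giving
  binomial SEs of ~3 percentage points on coverage.
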