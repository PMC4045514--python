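# Methods

## Median-mapping scale calibration

A bone-age rating method assigns each radiograph a maturity measure *M*:
the Greulich-Pyle bone age (GP BA, years) or the Tanner-Whitehouse Sum
Maturity Score (SMS, a weighted stage total over the 13 RUS bones that
saturates at 1000 at full maturity).  To adapt a method to a reference
population, the measure is treated as an abstract maturity score and its
median is tabulated against chronological age on a grid of sampling ages:
*T*(ca) = median{*M* | CA ∈ bin(ca)}.  The adapted bone age of an observed
value *m* is *T*⁻¹(*m*), the age at which *m* is the population median.
By construction the adapted bone age of the median child equals their
chronological age, so the population's BA − CA curve is centred on zero.

Implementation choices, where the procedure itself leaves them open:

* **Median estimator** — the interpolated sample median (mean of the two
  middle order statistics for even n).
* **Binning** — each record is assigned to the *nearest* grid age
  (midpoint boundaries, ties upward) and must lie within ±½ bin width
  (default 1 y).  On a uniform 1-y grid this is exactly the
  anniversary-centred convention `[c − 0.5, c + 0.5)` used by the
  reference curves; on a non-uniform grid that includes the extra 2.5 and
  3.5 y sampling ages it keeps each sampling age's records in their own
  bin rather than letting them contaminate the neighbouring anniversary
  bins (an effect worth ~0.15 y in the medians near ages 2–4 with fixed
  1-y windows).  Grid ages with fewer than `n_min` records (default 10)
  are dropped with a warning; fewer than two survivors aborts the
  calibration.
* **Monotonization** — sample medians can wiggle; inversion requires
  monotonicity.  A least-squares isotonic (pool-adjacent-violators) fit is
  applied before inversion (scikit-learn's `IsotonicRegression`).
* **Inversion** — piecewise-linear interpolation on the tabulated
  (median, age) pairs.  Flat segments created by pooling invert to the
  midpoint of the tied age range (the symmetric choice).  Observed values
  outside the tabulated medians clamp to the first/last grid age and
  raise an `OutOfRangeWarning`; the scales carry explicit reliability
  limits, so silent extrapolation would be misleading.
* **Correction-table layout** — GP-BA grid from 2.0 y up to the top
  tabulated median in 0.5-y steps; `correction(g) = invert(g) − g`
  rounded to 0.1 y; the terminal row carries "and above" semantics (its
  correction applies unchanged beyond the grid).  Corrections are emitted
  unsmoothed: neighbouring rows may change non-smoothly, which is the
  honest image of the underlying medians.  Pre-rounding, the mapping
  `g + correction(g)` is exactly `invert(g)` and hence non-decreasing;
  rounding can perturb it by at most one rounding unit.
* **SMS anchor layout** — anchors are (grid age, monotonized median SMS),
  exact ties pooled to their midpoint age so anchors are strictly
  increasing in both coordinates.  The terminal anchor is placed at SMS
  1000 by linearly extrapolating the last segment below saturation —
  e.g. anchors (15.0, 835) and (16.0, 959) put the scale end at
  16.0 + 41/124 ≈ 16.33 y.

## Published scales

The package ships the 2005 urban Han Chinese adaptation digit-for-digit:
a GP correction table (grid 2.0–17.0 y, step 0.5, terminal row
"17.0 and above", corrections −1.2 y for both sexes) and per-sex SMS
anchor tables ending at 16.1 y (boys) / 15.1 y (girls).  Application
operations interpolate linearly between rows/anchors, reproduce the table
exactly at grid points, clamp below-range inputs with a warning, and
flag outputs beyond the automated method's reliability limits (GP BA 17 y
boys / 15 y girls, i.e. 15.8 / 13.8 y on the adapted scale) with a
`ReliabilityWarning` rather than an error — the limits mark increased
uncertainty, not invalidity.

## Reference curves

BA − CA is summarized per sex in 1-y bins centred on anniversaries:
per-bin mean, sample SD (n − 1), and count; bins under `n_min` are absent,
not zero-filled.  The ±2 SD band is derived output.  A single SD quoted
for an age range is the *unweighted* mean of the per-bin SDs over bins
whose centres fall in the closed interval.  Per-city curves use the same
binning; pooling them back with n-weights reproduces the overall mean
curve identically.

## Agreement analysis

Two ratings of the same image form a pair with mid = (a + b)/2 and
diff = a − b, automated minus manual (this sign convention makes a manual
rater who reads *older* produce a negative bias).  Over a stated
mid-range, bias = mean(diff) and rms = √mean(diff²) about zero with the n
denominator, so rms² = bias² + Var(diff) holds as an identity.  The
running-average curve is a boxcar mean (default window 1 y) on a 0.25-y
grid, omitting points with fewer than 5 pairs.

## Synthetic cohort generator

The generator emulates a cross-sectional survey at the study's design
points: sampling ages at anniversaries 2–20 y plus 2.5 and 3.5 y, with
Gaussian age jitter (SD 0.05 y) around each.  For each child,

    gp_ba = ca + offset_sex(ca) + city_shift + eps,   eps ~ N(0, sd)

with a piecewise-linear maturation offset rising from 0 in childhood to
+1 y at the end of puberty (knots at 9→16 y for boys, 8→15 y for girls),
five cities with additive shifts −0.3, −0.15, 0, +0.15, +0.3 y
(Shanghai most advanced, Dalian most delayed), and residual SD 1.1 y
(optionally age-dependent).  A latent TW-scale bone age with the same
offset structure but independent noise is pushed through the monotone
age → SMS map (default: the packaged anchors, making generator and scale
mutual inverses) to produce the SMS channel, and is recorded as the
automated TW3 rating; the manual rating subtracts a per-sex
automated-minus-manual bias (0.0 boys, −0.37 girls) and adds scatter
(0.64 / 0.57 y), giving rms differences of ≈ 0.64 / 0.68 y.  Default
sample size is 30 children per age, sex and city (≈ 6300 records), the
scale of the emulated survey; bone ages are floored at 0.1 y.  One seeded
`numpy` generator per call; identical seeds give identical cohorts.

What the generator does *not* model — and therefore what passing recovery
tests do not establish about real data: non-Gaussian tails and
social-class heterogeneity within cities, per-city age-range gaps,
age-dependent rater bias, secular trends, and any coupling between the GP
and TW channels beyond their shared offset.  Published cohort-dependent
statistics (range-averaged SDs, rater bias/rms, rating efficiency) depend
on the real radiographs and are *not* reproduced; instead the tests check
parameter recovery: calibrating on a cohort with a known injected offset
recovers every interior correction to within ±0.15 y at 1000
children/age (≈ 3 median standard errors, SE ≈ 1.2533·σ/√n), corrections
on a zero-offset cohort stay within one rounding unit at 2000/age, and a
cohort built with σ = 1.26 y returns a range-averaged SD within ±0.05 y.

## Problem sizes and numerics

Monte-Carlo tests use 1000–2000 children per age and sex (42 000–84 000
records), chosen so that median standard errors are a factor ≳ 3 below
the asserted tolerances; the analysis scripts run the survey-scale
default (30/age/sex/city).  Bins near the age floor (≤ 4 y) are excluded
from moment-recovery assertions because the positivity floor censors the
noise there.  All randomness flows from explicit integer seeds;
determinism is asserted byte-for-byte on written CSVs.  Floats are
written with full `repr` precision so cohort round-trips are bit-exact.

## Known limitations

* The calibration assumes the cohort is representative; city pooling is a
  deliberate choice (city differences become statistical spread), and the
  emitted tables inherit any sampling bias.
* The terminal SMS anchor relies on linear extrapolation of the last
  below-saturation segment; with sparse anchors near saturation the scale
  end can move by a few tenths of a year.
* Half-year correction rows are served by interpolation of the
  anniversary medians, not by dedicated half-year samples (only 2.5 and
  3.5 y exist in the design).
* Corrections are not smoothed across grid points before rounding.
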