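"""Median-mapping calibration of population-adapted bone-age scales.

The core procedure: treat the maturity measure (GP bone age, or TW Sum
Maturity Score) as an abstract maturity score rather than an age estimate;
tabulate its median at each chronological age; monotonize the tabulation;
and invert it, so that an observed measure value maps to the chronological
age at which it is the population median.  A child whose GP BA equals the
median GP BA of 13-year-olds is assigned an adapted bone age of exactly 13,
whatever the GP atlas says.

Two emitted artefacts mirror the two published scale layouts:

* :func:`build_correction_table` — a GP-BA-indexed grid of additive
  corrections (adapted age minus GP BA), rounded to 0.1 y, the last row
  carrying "and above" semantics;
* :func:`build_sms_scale` — (bone age, median SMS) anchor pairs with the
  terminal anchor extended to SMS 1000 by linear extrapolation of the last
  segment, so the calibrated scale ends where the median score saturates.

Sample medians need not be monotone in age; :func:`monotonize` applies an
isotonic (pool-adjacent-violators, least-squares) fit before inversion.
Flat segments created by pooling invert to the midpoint of the tied age
range.  Observed values outside the tabulated range clamp to the first or
last grid age with an :class:`OutOfRangeWarning` — never silent
extrapolation, since the scales carry hard reliability limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .cohort import Cohort, Sex
from .errors import CalibrationError, OutOfRangeWarning
from .scales import CorrectionTable, SmsAnchorTable

__all__ = [
    "MedianCurve",
    "median_by_age",
    "monotonize",
    "invert_to_bone_age",
    "build_correction_table",
    "build_sms_scale",
    "scale_end",
]


@dataclass(frozen=True)
class MedianCurve:
    """Per-sex tabulation of the median maturity measure against CA."""

    sex: Sex
    measure: str
    ca_grid: np.ndarray
    median_value: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.ca_grid, dtype=float)
        m = np.asarray(self.median_value, dtype=float)
        object.__setattr__(self, "ca_grid", g)
        object.__setattr__(self, "median_value", m)
        if g.size != m.size:
            raise ValueError("ca_grid and median_value must be equal-length")
        if g.size and not np.all(np.diff(g) > 0):
            raise ValueError("ca_grid must be strictly increasing")

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.median_value) >= 0))


def median_by_age(
    cohort: Cohort,
    sex: Sex,
    measure: str = "gp_ba",
    grid: Optional[Sequence[float]] = None,
    n_min: int = 10,
    bin_width: float = 1.0,
) -> MedianCurve:
    """Interpolated sample median of ``measure`` at each grid age.

    Each record is assigned to its nearest grid age (midpoint boundaries,
    ties upward) provided it lies within the half-open window
    [g - w/2, g + w/2); on a uniform unit grid this is exactly the
    anniversary-centred bin convention of the reference curves, while a
    non-uniform grid (e.g. one containing the extra 2.5 and 3.5 y sampling
    ages) keeps each sampling age's records in their own bin instead of
    contaminating the neighbouring anniversary bins.  Grid ages whose bin
    holds fewer than ``n_min`` qualifying records are dropped with a
    warning; fewer than 2 surviving ages is a :class:`CalibrationError`.
    With no explicit grid, integer anniversary ages spanning the data are
    used.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    ca, val = [], []
    for r in cohort:
        if r.sex != sex:
            continue
        v = getattr(r, measure)
        if v is None:
            continue
        ca.append(r.ca)
        val.append(v)
    ca = np.asarray(ca, dtype=float)
    val = np.asarray(val, dtype=float)
    if ca.size == 0:
        raise CalibrationError(f"no {sex.value} records with {measure} present")
    if grid is None:
        grid = np.arange(np.ceil(ca.min()), np.floor(ca.max()) + 1.0)
    grid = np.asarray(sorted(grid), dtype=float)
    ages, medians, dropped = [], [], []
    half = bin_width / 2.0
    mids = (grid[:-1] + grid[1:]) / 2.0
    nearest = np.searchsorted(mids, ca, side="right")
    for k, g in enumerate(grid):
        mask = (nearest == k) & (ca >= g - half) & (ca < g + half)
        if mask.sum() < n_min:
            dropped.append(g)
            continue
        ages.append(g)
        medians.append(np.median(val[mask]))
    if dropped:
        warnings.warn(
            f"{len(dropped)} grid age(s) dropped for n < {n_min}: {dropped}", UserWarning
        )
    if len(ages) < 2:
        raise CalibrationError(
            f"only {len(ages)} grid age(s) survive n_min={n_min}; cannot calibrate"
        )
    return MedianCurve(sex, measure, np.array(ages), np.array(medians))


def monotonize(curve: MedianCurve) -> MedianCurve:
    """Non-decreasing least-squares fit of the medians (pool adjacent
    violators); the age grid is unchanged.  Monotone input is returned
    unchanged."""
    if curve.ca_grid.size == 0:
        raise CalibrationError("cannot monotonize an empty curve")
    if curve.is_monotone:
        return curve
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(curve.ca_grid, curve.median_value)
    return replace(curve, median_value=np.asarray(fitted, dtype=float))


def invert_to_bone_age(curve: MedianCurve, observed: float) -> float:
    """Chronological age at which the median curve equals ``observed``.

    Piecewise-linear interpolation on (median_value, ca_grid).  Flat
    segments (ties after monotonization) resolve to the midpoint of the
    tied age range.  Observed values below/above the tabulated medians
    clamp to the first/last grid age with an :class:`OutOfRangeWarning`.
    """
    m = curve.median_value
    a = curve.ca_grid
    if a.size == 0:
        raise CalibrationError("cannot invert an empty curve")
    if not curve.is_monotone:
        raise CalibrationError("curve must be monotonized before inversion")
    if observed < m[0]:
        warnings.warn(
            f"observed {observed} below tabulated range; clamped to age {a[0]}",
            OutOfRangeWarning,
        )
        return float(a[0])
    if observed > m[-1]:
        warnings.warn(
            f"observed {observed} above tabulated range; clamped to age {a[-1]}",
            OutOfRangeWarning,
        )
        return float(a[-1])
    exact = np.flatnonzero(m == observed)
    if exact.size:
        # midpoint of the (possibly single-point) tied age range
        return float((a[exact[0]] + a[exact[-1]]) / 2.0)
    i = int(np.searchsorted(m, observed)) - 1
    frac = (observed - m[i]) / (m[i + 1] - m[i])
    return float(a[i] + frac * (a[i + 1] - a[i]))


def build_correction_table(
    curve: MedianCurve,
    grid_step: float = 0.5,
    grid_lo: float = 2.0,
    rounding: float = 0.1,
) -> CorrectionTable:
    """Emit a GP-BA-indexed correction table from a monotone median curve.

    For each measure value ``g`` on the grid from ``grid_lo`` up to the
    curve's top median in steps of ``grid_step``:
    ``correction(g) = round(invert(g) - g)`` to the nearest ``rounding``.
    The terminal row carries "and above" semantics (its correction applies
    unchanged beyond the grid).
    """
    if not curve.is_monotone:
        raise CalibrationError("monotonize the curve before building a table")
    top = float(curve.median_value[-1])
    n_steps = int(np.floor((top - grid_lo) / grid_step + 1e-9))
    if n_steps < 0:
        raise CalibrationError(
            f"empty grid: top median {top} below grid_lo {grid_lo}"
        )
    grid = grid_lo + grid_step * np.arange(n_steps + 1)
    corrections = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OutOfRangeWarning)
        for g in grid:
            raw = invert_to_bone_age(curve, float(g)) - g
            corrections.append(round(np.round(raw / rounding) * rounding, 6))
    return CorrectionTable(curve.sex, grid, np.array(corrections), terminal_and_above=True)


def build_sms_scale(
    cohort: Cohort,
    sex: Sex,
    ba_grid: Optional[Sequence[float]] = None,
    n_min: int = 10,
    bin_width: float = 1.0,
) -> SmsAnchorTable:
    """Calibrate an SMS anchor table: (bone age = grid age, median SMS).

    The monotonized median SMS at each surviving grid age becomes an
    anchor.  The terminal anchor is extended to SMS 1000 at the age where
    the median first reaches it, by linear extrapolation of the last
    segment below saturation.
    """
    curve = monotonize(median_by_age(cohort, sex, "sms", ba_grid, n_min, bin_width))
    ages = curve.ca_grid
    sms = curve.median_value
    below = sms < 1000.0
    if below.sum() < 2:
        raise CalibrationError("need >= 2 anchors below SMS 1000 to place the scale end")
    a = ages[below]
    s = sms[below]
    # strictly increasing anchors: pool exact ties to their midpoint age
    keep_a, keep_s = [], []
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and s[j + 1] == s[i]:
            j += 1
        keep_a.append((a[i] + a[j]) / 2.0)
        keep_s.append(s[i])
        i = j + 1
    a = np.array(keep_a)
    s = np.array(keep_s)
    if a.size < 2:
        raise CalibrationError("degenerate median SMS curve (all values tied)")
    slope = (s[-1] - s[-2]) / (a[-1] - a[-2])
    end_age = a[-1] + (1000.0 - s[-1]) / slope
    return SmsAnchorTable(
        Sex.parse(sex) if not isinstance(sex, Sex) else sex,
        np.append(a, end_age),
        np.append(s, 1000.0),
    )


def scale_end(table: CorrectionTable, gp_scale_end: float) -> float:
    """Terminal age of a calibrated GP-style scale: the original GP scale
    end plus the terminal ("and above") correction."""
    return float(gp_scale_end + table.terminal_correction)
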