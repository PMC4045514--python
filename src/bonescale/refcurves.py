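"""Binned BA - CA reference curves: mean, SD and +/-2 SD bands per age bin.

Records are assigned to half-open 1-year bins centred on anniversary ages,
[c - 0.5, c + 0.5), matching a survey sampled at anniversaries: each bin
owns exactly one anniversary and jittered ages bin deterministically.  Bins
with fewer than ``n_min`` records are absent from the curve, not
zero-filled.  The +/-2 SD band is derived (mean +/- 2 sd), never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, Sex

__all__ = ["BinnedCurve", "ba_minus_ca_curve", "average_sd", "city_curves"]


@dataclass(frozen=True)
class BinnedCurve:
    """Per-sex BA - CA statistics (mean, sample SD, n) in age bins."""

    sex: Sex
    bin_centers: np.ndarray
    mean_diff: np.ndarray
    sd_diff: np.ndarray
    n: np.ndarray

    def band(self, k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper reference band, mean -/+ k*SD."""
        return self.mean_diff - k * self.sd_diff, self.mean_diff + k * self.sd_diff

    @property
    def total_n(self) -> int:
        return int(self.n.sum())


def _bin_center(ages: np.ndarray, bin_width: float) -> np.ndarray:
    # half-open [c - w/2, c + w/2) bins centred on multiples of the width
    return np.floor(np.asarray(ages) / bin_width + 0.5) * bin_width


def _extract(cohort: Cohort, sex: Sex, measure: str):
    ca, val = [], []
    for r in cohort:
        if r.sex != sex:
            continue
        v = getattr(r, measure)
        if v is None:
            continue
        ca.append(r.ca)
        val.append(v)
    return np.asarray(ca, dtype=float), np.asarray(val, dtype=float)


def ba_minus_ca_curve(
    cohort: Cohort,
    sex: Sex,
    measure: str = "gp_ba",
    bin_width: float = 1.0,
    n_min: int = 10,
) -> BinnedCurve:
    """Bin ``measure - ca`` for one sex and return per-bin mean, SD and n.

    ``measure`` names a record field (``gp_ba``, ``tw3_auto``, ...).  The
    SD is the sample SD (n - 1 denominator); bins with n < ``n_min`` are
    dropped.  Raises ``ValueError`` when no bin qualifies.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    ca, val = _extract(cohort, sex, measure)
    if ca.size == 0:
        raise ValueError(f"no {sex.value} records with {measure} present")
    diff = val - ca
    centers = _bin_center(ca, bin_width)
    out_c, out_m, out_s, out_n = [], [], [], []
    for c in np.unique(centers):
        d = diff[centers == c]
        if d.size < n_min:
            continue
        out_c.append(c)
        out_m.append(d.mean())
        out_s.append(d.std(ddof=1) if d.size >= 2 else 0.0)
        out_n.append(d.size)
    if not out_c:
        raise ValueError(f"no bin reached n_min={n_min}")
    return BinnedCurve(sex, np.array(out_c), np.array(out_m), np.array(out_s), np.array(out_n))


def average_sd(curve: BinnedCurve, age_lo: float, age_hi: float) -> float:
    """Unweighted mean of the per-bin SD over bins whose centres fall in
    the closed interval [age_lo, age_hi] — the convention used to quote a
    single SD for a whole age range."""
    mask = (curve.bin_centers >= age_lo) & (curve.bin_centers <= age_hi)
    if not mask.any():
        raise ValueError(f"no bin centers in [{age_lo}, {age_hi}]")
    return float(curve.sd_diff[mask].mean())


def city_curves(
    cohort: Cohort,
    sex: Sex,
    measure: str = "gp_ba",
    bin_width: float = 1.0,
    n_min: int = 10,
) -> dict[str, BinnedCurve]:
    """One BA - CA curve per distinct (nonempty) city label."""
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    cities = sorted({r.city for r in cohort if r.city})
    if not cities:
        raise ValueError("cohort has no city labels")
    out = {}
    for city in cities:
        sub = Cohort([r for r in cohort if r.city == city], provenance=cohort.provenance)
        try:
            out[city] = ba_minus_ca_curve(sub, sex, measure, bin_width, n_min)
        except ValueError:
            continue  # city contributes no qualifying bin for this sex
    if not out:
        raise ValueError("no city produced a qualifying curve")
    return out
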