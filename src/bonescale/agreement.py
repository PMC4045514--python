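"""Bland-Altman agreement between two bone-age ratings of the same images.

The convention throughout: ``rating_a`` is the automated rating, ``rating_b``
the manual one, ``diff = a - b`` (so a negative bias means the automated
rating reads younger than the manual one), and ``mid = (a + b) / 2`` is the
Bland-Altman x-axis.  The rms deviation is the root-mean-square of the raw
differences about zero (n denominator), not a variance estimate, so the
identity rms^2 = bias^2 + population-variance(diff) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = ["RatingPair", "AgreementSummary", "pair_ratings", "bias_rms", "running_average"]


@dataclass(frozen=True)
class RatingPair:
    """One image rated twice; mid and diff are derived, never stored."""

    subject_id: str
    rating_a: float
    rating_b: float

    @property
    def mid(self) -> float:
        return (self.rating_a + self.rating_b) / 2.0

    @property
    def diff(self) -> float:
        return self.rating_a - self.rating_b


class PairedRatings(list):
    """List of :class:`RatingPair` that also reports how many records were
    skipped for missing a rating."""

    def __init__(self, pairs, n_skipped: int = 0):
        super().__init__(pairs)
        self.n_skipped = n_skipped


@dataclass(frozen=True)
class AgreementSummary:
    bias: float
    rms: float
    n: int
    range: tuple[float, float]


def pair_ratings(cohort: Cohort, field_a: str = "tw3_auto", field_b: str = "tw3_manual") -> PairedRatings:
    """One pair per record carrying both ratings; records missing either
    are skipped and counted on the result's ``n_skipped``."""
    pairs, skipped = [], 0
    for r in cohort:
        a = getattr(r, field_a)
        b = getattr(r, field_b)
        if a is None or b is None:
            skipped += 1
            continue
        pairs.append(RatingPair(r.subject_id, float(a), float(b)))
    if not pairs:
        raise ValueError(f"no records carry both {field_a} and {field_b}")
    return PairedRatings(pairs, n_skipped=skipped)


def bias_rms(pairs, mid_lo: float, mid_hi: float) -> AgreementSummary:
    """Mean and root-mean-square difference over pairs whose mid lies in
    the closed interval [mid_lo, mid_hi]."""
    diffs = np.array([p.diff for p in pairs if mid_lo <= p.mid <= mid_hi])
    if diffs.size < 2:
        raise ValueError(f"need >= 2 pairs with mid in [{mid_lo}, {mid_hi}], got {diffs.size}")
    return AgreementSummary(
        bias=float(diffs.mean()),
        rms=float(np.sqrt(np.mean(diffs**2))),
        n=int(diffs.size),
        range=(float(mid_lo), float(mid_hi)),
    )


def running_average(
    pairs,
    window: float = 1.0,
    grid_step: float = 0.25,
    min_pairs: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar running mean of diff versus mid.

    Evaluated on a ``grid_step`` grid spanning the mid range; each point
    averages the pairs with |mid - point| <= window/2 and is omitted when
    fewer than ``min_pairs`` fall in its window.  Returns (grid, means).
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 pairs for a running average")
    mids = np.array([p.mid for p in pairs])
    diffs = np.array([p.diff for p in pairs])
    lo = np.floor(mids.min() / grid_step) * grid_step
    hi = np.ceil(mids.max() / grid_step) * grid_step
    grid = lo + grid_step * np.arange(int(round((hi - lo) / grid_step)) + 1)
    out_x, out_y = [], []
    for x in grid:
        mask = np.abs(mids - x) <= window / 2.0
        if mask.sum() < min_pairs:
            continue
        out_x.append(x)
        out_y.append(diffs[mask].mean())
    return np.array(out_x), np.array(out_y)
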