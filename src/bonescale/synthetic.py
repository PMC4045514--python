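"""Synthetic cross-sectional cohorts with the structure the analysis assumes.

The generator emulates the design of the 2005 five-city Chinese bone-age
survey: children sampled close to their birthday anniversaries from 2 to
20 years (plus extra sampling points at 2.5 and 3.5 y), a sex-specific
population maturation offset (mean BA - CA) rising to about +1 year by the
end of puberty, additive city-level shifts, and Gaussian individual scatter
of BA - CA with SD near 1.1 years.  The Sum Maturity Score channel is
generated by pushing a latent TW-scale bone age (same offset structure,
independent noise) through a monotone age -> SMS map, by default the
published TW-China05 anchors, so the generator and the published scale are
mutually consistent and calibration on synthetic data can be checked
against the injected truth.

Real data differ in ways the generator does not model: rater drift,
non-Gaussian tails, secular trends, and per-city age-range gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .cohort import Cohort, Sex, SubjectRecord
from . import scales

__all__ = ["OffsetCurve", "CohortConfig", "simulate_cohort", "maturity_to_sms", "DEFAULT_AGES"]

#: Anniversary sampling ages 2-20 y plus the extra 2.5 and 3.5 y points.
DEFAULT_AGES: tuple[float, ...] = tuple(
    sorted(set([float(a) for a in range(2, 21)] + [2.5, 3.5]))
)

#: Bone ages are floored here to keep them positive after noise.
_BA_FLOOR = 0.1


@dataclass(frozen=True)
class OffsetCurve:
    """Piecewise-linear curve of (age, offset) knots, constant beyond the ends.

    Used for the population maturation offset (mean BA - CA as a function of
    age) and, optionally, for an age-dependent residual SD.
    """

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        knots = tuple((float(a), float(v)) for a, v in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 2:
            raise ValueError("an OffsetCurve needs at least 2 knots")
        ages = [a for a, _ in knots]
        if not all(b > a for a, b in zip(ages, ages[1:])):
            raise ValueError("knot ages must be strictly increasing")

    def __call__(self, age):
        ages, values = zip(*self.knots)
        return np.interp(age, ages, values)

    @classmethod
    def constant(cls, value: float, lo: float = 0.0, hi: float = 100.0) -> "OffsetCurve":
        return cls(((lo, value), (hi, value)))


# Default maturation offsets: flat at zero through childhood, rising through
# puberty to +1 y at its end (boys ~16 y, girls ~15 y), flat thereafter.
DEFAULT_OFFSET_MALE = OffsetCurve(((2.0, 0.0), (9.0, 0.0), (16.0, 1.0), (20.0, 1.0)))
DEFAULT_OFFSET_FEMALE = OffsetCurve(((2.0, 0.0), (8.0, 0.0), (15.0, 1.0), (19.0, 1.0)))

# Five cities with additive BA - CA shifts spanning ~0.6 y, the most
# advanced being Shanghai and the most delayed Dalian.
DEFAULT_CITIES: Mapping[str, float] = {
    "Dalian": -0.3,
    "Wenzhou": -0.15,
    "Shijiazhuang": 0.0,
    "Guangzhou": 0.15,
    "Shanghai": 0.3,
}

# TW3 automated-vs-manual rater model: per-sex bias (automated - manual)
# and scatter of the manual rating about the automated one.  With bias b
# and scatter s the rms difference is sqrt(b^2 + s^2): 0.64 y for boys,
# ~0.68 y for girls.
DEFAULT_RATER_BIAS: Mapping[Sex, float] = {Sex.MALE: 0.0, Sex.FEMALE: -0.37}
DEFAULT_RATER_SD: Mapping[Sex, float] = {Sex.MALE: 0.64, Sex.FEMALE: 0.57}


def maturity_to_sms(
    tw_ba: float,
    sex: Sex,
    anchors: Optional[scales.SmsAnchorTable] = None,
):
    """Map a TW-scale bone age to a Sum Maturity Score.

    Strictly increasing piecewise-linear map through the anchor set
    (default: the published TW-China05 anchors).  Output is clamped to
    [first anchor SMS, 1000]; at or beyond the terminal anchor age it
    returns 1000.  Exactly inverse (up to interpolation) to
    :func:`bonescale.scales.tw_china05` on the shared anchors.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    if np.any(np.asarray(tw_ba) <= 0):
        raise ValueError("tw_ba must be positive")
    if anchors is None:
        anchors = scales.packaged_sms_table(sex)
    out = np.interp(tw_ba, anchors.bone_ages, anchors.sms)
    return float(out) if np.isscalar(tw_ba) else out


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated cross-sectional survey.

    ``n_per_age_per_sex`` counts children per sampling age, per sex, *per
    city*.  ``residual_sd`` is the SD of individual BA - CA scatter in
    years (a float, or an :class:`OffsetCurve` of SDs for age dependence).
    ``tw3_rater_bias``/``tw3_rater_sd`` parameterize the manual TW3 rating
    generated alongside the automated one.
    """

    ages: tuple[float, ...] = DEFAULT_AGES
    n_per_age_per_sex: int = 30
    cities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CITIES))
    offset_curve_male: OffsetCurve = DEFAULT_OFFSET_MALE
    offset_curve_female: OffsetCurve = DEFAULT_OFFSET_FEMALE
    residual_sd: Union[float, OffsetCurve] = 1.1
    age_jitter_sd: float = 0.05
    tw3_rater_bias: Mapping[Sex, float] = field(default_factory=lambda: dict(DEFAULT_RATER_BIAS))
    tw3_rater_sd: Mapping[Sex, float] = field(default_factory=lambda: dict(DEFAULT_RATER_SD))
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_age_per_sex < 1:
            raise ValueError("n_per_age_per_sex must be >= 1")
        if not self.ages or any(a <= 0 for a in self.ages):
            raise ValueError("all sampling ages must be positive")
        if isinstance(self.residual_sd, OffsetCurve):
            if any(v <= 0 for _, v in self.residual_sd.knots):
                raise ValueError("residual_sd curve values must be positive")
        elif not self.residual_sd > 0:
            raise ValueError("residual_sd must be positive")
        if self.age_jitter_sd < 0:
            raise ValueError("age_jitter_sd must be non-negative")
        if not self.cities:
            raise ValueError("at least one city is required")

    def offset_curve(self, sex: Sex) -> OffsetCurve:
        return self.offset_curve_male if sex == Sex.MALE else self.offset_curve_female

    def residual_sd_at(self, age):
        if isinstance(self.residual_sd, OffsetCurve):
            return self.residual_sd(age)
        return np.full_like(np.asarray(age, dtype=float), float(self.residual_sd))

    def digest(self) -> str:
        """Stable config fingerprint for provenance/manifests."""
        import hashlib

        def _enc(obj):
            if isinstance(obj, OffsetCurve):
                return {"knots": obj.knots}
            if isinstance(obj, Sex):
                return obj.value
            if isinstance(obj, Mapping):
                return {(_k.value if isinstance(_k, Sex) else _k): _enc(v) for _k, v in obj.items()}
            return obj

        blob = json.dumps({k: _enc(v) for k, v in asdict(self).items()}, sort_keys=True, default=_enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cross-sectional cohort; deterministic given ``config.seed``.

    For each sex, sampling age ``a`` and city ``k``:

    * ``ca = a + jitter``, jitter ~ Normal(0, age_jitter_sd)
    * ``gp_ba = ca + offset_sex(ca) + shift_k + eps``, eps ~ Normal(0, sd(ca))
    * a latent TW bone age with the same offset structure but independent
      noise is pushed through :func:`maturity_to_sms` to produce ``sms``
      and recorded as ``tw3_auto``; ``tw3_manual`` adds the rater
      bias/scatter for that sex.

    Bone ages are floored at a small positive value.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    counter = 0
    for sex in (Sex.MALE, Sex.FEMALE):
        offset = config.offset_curve(sex)
        bias = float(config.tw3_rater_bias.get(sex, 0.0))
        rater_sd = float(config.tw3_rater_sd.get(sex, 0.0))
        for city, shift in config.cities.items():
            for a in config.ages:
                n = config.n_per_age_per_sex
                ca = a + rng.normal(0.0, config.age_jitter_sd, n) if config.age_jitter_sd > 0 else np.full(n, float(a))
                ca = np.maximum(ca, _BA_FLOOR)
                sd = config.residual_sd_at(ca)
                gp_ba = np.maximum(ca + offset(ca) + shift + rng.normal(0.0, 1.0, n) * sd, _BA_FLOOR)
                tw_ba = np.maximum(ca + offset(ca) + shift + rng.normal(0.0, 1.0, n) * sd, _BA_FLOOR)
                sms = maturity_to_sms(tw_ba, sex)
                # bias is automated - manual, so the manual rating subtracts it
                tw3_manual = tw_ba - bias + (rng.normal(0.0, rater_sd, n) if rater_sd > 0 else 0.0)
                for i in range(n):
                    records.append(
                        SubjectRecord(
                            subject_id=f"S{counter:06d}",
                            sex=sex,
                            ca=float(ca[i]),
                            city=city,
                            gp_ba=float(gp_ba[i]),
                            sms=float(sms[i]),
                            tw3_auto=float(tw_ba[i]),
                            tw3_manual=float(tw3_manual[i]),
                        )
                    )
                    counter += 1
    return Cohort(records, provenance=f"simulate_cohort(seed={config.seed}, digest={config.digest()})")
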