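"""Shared synthetic-cohort fixtures.

All cohorts are generated at test time with fixed seeds; the heavier
Monte-Carlo cohorts are session-scoped so the recovery tests and the
acceptance checks share them.
"""

import pytest

import bonescale as bs

ZERO = bs.OffsetCurve.constant(0.0)


@pytest.fixture(scope="session")
def zero_offset_cohort_2000():
    """Single city, zero maturation offset, sigma = 1.1 y, n = 2000/age/sex."""
    cfg = bs.CohortConfig(
        seed=42,
        n_per_age_per_sex=2000,
        cities={"one": 0.0},
        offset_curve_male=ZERO,
        offset_curve_female=ZERO,
    )
    return cfg, bs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def offset_cohort_1000():
    """Single city, default piecewise offsets peaking at +1.0 y, n = 1000/age/sex."""
    cfg = bs.CohortConfig(seed=7, n_per_age_per_sex=1000, cities={"one": 0.0})
    return cfg, bs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sd126_cohort():
    """Zero offset, sigma = 1.26 y, n = 2000/age/sex — SD-recovery conditions."""
    cfg = bs.CohortConfig(
        seed=11,
        n_per_age_per_sex=2000,
        cities={"one": 0.0},
        offset_curve_male=ZERO,
        offset_curve_female=ZERO,
        residual_sd=1.26,
    )
    return cfg, bs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def const_half_cohort():
    """Constant +0.5 y offset, sigma = 1.1 y, n = 2000/age/sex."""
    cfg = bs.CohortConfig(
        seed=13,
        n_per_age_per_sex=2000,
        cities={"one": 0.0},
        offset_curve_male=bs.OffsetCurve.constant(0.5),
        offset_curve_female=bs.OffsetCurve.constant(0.5),
    )
    return cfg, bs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def five_city_cohort():
    """Default five-city design at survey scale (30/age/sex/city)."""
    cfg = bs.CohortConfig(seed=5)
    return cfg, bs.simulate_cohort(cfg)
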