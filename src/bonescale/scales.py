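"""Population-adapted bone-age scales and their application.

Two scale families are supported:

* **Correction tables** (BX-China05 style): a per-sex grid of Greulich-Pyle
  bone ages with an additive correction at each grid point, the last row
  carrying "and above" semantics.  Applying the scale means adding the
  (linearly interpolated) correction to an observed GP BA.
* **SMS anchor tables** (TW-China05 style): per-sex ascending pairs of
  (bone age, Sum Maturity Score); applying the scale means piecewise-linear
  interpolation of bone age against an observed SMS.  The terminal anchor
  sits at SMS = 1000, the score at full maturity, so the anchored terminal
  age is where the scale ends.

The tables published for 2005 urban Han Chinese children ship with the
package and are the defaults; any table in the same CSV layouts can be
loaded and used instead.  The automated GP rating becomes unreliable above
GP BA 17 y (boys) / 15 y (girls); outputs beyond those limits carry a
:class:`ReliabilityWarning` rather than failing, since they are flagged as
increased-uncertainty, not invalid.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .cohort import Sex
from .errors import OutOfRangeWarning, ReliabilityWarning, ScaleValidationError

__all__ = [
    "CorrectionTable",
    "SmsAnchorTable",
    "bx_china05",
    "tw_china05",
    "load_scale",
    "save_correction_tables",
    "save_sms_tables",
    "packaged_correction_table",
    "packaged_sms_table",
]

#: GP BA above which the automated rating grows uncertain (years).
RELIABILITY_LIMIT_GP = {Sex.MALE: 17.0, Sex.FEMALE: 15.0}
#: Terminal age of the original GP atlas scale (years).
GP_SCALE_END = {Sex.MALE: 19.0, Sex.FEMALE: 18.0}

_AND_ABOVE = "_and_above"


@dataclass(frozen=True)
class CorrectionTable:
    """Per-sex grid of (GP BA, additive correction) pairs.

    ``terminal_and_above`` marks the last row as open-ended: its correction
    applies unchanged to any GP BA at or beyond the last grid value.
    """

    sex: Sex
    gp_grid: np.ndarray
    corrections: np.ndarray
    terminal_and_above: bool = True

    def __post_init__(self):
        g = np.asarray(self.gp_grid, dtype=float)
        c = np.asarray(self.corrections, dtype=float)
        object.__setattr__(self, "gp_grid", g)
        object.__setattr__(self, "corrections", c)
        if g.size != c.size or g.size < 1:
            raise ScaleValidationError("grid and corrections must be equal-length and nonempty")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ScaleValidationError("gp_ba grid must be strictly increasing")

    @property
    def terminal_correction(self) -> float:
        return float(self.corrections[-1])

    def adapted_ages(self) -> np.ndarray:
        """gp_ba + correction at each grid point (the calibrated mapping)."""
        return self.gp_grid + self.corrections

    def scale_end(self, gp_scale_end: Optional[float] = None) -> float:
        """Terminal age of the adapted scale: original scale end plus the
        "and above" correction."""
        if gp_scale_end is None:
            gp_scale_end = GP_SCALE_END[self.sex]
        return float(gp_scale_end + self.terminal_correction)

    def validate_strict(self) -> None:
        """Enforce the published-table invariants: corrections are exact
        multiples of 0.1 and the adapted mapping is non-decreasing."""
        mult = np.round(self.corrections / 0.1)
        if not np.allclose(self.corrections, mult * 0.1, atol=1e-9):
            bad = int(np.argmax(~np.isclose(self.corrections, mult * 0.1, atol=1e-9)))
            raise ScaleValidationError(
                f"row {bad}: correction {self.corrections[bad]} is not a multiple of 0.1"
            )
        adapted = self.adapted_ages()
        if np.any(np.diff(adapted) < -1e-9):
            bad = int(np.argmax(np.diff(adapted) < -1e-9)) + 1
            raise ScaleValidationError(f"row {bad}: gp_ba + correction decreases")


@dataclass(frozen=True)
class SmsAnchorTable:
    """Per-sex ascending (bone age, SMS) anchors; terminal anchor at SMS 1000."""

    sex: Sex
    bone_ages: np.ndarray
    sms: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.bone_ages, dtype=float)
        s = np.asarray(self.sms, dtype=float)
        object.__setattr__(self, "bone_ages", a)
        object.__setattr__(self, "sms", s)
        if a.size != s.size or a.size < 2:
            raise ScaleValidationError("need >= 2 equal-length anchor pairs")
        if not np.all(np.diff(a) > 0):
            raise ScaleValidationError("anchor bone ages must be strictly increasing")
        if not np.all(np.diff(s) > 0):
            raise ScaleValidationError("anchor SMS values must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1000):
            bad = int(np.argmax((s < 0) | (s > 1000)))
            raise ScaleValidationError(f"row {bad}: sms {s[bad]} outside [0, 1000]")

    @property
    def scale_end(self) -> float:
        """Bone age at SMS 1000 — where the adapted TW scale ends."""
        return float(self.bone_ages[-1])

    def validate_strict(self) -> None:
        if self.sms[-1] != 1000:
            raise ScaleValidationError("terminal anchor must have sms = 1000")


def _packaged(name: str) -> Path:
    return Path(str(resources.files("bonescale").joinpath("data", name)))


def _load_correction_csv(path: Path) -> dict[Sex, CorrectionTable]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ScaleValidationError(f"{path}: empty scale file")
    cols = {
        Sex.MALE: next((c for c in rows[0] if c in ("correction_boys", "correction_male")), None),
        Sex.FEMALE: next((c for c in rows[0] if c in ("correction_girls", "correction_female")), None),
    }
    grid, terminal = [], False
    for i, row in enumerate(rows):
        token = row["gp_ba"]
        if token.endswith(_AND_ABOVE):
            if i != len(rows) - 1:
                raise ScaleValidationError(f"row {i}: '{_AND_ABOVE}' marker before last row")
            token = token[: -len(_AND_ABOVE)]
            terminal = True
        try:
            grid.append(float(token))
        except ValueError:
            raise ScaleValidationError(f"row {i}: bad gp_ba {row['gp_ba']!r}") from None
    tables = {}
    for sex, col in cols.items():
        if col is None:
            continue
        try:
            corr = [float(r[col]) for r in rows]
        except ValueError as exc:
            raise ScaleValidationError(f"{path}: {exc}") from None
        tables[sex] = CorrectionTable(sex, np.array(grid), np.array(corr), terminal_and_above=terminal)
    if not tables:
        raise ScaleValidationError(f"{path}: no correction column found")
    return tables


def _load_sms_csv(path: Path) -> dict[Sex, SmsAnchorTable]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    by_sex: dict[Sex, list[tuple[float, float]]] = {}
    for i, row in enumerate(rows):
        try:
            sex = Sex.parse(row["sex"])
            pair = (float(row["bone_age"]), float(row["sms"]))
        except (ValueError, KeyError) as exc:
            raise ScaleValidationError(f"row {i}: {exc}") from None
        by_sex.setdefault(sex, []).append(pair)
    tables = {}
    for sex, pairs in by_sex.items():
        ages, sms = zip(*pairs)
        tables[sex] = SmsAnchorTable(sex, np.array(ages), np.array(sms))
    return tables


def load_scale(
    path: str | Path,
    kind: str,
    sex: Optional[Sex] = None,
    strict: bool = True,
) -> Union[CorrectionTable, SmsAnchorTable, dict]:
    """Load a scale table from its CSV layout.

    Parameters
    ----------
    kind : {'correction', 'sms'}
    sex : optional
        If given, return that sex's table; otherwise return a
        ``{Sex: table}`` mapping (or the single table if only one sex is
        present in the file).
    strict : bool
        Enforce the published-table invariants (corrections multiples of
        0.1, monotone adapted mapping, terminal SMS = 1000).
    """
    path = Path(path)
    if kind == "correction":
        tables = _load_correction_csv(path)
    elif kind == "sms":
        tables = _load_sms_csv(path)
    else:
        raise ValueError(f"unknown scale kind {kind!r}")
    if strict:
        for t in tables.values():
            t.validate_strict()
    if sex is not None:
        if sex not in tables:
            raise ScaleValidationError(f"{path}: no table for sex {sex.value}")
        return tables[sex]
    if len(tables) == 1:
        return next(iter(tables.values()))
    return tables


def align_correction_tables(tables: dict[Sex, CorrectionTable]) -> dict[Sex, CorrectionTable]:
    """Truncate correction tables to their shared grid so they can be
    co-saved in one file (the printed-table layout).  The new terminal row
    keeps "and above" semantics."""
    grids = [t.gp_grid for t in tables.values()]
    shared = grids[0]
    for g in grids[1:]:
        shared = np.intersect1d(shared, g)
    if shared.size == 0:
        raise ValueError("correction tables share no grid values")
    out = {}
    for sex, t in tables.items():
        mask = np.isin(t.gp_grid, shared)
        out[sex] = CorrectionTable(
            sex, t.gp_grid[mask], t.corrections[mask], terminal_and_above=t.terminal_and_above
        )
    return out


def save_correction_tables(tables: dict[Sex, CorrectionTable], path: str | Path) -> None:
    """Write correction tables in the documented layout (shared grid required)."""
    tabs = list(tables.values())
    grid = tabs[0].gp_grid
    for t in tabs[1:]:
        if not np.array_equal(t.gp_grid, grid):
            raise ValueError("correction tables must share a gp_ba grid to be co-saved")
    header = ["gp_ba"] + [
        "correction_boys" if s == Sex.MALE else "correction_girls" for s in tables
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, g in enumerate(grid):
            label = f"{g:g}"
            if i == len(grid) - 1 and tabs[0].terminal_and_above:
                label += _AND_ABOVE
            writer.writerow([label] + [f"{t.corrections[i]:.1f}" for t in tabs])


def save_sms_tables(tables: dict[Sex, SmsAnchorTable], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sex", "bone_age", "sms"])
        for sex, t in tables.items():
            for a, s in zip(t.bone_ages, t.sms):
                writer.writerow([sex.value, repr(float(a)), f"{s:g}"])


_PACKAGED_CORRECTIONS: Optional[dict] = None
_PACKAGED_SMS: Optional[dict] = None


def packaged_correction_table(sex: Sex) -> CorrectionTable:
    """The published BX-China05 correction table for one sex."""
    global _PACKAGED_CORRECTIONS
    if _PACKAGED_CORRECTIONS is None:
        _PACKAGED_CORRECTIONS = _load_correction_csv(_packaged("bx_china05_corrections.csv"))
        for t in _PACKAGED_CORRECTIONS.values():
            t.validate_strict()
    return _PACKAGED_CORRECTIONS[sex]


def packaged_sms_table(sex: Sex) -> SmsAnchorTable:
    """The published TW-China05 anchor table for one sex."""
    global _PACKAGED_SMS
    if _PACKAGED_SMS is None:
        _PACKAGED_SMS = _load_sms_csv(_packaged("tw_china05_anchors.csv"))
        for t in _PACKAGED_SMS.values():
            t.validate_strict()
    return _PACKAGED_SMS[sex]


def bx_china05(gp_ba: float, sex: Sex, table: Optional[CorrectionTable] = None) -> float:
    """Adapt a Greulich-Pyle bone age to the reference population.

    The correction is looked up at ``gp_ba`` (exact grid hit) or linearly
    interpolated between adjacent grid corrections.  Beyond the terminal
    grid value the terminal ("and above") correction applies unchanged;
    below the first grid value the first correction applies and an
    :class:`OutOfRangeWarning` is emitted.  Values beyond the automated
    method's reliability limit additionally emit a
    :class:`ReliabilityWarning`.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    if not gp_ba > 0:
        raise ValueError(f"gp_ba must be positive, got {gp_ba}")
    if table is None:
        table = packaged_correction_table(sex)
    if gp_ba < table.gp_grid[0]:
        warnings.warn(
            f"GP BA {gp_ba} below table range; first correction applied", OutOfRangeWarning
        )
    limit = RELIABILITY_LIMIT_GP.get(sex)
    if limit is not None and gp_ba > limit:
        warnings.warn(
            f"GP BA {gp_ba} above the automated reliability limit of {limit} y",
            ReliabilityWarning,
        )
    corr = float(np.interp(gp_ba, table.gp_grid, table.corrections))
    return float(gp_ba + corr)


def tw_china05(sms: float, sex: Sex, table: Optional[SmsAnchorTable] = None) -> float:
    """Convert a Sum Maturity Score to the population-adapted TW bone age.

    Piecewise-linear interpolation on the (SMS, bone age) anchors; exact
    anchor hits return the anchored bone age.  An SMS below the first
    anchor clamps to the first anchored bone age with an
    :class:`OutOfRangeWarning`.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    if not (0 <= sms <= 1000):
        raise ValueError(f"sms must lie in [0, 1000], got {sms}")
    if table is None:
        table = packaged_sms_table(sex)
    if sms < table.sms[0]:
        warnings.warn(
            f"SMS {sms} below the first anchor; clamped to bone age {table.bone_ages[0]}",
            OutOfRangeWarning,
        )
    return float(np.interp(sms, table.sms, table.bone_ages))
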