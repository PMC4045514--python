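"""Exception and warning types shared across the pipeline."""


class BonescaleError(Exception):
    """Base class for all package-specific errors."""


class CohortFormatError(BonescaleError):
    """A cohort file is structurally unusable (e.g. a mandatory column is missing)."""


class RowValidationError(BonescaleError):
    """A single cohort row violates an invariant.

    Carries the zero-based data-row index so callers can point at the
    offending line.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class CalibrationError(BonescaleError):
    """A scale cannot be calibrated from the data at hand (too few bins, etc.)."""


class ScaleValidationError(BonescaleError):
    """A scale table violates its invariants (non-monotone grid, SMS > 1000, ...)."""


class OutOfRangeWarning(UserWarning):
    """An observed value fell outside a table/curve range and was clamped."""


class ReliabilityWarning(UserWarning):
    """A bone age lies beyond the automated method's stated reliability limit."""
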