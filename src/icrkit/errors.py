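"""Shared exception types.

All validation problems raise :class:`ValidationError` (a ``ValueError``)
so callers can catch one type; more specific subclasses carry structured
context for reporting.
"""

from __future__ import annotations


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class SchemeError(ValidationError):
    """A scoring scheme violates its structural invariants."""


class MissingItemError(ValidationError):
    """A record lacks one or more required items."""

    def __init__(self, patient_id: str, missing: list[str]):
        self.patient_id = patient_id
        self.missing = list(missing)
        super().__init__(
            f"record {patient_id!r} is missing item(s): {', '.join(self.missing)}"
        )


class RangeError(ValidationError):
    """A numeric value lies outside its admissible range."""


class InfeasibleTargetError(ValueError):
    """A calibration target exceeds what the generative model can produce."""

    def __init__(self, target: float, achievable_max: float):
        self.target = target
        self.achievable_max = achievable_max
        super().__init__(
            f"target correlation {target:.3f} is unattainable; the achievable "
            f"maximum under the current marginals and loadings is about "
            f"{achievable_max:.3f}"
        )


class CohortValidationError(ValidationError):
    """One or more cohort rows failed validation.

    ``row_errors`` is a list of ``(row_number, message)`` pairs, with row
    numbers counted from 1 at the first data row.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.row_errors[:10])
        more = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}{more}")
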