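"""Interoperability with externally computed Cariogram assessments.

The Cariogram software outputs a "chance of avoiding caries" percentage.
For comparison against a risk-scaled instrument that value is replaced by
its complement to 100 (e.g. a 33% chance of avoiding caries becomes a 67%
risk value), and the chance is binned into Low / Moderate / High risk.
The Cariogram algorithm itself is out of scope here: the percentage is an
input.

Two published boundary conventions exist for the category bins and both
are implemented:

``"table"`` (default)
    Closed integer bins on the chance scale — High 0–25, Moderate 26–75,
    Low 76–100 — extended to real values as [0, 25.5) / [25.5, 75.5) /
    [75.5, 100].
``"strict"``
    Open boundaries — chance < 25 → High, 25–75 → Moderate, > 75 → Low.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RangeError, ValidationError

#: Cariogram risk category labels, lowest risk first.
CARIOGRAM_CATEGORIES: tuple[str, ...] = ("Low", "Moderate", "High")

CONVENTIONS = ("table", "strict")


def complement_risk(chance_avoid: float) -> float:
    """Risk percentage: 100 minus the chance of avoiding caries."""
    if not (0 <= chance_avoid <= 100):
        raise RangeError(f"chance of avoiding caries {chance_avoid!r} outside [0, 100]")
    return 100 - chance_avoid


def categorize_cariogram(chance_avoid: float, convention: str = "table") -> str:
    """Risk category from the chance-of-avoiding-caries percentage.

    A *low* chance of avoiding caries means a *high* caries risk, so the
    category scale runs opposite to the chance scale.
    """
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    if not (0 <= chance_avoid <= 100):
        raise RangeError(f"chance of avoiding caries {chance_avoid!r} outside [0, 100]")
    if convention == "table":
        if chance_avoid < 25.5:
            return "High"
        if chance_avoid < 75.5:
            return "Moderate"
        return "Low"
    # strict: < 25 / 25–75 / > 75
    if chance_avoid < 25:
        return "High"
    if chance_avoid <= 75:
        return "Moderate"
    return "Low"


@dataclass(frozen=True)
class CariogramAssessment:
    """Chance value, its risk complement, and the risk category."""

    patient_id: str
    chance_avoid: float
    risk_value: float
    category: str


def assess(
    patient_id: str, chance_avoid: float, convention: str = "table"
) -> CariogramAssessment:
    """Bundle the risk complement and the category for one patient."""
    return CariogramAssessment(
        patient_id=patient_id,
        chance_avoid=chance_avoid,
        risk_value=complement_risk(chance_avoid),
        category=categorize_cariogram(chance_avoid, convention),
    )
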