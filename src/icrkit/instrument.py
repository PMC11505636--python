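"""The Index of Caries Risk (ICR) scoring instrument.

The ICR is a pediatric caries-risk questionnaire built from eight ordinal
items — diet content, diet frequency, oral-hygiene habits, fluoride
program, family susceptibility, caries experience, oral-hygiene status and
a salivary pH litmus test — each observed at one of four ordered levels.
The instrument score is the sum of the per-level points over the eight
items, and the total is binned into Low / Moderate / High / Very High
risk categories.

This module defines the scheme (items, points, category bins), validates
patient records, computes scores, and maps raw clinical measurements
(meal counts, dmft-style caries counts, numeric pH, parent caries status)
onto item levels.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .errors import MissingItemError, RangeError, SchemeError, ValidationError

#: Canonical item identifiers, in questionnaire order.
ITEM_IDS: tuple[str, ...] = (
    "diet_content",
    "diet_frequency",
    "hygiene_habits",
    "fluoride_program",
    "family_susceptibility",
    "caries_experience",
    "oral_hygiene_status",
    "ph_test",
)

#: Risk category labels, lowest risk first.
ICR_CATEGORIES: tuple[str, ...] = ("Low", "Moderate", "High", "Very High")

N_LEVELS = 4


@dataclass(frozen=True)
class ItemDefinition:
    """One ICR item: four ordered levels with labels and point values."""

    item_id: str
    level_labels: tuple[str, ...]
    level_points: tuple[int, ...]

    def __post_init__(self):
        if self.item_id not in ITEM_IDS:
            raise SchemeError(f"unknown item_id {self.item_id!r}")
        if len(self.level_labels) != N_LEVELS or len(self.level_points) != N_LEVELS:
            raise SchemeError(
                f"item {self.item_id!r} must define exactly {N_LEVELS} levels"
            )
        pts = self.level_points
        if pts[0] != 0:
            raise SchemeError(f"item {self.item_id!r}: level 0 must award 0 points")
        if any(int(p) != p or p < 0 for p in pts):
            raise SchemeError(f"item {self.item_id!r}: points must be non-negative integers")
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise SchemeError(f"item {self.item_id!r}: points must be non-decreasing")

    @property
    def max_points(self) -> int:
        return self.level_points[-1]


@dataclass(frozen=True)
class ScoringScheme:
    """The full ICR definition: eight items plus category bins.

    ``category_thresholds`` is an ordered tuple of ``(label, lo, hi)``
    closed integer bins; they must be contiguous, start at 0 and cover the
    theoretical maximum score.
    """

    items: Mapping[str, ItemDefinition]
    category_thresholds: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if set(self.items) != set(ITEM_IDS):
            missing = sorted(set(ITEM_IDS) - set(self.items))
            extra = sorted(set(self.items) - set(ITEM_IDS))
            raise SchemeError(f"scheme items mismatch (missing {missing}, extra {extra})")
        for item_id, item in self.items.items():
            if item.item_id != item_id:
                raise SchemeError(f"item keyed {item_id!r} has item_id {item.item_id!r}")
        bins = self.category_thresholds
        if not bins or bins[0][1] != 0:
            raise SchemeError("category bins must start at 0")
        for (_, _, hi), (_, lo2, _) in zip(bins, bins[1:]):
            if lo2 != hi + 1:
                raise SchemeError("category bins must be contiguous and non-overlapping")
        if bins[-1][2] < self.max_score:
            raise SchemeError(
                f"category bins end at {bins[-1][2]} but the maximum score is {self.max_score}"
            )

    @property
    def max_score(self) -> int:
        return sum(item.max_points for item in self.items.values())

    @property
    def category_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.category_thresholds)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "items": {
                item_id: {
                    "level_labels": list(item.level_labels),
                    "level_points": list(item.level_points),
                }
                for item_id, item in self.items.items()
            },
            "category_thresholds": [list(b) for b in self.category_thresholds],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScoringScheme":
        try:
            items = {
                item_id: ItemDefinition(
                    item_id=item_id,
                    level_labels=tuple(spec["level_labels"]),
                    level_points=tuple(int(p) for p in spec["level_points"]),
                )
                for item_id, spec in d["items"].items()
            }
            bins = tuple(
                (str(label), int(lo), int(hi)) for label, lo, hi in d["category_thresholds"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"malformed scheme definition: {exc}") from exc
        return cls(items=items, category_thresholds=bins)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoringScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoringScheme":
        """The shipped default scheme (uniform 0–3 points, bins 0–5/6–10/11–15/16–24)."""
        ref = importlib.resources.files("icrkit.data").joinpath("default_scheme.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass
class PatientRecord:
    """One child's questionnaire responses plus optional Cariogram input.

    ``item_levels`` maps item id to a level index 0..3 (0 = lowest risk);
    ``cariogram_chance`` is the externally computed "chance of avoiding
    caries" percentage, when available.
    """

    patient_id: str
    age_years: Optional[float] = None
    sex: Optional[str] = None
    item_levels: dict[str, int] = field(default_factory=dict)
    cariogram_chance: Optional[float] = None

    def __post_init__(self):
        for item_id, level in self.item_levels.items():
            if item_id not in ITEM_IDS:
                raise ValidationError(
                    f"record {self.patient_id!r}: unknown item {item_id!r}"
                )
            if level not in (0, 1, 2, 3):
                raise ValidationError(
                    f"record {self.patient_id!r}: item {item_id!r} level {level!r} "
                    f"not in 0..3"
                )
        if self.cariogram_chance is not None and not (0 <= self.cariogram_chance <= 100):
            raise RangeError(
                f"record {self.patient_id!r}: cariogram_chance "
                f"{self.cariogram_chance!r} outside [0, 100]"
            )


@dataclass(frozen=True)
class ICRResult:
    """Total ICR score and assigned risk category for one record."""

    patient_id: str
    total_score: int
    category: str


def score_item(item: ItemDefinition, level_index: int) -> int:
    """Points awarded by ``item`` at the given level index (0..3)."""
    if level_index not in (0, 1, 2, 3):
        raise ValidationError(
            f"item {item.item_id!r}: level index {level_index!r} not in 0..3"
        )
    return item.level_points[level_index]


def categorize_icr(total_score: int, scheme: Optional[ScoringScheme] = None) -> str:
    """Risk category label for a total score under the scheme's bins."""
    scheme = scheme or ScoringScheme.default()
    if not (0 <= total_score <= scheme.max_score):
        raise RangeError(
            f"total score {total_score!r} outside [0, {scheme.max_score}]"
        )
    for label, lo, hi in scheme.category_thresholds:
        if lo <= total_score <= hi:
            return label
    raise RangeError(f"no category bin contains score {total_score!r}")  # pragma: no cover


def compute_icr(record: PatientRecord, scheme: Optional[ScoringScheme] = None) -> ICRResult:
    """Score one record: sum of the eight item points, then bin.

    A record missing any item is rejected — the instrument scores complete
    questionnaires only; nothing is imputed.
    """
    scheme = scheme or ScoringScheme.default()
    missing = [i for i in ITEM_IDS if i not in record.item_levels]
    if missing:
        raise MissingItemError(record.patient_id, missing)
    total = sum(
        score_item(scheme.items[i], record.item_levels[i]) for i in ITEM_IDS
    )
    return ICRResult(
        patient_id=record.patient_id,
        total_score=total,
        category=categorize_icr(total, scheme),
    )


# ---------------------------------------------------------------------------
# Raw-measurement → level mapping
# ---------------------------------------------------------------------------

#: Parent caries-status codes, in increasing severity.
PARENT_STATUS_ORDER = ("-", "+", "++")


@dataclass(frozen=True)
class MeasurementRules:
    """Configurable bin edges mapping raw measurements to item levels.

    Defaults: sugar exposures/day ≤1, ≤3, ≤5, else; meals/day ≤3, ≤5, ≤7,
    else; caries-experience total count 0, ≤2, ≤4, else; pH >7 (outside a
    ±``ph_neutral_tol`` band around 7) → level 0, within the band → level 1
    (neutral), ``[ph_acidic_lo, 7 − tol)`` → level 2, below
    ``ph_acidic_lo`` → level 3.
    """

    sugar_exposure_edges: tuple[float, float, float] = (1.0, 3.0, 5.0)
    meals_per_day_edges: tuple[float, float, float] = (3.0, 5.0, 7.0)
    caries_count_edges: tuple[int, int] = (2, 4)
    ph_neutral_tol: float = 0.25
    ph_acidic_lo: float = 5.5


DEFAULT_RULES = MeasurementRules()

#: Raw-measurement keys understood per item (besides a pre-coded level
#: under the item's own id).
RAW_KEYS: dict[str, tuple[str, ...]] = {
    "diet_content": ("sugar_exposures_per_day",),
    "diet_frequency": ("meals_per_day",),
    "family_susceptibility": ("mother_status", "father_status"),
    "caries_experience": (
        "caries_count",
        "restorations_count",
        "missing_teeth_count",
    ),
    "ph_test": ("ph_value",),
}


def _bin3(value: float, edges: tuple[float, ...]) -> int:
    for level, edge in enumerate(edges):
        if value <= edge:
            return level
    return len(edges)


def _map_family(mother: str, father: str) -> int:
    """Level from the unordered parent status pair, ordered by severity.

    Listed patterns are (−,−)→0, (+,−)→1, (++,+/−)→2, (++,++)→3; an
    unlisted pair (e.g. +,+) maps to the highest listed pattern it
    dominates.
    """
    try:
        a, b = sorted(
            (PARENT_STATUS_ORDER.index(mother), PARENT_STATUS_ORDER.index(father)),
            reverse=True,
        )
    except ValueError:
        raise ValidationError(
            f"parent status must be one of {PARENT_STATUS_ORDER}, "
            f"got mother={mother!r}, father={father!r}"
        ) from None
    if a == 0:
        return 0
    if a == 1:
        return 1
    return 3 if b == 2 else 2


def _map_ph(ph: float, rules: MeasurementRules) -> int:
    if not (0 <= ph <= 14):
        raise RangeError(f"pH value {ph!r} outside 0–14")
    lo, hi = 7.0 - rules.ph_neutral_tol, 7.0 + rules.ph_neutral_tol
    if ph > hi:
        return 0
    if ph >= lo:
        return 1
    if ph >= rules.ph_acidic_lo:
        return 2
    return 3


def map_measurements_to_levels(
    raw: Mapping[str, Any],
    rules: MeasurementRules = DEFAULT_RULES,
) -> dict[str, int]:
    """Build a complete ``item_levels`` map from pre-coded levels and/or
    raw measurements.

    For each of the eight items, ``raw`` must carry either a pre-coded
    level under the item id, or the raw measurement keys of
    :data:`RAW_KEYS`. Pre-coded levels pass through unchanged; raw values
    are binned by ``rules``. Items observed only clinically
    (hygiene_habits, fluoride_program, oral_hygiene_status) accept
    pre-coded levels only.
    """
    levels: dict[str, int] = {}
    missing: list[str] = []
    for item_id in ITEM_IDS:
        if item_id in raw and raw[item_id] is not None:
            level = raw[item_id]
            if level not in (0, 1, 2, 3):
                raise ValidationError(
                    f"pre-coded level for {item_id!r} must be 0..3, got {level!r}"
                )
            levels[item_id] = int(level)
            continue
        keys = RAW_KEYS.get(item_id, ())
        if not keys or not all(k in raw and raw[k] is not None for k in keys):
            missing.append(item_id)
            continue
        if item_id == "diet_content":
            x = float(raw["sugar_exposures_per_day"])
            if x < 0:
                raise RangeError(f"sugar exposures per day cannot be negative ({x})")
            levels[item_id] = _bin3(x, rules.sugar_exposure_edges)
        elif item_id == "diet_frequency":
            x = float(raw["meals_per_day"])
            if x < 0:
                raise RangeError(f"meals per day cannot be negative ({x})")
            levels[item_id] = _bin3(x, rules.meals_per_day_edges)
        elif item_id == "family_susceptibility":
            levels[item_id] = _map_family(raw["mother_status"], raw["father_status"])
        elif item_id == "caries_experience":
            counts = [int(raw[k]) for k in keys]
            if any(c < 0 for c in counts):
                raise RangeError(f"caries-experience counts cannot be negative ({counts})")
            total = sum(counts)
            # 0 → 0; 1–2 → 1; 3–4 → 2; ≥5 → 3 under the default edges
            if total == 0:
                levels[item_id] = 0
            elif total <= rules.caries_count_edges[0]:
                levels[item_id] = 1
            elif total <= rules.caries_count_edges[1]:
                levels[item_id] = 2
            else:
                levels[item_id] = 3
        elif item_id == "ph_test":
            levels[item_id] = _map_ph(float(raw["ph_value"]), rules)
    if missing:
        raise ValidationError(
            "no pre-coded level or usable raw measurement for item(s): "
            + ", ".join(missing)
        )
    return levels
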