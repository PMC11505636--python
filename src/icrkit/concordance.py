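"""Concordance statistics for comparing two caries-risk instruments.

Covers the descriptive and agreement analyses of a method-comparison
study: sample descriptives, rounded frequency tables, the joint
cross-tabulation of the two instruments' categories, Pearson correlation
with a Fisher-z confidence interval, Cohen's kappa (unweighted, linear,
quadratic), and the Fisher-z sample-size calculation for detecting a
non-zero correlation.

Standard statistics are delegated: Pearson to :func:`scipy.stats.pearsonr`,
kappa to :func:`statsmodels.stats.inter_rater.cohens_kappa`, contingency
counting to :func:`pandas.crosstab`. Percent rounding is half-away-from-
zero, the convention used by most clinical tables (Python's built-in
``round`` is banker's rounding and differs at exact halves).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .cariogram import CariogramAssessment
from .errors import RangeError, ValidationError
from .instrument import ICRResult

__all__ = [
    "DescriptiveSummary",
    "FrequencyTable",
    "CrossTab",
    "CorrelationResult",
    "AgreementResult",
    "PowerSpec",
    "ComparisonReport",
    "describe",
    "round_half_away",
    "frequency_table",
    "cross_tabulate",
    "pearson",
    "cohens_kappa",
    "collapse_categories",
    "sample_size_for_correlation",
    "compare_cohort",
]


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveSummary:
    """n, mean (M), sample SD, min and max of one variable.

    ``degenerate`` flags a single-observation sample, whose SD is
    reported as 0 by convention rather than left undefined.
    """

    n: int
    mean: float
    sd: float
    min: float
    max: float
    degenerate: bool = False


def describe(values: Sequence[float]) -> DescriptiveSummary:
    """Sample mean, SD (n−1 denominator), min and max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot describe an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("sample contains non-finite values")
    degenerate = arr.size == 1
    sd = 0.0 if degenerate else float(np.std(arr, ddof=1))
    return DescriptiveSummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (15.5 → 16, −15.5 → −16)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class FrequencyTable:
    """Ordered (label, count, percent) rows over a fixed label set."""

    rows: tuple[tuple[str, int, float], ...]
    total: int
    percent_decimals: int

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rows)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(r[1] for r in self.rows)

    @property
    def percents(self) -> tuple[float, ...]:
        return tuple(r[2] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "n", "percent"])


def frequency_table(
    labels: Sequence[str],
    label_order: Sequence[str],
    decimals: int = 0,
    total: Optional[int] = None,
) -> FrequencyTable:
    """Counts and rounded percents of ``labels`` over ``label_order``.

    ``total`` defaults to ``len(labels)``; passing it explicitly allows
    re-deriving printed percentages directly from printed counts.
    """
    order = list(label_order)
    if len(set(order)) != len(order):
        raise ValidationError("label_order contains duplicates")
    unknown = sorted(set(labels) - set(order))
    if unknown:
        raise ValidationError(f"labels outside the label set: {unknown}")
    counts = {lab: 0 for lab in order}
    for lab in labels:
        counts[lab] += 1
    n_total = len(labels) if total is None else int(total)
    if n_total <= 0:
        raise ValidationError("total must be positive")
    if sum(counts.values()) != n_total:
        raise ValidationError(
            f"counts sum to {sum(counts.values())} but total is {n_total}"
        )
    rows = tuple(
        (lab, counts[lab], round_half_away(100.0 * counts[lab] / n_total, decimals))
        for lab in order
    )
    return FrequencyTable(rows=rows, total=n_total, percent_decimals=decimals)


def frequency_table_from_counts(
    counts: Sequence[int],
    label_order: Sequence[str],
    decimals: int = 0,
) -> FrequencyTable:
    """Frequency table from per-label counts (e.g. a printed table)."""
    if len(counts) != len(label_order):
        raise ValidationError("counts and label_order lengths differ")
    labels: list[str] = []
    for lab, c in zip(label_order, counts):
        if c < 0:
            raise ValidationError("counts must be non-negative")
        labels.extend([lab] * int(c))
    return frequency_table(labels, label_order, decimals=decimals)


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossTab:
    """Joint category counts of two instruments with marginal accessors."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=int)
        if cells.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("cell matrix shape does not match labels")
        if (cells < 0).any():
            raise ValidationError("cell counts must be non-negative")
        object.__setattr__(self, "cells", cells)

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.cells.sum(axis=1))

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.cells.sum(axis=0))

    @property
    def grand_total(self) -> int:
        return int(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=list(self.row_labels), columns=list(self.col_labels)
        )


def cross_tabulate(
    pairs: Sequence[tuple[str, str]],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> CrossTab:
    """Cross-tabulate paired category labels; empty cells count 0."""
    row_labels = tuple(row_labels)
    col_labels = tuple(col_labels)
    rows = [p[0] for p in pairs]
    cols = [p[1] for p in pairs]
    bad_r = sorted(set(rows) - set(row_labels))
    bad_c = sorted(set(cols) - set(col_labels))
    if bad_r or bad_c:
        raise ValidationError(
            f"labels outside the instruments' sets (rows: {bad_r}, cols: {bad_c})"
        )
    r = pd.Categorical(rows, categories=row_labels)
    c = pd.Categorical(cols, categories=col_labels)
    table = pd.crosstab(r, c, dropna=False).reindex(
        index=row_labels, columns=col_labels, fill_value=0
    )
    return CrossTab(row_labels=row_labels, col_labels=col_labels, cells=table.to_numpy())


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with exact p-value and Fisher-z confidence interval."""

    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def pearson(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> CorrelationResult:
    """Product-moment correlation with t-test p and Fisher-z CI."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if not (0 < confidence < 1):
        raise ValidationError("confidence must lie in (0, 1)")
    for name, arr in (("x", xa), ("y", ya)):
        if np.ptp(arr) == 0:
            raise ValidationError(f"variable {name!r} is constant; correlation undefined")
    res = stats.pearsonr(xa, ya)
    ci = res.confidence_interval(confidence_level=confidence)
    return CorrelationResult(
        r=float(res.statistic),
        n=int(xa.size),
        p_value=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with a confidence interval."""

    kappa: float
    ci_low: float
    ci_high: float
    weighting: str
    n: int
    se: float
    confidence: float = 0.95


_WT_MAP = {"none": None, "linear": "ca", "quadratic": "fc"}


def collapse_categories(
    ratings: Sequence[str], mapping: dict[str, str]
) -> list[str]:
    """Map each rating through an explicit category-collapsing map."""
    missing = sorted({r for r in ratings if r not in mapping})
    if missing:
        raise ValidationError(f"collapsing map lacks entries for: {missing}")
    return [mapping[r] for r in ratings]


def cohens_kappa(
    ratings_a: Sequence[str],
    ratings_b: Sequence[str],
    labels: Sequence[str],
    weighting: str = "none",
    confidence: float = 0.95,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Chance-corrected agreement between two raters on a shared label set.

    ``labels`` is the ordered shared label set both raters must use;
    ratings outside it are rejected (comparing instruments with different
    category sets requires an explicit :func:`collapse_categories` map
    first — none is applied silently). ``weighting`` is ``"none"``,
    ``"linear"`` or ``"quadratic"`` (disagreement weights on the ordered
    labels). The CI is the asymptotic (delta-method) interval by default;
    ``bootstrap=True`` selects a seeded percentile bootstrap instead.
    """
    if weighting not in _WT_MAP:
        raise ValidationError(f"weighting must be one of {sorted(_WT_MAP)}")
    if len(ratings_a) != len(ratings_b):
        raise ValidationError("rating sequences have different lengths")
    if len(ratings_a) < 2:
        raise ValidationError("need at least 2 paired ratings")
    labels = tuple(labels)
    bad = sorted((set(ratings_a) | set(ratings_b)) - set(labels))
    if bad:
        raise ValidationError(
            f"ratings outside the shared label set {labels}: {bad}; "
            "collapse categories explicitly before computing kappa"
        )

    def _table(a: Sequence[str], b: Sequence[str]) -> np.ndarray:
        idx = {lab: i for i, lab in enumerate(labels)}
        t = np.zeros((len(labels), len(labels)), dtype=float)
        for ra, rb in zip(a, b):
            t[idx[ra], idx[rb]] += 1
        return t

    res = _sm_cohens_kappa(_table(ratings_a, ratings_b), wt=_WT_MAP[weighting])
    kappa = float(res.kappa)
    se = float(res.std_kappa)
    z = stats.norm.ppf(0.5 + confidence / 2)
    if bootstrap:
        rng = np.random.default_rng(seed)
        n = len(ratings_a)
        a = np.asarray(ratings_a, dtype=object)
        b = np.asarray(ratings_b, dtype=object)
        boots = []
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            kb = _sm_cohens_kappa(_table(a[take], b[take]), wt=_WT_MAP[weighting],
                                  return_results=True).kappa
            boots.append(kb)
        lo, hi = np.quantile(boots, [(1 - confidence) / 2, 0.5 + confidence / 2])
        ci_low, ci_high = float(lo), float(hi)
    else:
        ci_low, ci_high = kappa - z * se, kappa + z * se
    return AgreementResult(
        kappa=kappa,
        ci_low=min(ci_low, kappa),
        ci_high=max(ci_high, kappa),
        weighting=weighting,
        n=len(ratings_a),
        se=se,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Sample size for detecting a correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the correlation sample-size calculation."""

    alpha: float = 0.05
    power: float = 0.80
    target_r: float = 0.7

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise RangeError(f"alpha {self.alpha!r} outside (0, 1)")
        if not (0 < self.power < 1):
            raise RangeError(f"power {self.power!r} outside (0, 1)")
        if not (0 < abs(self.target_r) < 1):
            raise RangeError(f"target_r {self.target_r!r} must satisfy 0 < |r| < 1")


def _fisher_power(n: int, r: float, alpha: float) -> float:
    """Approximate power of the two-sided zero-correlation test at size n.

    Fisher-z approximation with the finite-sample mean correction
    E[z] ≈ atanh(r) + r / (2(n−1)); without the correction the
    approximation is conservative by about one subject.
    """
    z_a = stats.norm.ppf(1 - alpha / 2)
    mu = math.atanh(abs(r)) + abs(r) / (2 * (n - 1))
    return float(stats.norm.cdf(math.sqrt(n - 3) * mu - z_a))


def sample_size_for_correlation(spec: PowerSpec) -> int:
    """Smallest n giving the requested power to detect ``target_r``.

    Uses the Fisher-z approximation (with mean correction); at the
    classic design α=0.05, power 0.80, r=0.7 this yields n=13.
    """
    n = 4
    while _fisher_power(n, spec.target_r, spec.alpha) < spec.power:
        n += 1
        if n > 10_000_000:  # pragma: no cover - unreachable for valid specs
            raise RangeError("sample size search did not converge")
    return n


# ---------------------------------------------------------------------------
# Whole-cohort comparison bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    """All §-style comparison outputs for one cohort."""

    n: int
    icr_summary: DescriptiveSummary
    cariogram_summary: DescriptiveSummary
    icr_table: FrequencyTable
    cariogram_table: FrequencyTable
    crosstab: CrossTab
    correlation: CorrelationResult
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icr": {
                "mean": self.icr_summary.mean,
                "sd": self.icr_summary.sd,
                "min": self.icr_summary.min,
                "max": self.icr_summary.max,
                "categories": [list(r) for r in self.icr_table.rows],
            },
            "cariogram_risk": {
                "mean": self.cariogram_summary.mean,
                "sd": self.cariogram_summary.sd,
                "min": self.cariogram_summary.min,
                "max": self.cariogram_summary.max,
                "categories": [list(r) for r in self.cariogram_table.rows],
            },
            "crosstab": {
                "row_labels": list(self.crosstab.row_labels),
                "col_labels": list(self.crosstab.col_labels),
                "cells": self.crosstab.cells.tolist(),
                "row_totals": list(self.crosstab.row_totals),
                "col_totals": list(self.crosstab.col_totals),
                "grand_total": self.crosstab.grand_total,
            },
            "correlation": {
                "r": self.correlation.r,
                "n": self.correlation.n,
                "p_value": self.correlation.p_value,
                "ci_low": self.correlation.ci_low,
                "ci_high": self.correlation.ci_high,
                "confidence": self.correlation.confidence,
            },
            "excluded": list(self.excluded),
        }


def compare_cohort(
    scored: Sequence[ICRResult],
    assessments: Sequence[CariogramAssessment],
    icr_categories: Sequence[str],
    cariogram_categories: Sequence[str],
    confidence: float = 0.95,
    percent_decimals: int = 0,
    allow_missing: bool = False,
) -> ComparisonReport:
    """Compare ICR scores with Cariogram assessments patient by patient.

    Records present in only one of the two inputs are an error unless
    ``allow_missing`` is set, in which case they are excluded and listed
    in the report. Correlation is computed between the ICR total score
    and the Cariogram *risk* value (the complement scale).
    """
    by_id_icr = {r.patient_id: r for r in scored}
    by_id_car = {a.patient_id: a for a in assessments}
    if len(by_id_icr) != len(scored) or len(by_id_car) != len(assessments):
        raise ValidationError("duplicate patient_id in inputs")
    common = [pid for pid in by_id_icr if pid in by_id_car]
    missing = sorted(set(by_id_icr) ^ set(by_id_car))
    if missing and not allow_missing:
        raise ValidationError(
            f"records missing one instrument: {missing}; pass allow_missing=True "
            "to exclude them explicitly"
        )
    if len(common) < 3:
        raise ValidationError("need at least 3 records with both instruments")

    totals = [by_id_icr[p].total_score for p in common]
    risks = [by_id_car[p].risk_value for p in common]
    report = ComparisonReport(
        n=len(common),
        icr_summary=describe(totals),
        cariogram_summary=describe(risks),
        icr_table=frequency_table(
            [by_id_icr[p].category for p in common], icr_categories,
            decimals=percent_decimals,
        ),
        cariogram_table=frequency_table(
            [by_id_car[p].category for p in common], cariogram_categories,
            decimals=percent_decimals,
        ),
        crosstab=cross_tabulate(
            [(by_id_icr[p].category, by_id_car[p].category) for p in common],
            icr_categories,
            cariogram_categories,
        ),
        correlation=pearson(totals, risks, confidence=confidence),
        excluded=tuple(missing),
    )
    return report
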