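"""Concordance statistics: descriptives, tables, r, kappa, sample size."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icrkit import (
    CARIOGRAM_CATEGORIES,
    ICR_CATEGORIES,
    PowerSpec,
    RangeError,
    ValidationError,
    assess,
    cohens_kappa,
    collapse_categories,
    compare_cohort,
    cross_tabulate,
    describe,
    frequency_table,
    frequency_table_from_counts,
    pearson,
    sample_size_for_correlation,
)
from icrkit.concordance import round_half_away
from icrkit.instrument import ICRResult

# Published one-way category counts over 55 children and the merged
# cross-tabulation cells they must reconcile with.
CARIOGRAM_COUNTS = {"High": 19, "Moderate": 21, "Low": 15}
ICR_COUNTS = {"Very High": 7, "High": 12, "Moderate": 28, "Low": 8}
MERGED_CELLS = {  # (icr_category, cariogram_category) -> count
    ("Low", "Low"): 8,
    ("Moderate", "Low"): 7,
    ("Moderate", "Moderate"): 18,
    ("Moderate", "High"): 3,
    ("High", "Moderate"): 3,
    ("High", "High"): 9,
    ("Very High", "High"): 7,
}


class TestDescribe:
    def test_constant_sample(self):
        s = describe([5, 5, 5])
        assert (s.mean, s.sd, s.min, s.max, s.n) == (5, 0, 5, 5, 3)

    def test_hand_computed_sd(self):
        s = describe([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sd == pytest.approx(math.sqrt(5 / 3), abs=1e-12)

    def test_single_value_flagged_degenerate(self):
        s = describe([7])
        assert s.degenerate and s.sd == 0 and s.mean == 7

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            describe([])


class TestFrequencyTable:
    def test_cariogram_counts_round_as_printed(self):
        ft = frequency_table_from_counts([19, 21, 15], ["High", "Moderate", "Low"])
        assert ft.percents == (35, 38, 27)
        assert ft.total == 55

    def test_icr_counts_round_as_printed(self):
        ft = frequency_table_from_counts([7, 12, 28, 8], ["VH", "H", "M", "L"])
        assert ft.percents == (13, 22, 51, 15)

    def test_mass_on_one_label(self):
        ft = frequency_table_from_counts([0, 0, 55], ["a", "b", "c"])
        assert ft.percents == (0, 0, 100)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(14.545, 0) == 15
        assert round_half_away(34.545, 1) == 34.5
        assert round_half_away(2.5, 0) == 3  # banker's rounding would give 2
        assert round_half_away(-2.5, 0) == -3

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            frequency_table(["a", "z"], ["a", "b"])

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 200), min_size=2, max_size=5),
        decimals=st.integers(0, 2),
    )
    def test_percent_error_below_half_last_decimal(self, counts, decimals):
        if sum(counts) == 0:
            counts[0] = 1
        labels = [f"c{i}" for i in range(len(counts))]
        ft = frequency_table_from_counts(counts, labels, decimals=decimals)
        for (_, n, pct) in ft.rows:
            exact = 100 * n / ft.total
            assert abs(pct - exact) <= 0.5 * 10 ** (-decimals) + 1e-9


class TestCrossTab:
    def test_merged_table_marginals_reconcile(self):
        pairs = [
            pair for pair, count in MERGED_CELLS.items() for _ in range(count)
        ]
        ct = cross_tabulate(pairs, list(ICR_COUNTS), CARIOGRAM_CATEGORIES)
        assert ct.grand_total == 55
        assert dict(zip(ct.row_labels, ct.row_totals)) == ICR_COUNTS
        assert dict(zip(ct.col_labels, ct.col_totals)) == {
            "Low": 15, "Moderate": 21, "High": 19,
        }

    def test_identical_pairs_fill_single_cell(self):
        ct = cross_tabulate([("a", "x")] * 9, ["a", "b"], ["x", "y"])
        assert ct.cells[0, 0] == 9 and ct.cells.sum() == 9

    def test_matches_dictionary_counting_oracle(self):
        rng = np.random.default_rng(11)
        rows = ["a", "b", "c"]
        cols = ["x", "y"]
        pairs = [
            (rows[rng.integers(3)], cols[rng.integers(2)]) for _ in range(200)
        ]
        ct = cross_tabulate(pairs, rows, cols)
        oracle = Counter(pairs)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                assert ct.cells[i, j] == oracle[(r, c)]

    def test_label_outside_sets_rejected(self):
        with pytest.raises(ValidationError):
            cross_tabulate([("a", "z")], ["a"], ["x"])


class TestPearson:
    def test_perfect_positive_affine(self):
        x = [1, 2, 3, 5, 8]
        res = pearson(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 4.0]
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        assert res.ci_low < 0.8 < res.ci_high
        # two-sided p from t = r sqrt(n-2)/sqrt(1-r^2) with 3 df
        t = 0.8 * math.sqrt(3) / math.sqrt(1 - 0.64)
        assert res.p_value == pytest.approx(2 * stats.t.sf(t, df=3), rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r_xy = pearson(x, y).r
        assert pearson(y, x).r == pytest.approx(r_xy)
        assert pearson(a * x + b, y).r == pytest.approx(r_xy)
        assert pearson(-a * x + b, y).r == pytest.approx(-r_xy)

    def test_constant_variable_named_in_error(self):
        with pytest.raises(ValidationError, match="'y'"):
            pearson([1, 2, 3], [4, 4, 4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 2, 3], [1, 2])


class TestKappa:
    def test_perfect_agreement(self):
        a = ["x", "y", "z"] * 5
        res = cohens_kappa(a, list(a), ["x", "y", "z"])
        assert res.kappa == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # table (20,5;10,15): p_o = 0.7, p_e = 0.5 -> kappa 0.4
        a = ["+"] * 25 + ["-"] * 25
        b = ["+"] * 20 + ["-"] * 5 + ["+"] * 10 + ["-"] * 15
        res = cohens_kappa(a, b, ["+", "-"])
        assert res.kappa == pytest.approx(0.4)
        assert res.ci_low <= 0.4 <= res.ci_high

    def test_independent_product_table_gives_zero(self):
        # joint counts = product of margins -> p_o == p_e exactly
        a, b = [], []
        for i, ca in enumerate(["x", "y"]):
            for j, cb in enumerate(["x", "y"]):
                n = [[9, 6], [3, 2]][i][j]  # margins (15, 5) x (12, 8) / 20
                a += [ca] * n
                b += [cb] * n
        assert cohens_kappa(a, b, ["x", "y"]).kappa == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_weights_on_two_levels_equal_unweighted(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["x", "y"], size=60).tolist()
        b = rng.choice(["x", "y"], size=60).tolist()
        plain = cohens_kappa(a, b, ["x", "y"]).kappa
        quad = cohens_kappa(a, b, ["x", "y"], weighting="quadratic").kappa
        assert quad == pytest.approx(plain, abs=1e-12)

    def test_adjacent_disagreements_penalized_less_under_weights(self):
        # every disagreement is one ordinal step, so partial credit raises kappa
        a = ["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10
        b = ["lo"] * 8 + ["mid"] * 2 + ["mid"] * 8 + ["hi"] * 2 + ["hi"] * 10
        labels = ["lo", "mid", "hi"]
        plain = cohens_kappa(a, b, labels).kappa
        lin = cohens_kappa(a, b, labels, weighting="linear").kappa
        quad = cohens_kappa(a, b, labels, weighting="quadratic").kappa
        assert plain < lin < quad < 1

    def test_mismatched_label_sets_require_explicit_collapse(self):
        icr = ["Very High", "High", "Moderate"]
        cario = ["High", "High", "Moderate"]
        with pytest.raises(ValidationError, match="collapse"):
            cohens_kappa(icr, cario, CARIOGRAM_CATEGORIES)
        merged = collapse_categories(icr, {**{c: c for c in CARIOGRAM_CATEGORIES},
                                           "Very High": "High"})
        res = cohens_kappa(merged, cario, CARIOGRAM_CATEGORIES)
        assert res.kappa <= 1

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["x", "y", "z"], size=40).tolist()
        b = [v if rng.random() < 0.7 else "x" for v in a]
        r1 = cohens_kappa(a, b, ["x", "y", "z"], bootstrap=True, n_boot=200, seed=1)
        r2 = cohens_kappa(a, b, ["x", "y", "z"], bootstrap=True, n_boot=200, seed=1)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.kappa <= r1.ci_high


def _mc_power(n: int, rho: float, reps: int, seed: int, alpha: float = 0.05) -> float:
    """Monte-Carlo power of the two-sided Pearson test at sample size n."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n))
    y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return float(np.mean(p < alpha))


class TestSampleSize:
    @pytest.mark.parametrize("r, expected", [(0.7, 13), (0.5, 29)])
    def test_classic_designs(self, r, expected):
        assert sample_size_for_correlation(PowerSpec(0.05, 0.80, r)) == expected

    def test_nonincreasing_in_target_r(self):
        sizes = [
            sample_size_for_correlation(PowerSpec(0.05, 0.80, r))
            for r in (0.2, 0.3, 0.5, 0.7, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.7])
    def test_agrees_with_monte_carlo_within_one_subject(self, rho):
        n_closed = sample_size_for_correlation(PowerSpec(0.05, 0.80, rho))
        # smallest n whose Monte-Carlo power reaches 0.80
        n_mc = None
        for n in range(max(4, n_closed - 2), n_closed + 3):
            if _mc_power(n, rho, reps=20_000, seed=20240925 + n) >= 0.80:
                n_mc = n
                break
        assert n_mc is not None
        assert abs(n_mc - n_closed) <= 1

    @pytest.mark.parametrize("alpha, power, r", [(0, 0.8, 0.5), (0.05, 1.5, 0.5), (0.05, 0.8, 0)])
    def test_degenerate_specs_rejected(self, alpha, power, r):
        with pytest.raises(RangeError):
            PowerSpec(alpha, power, r)


class TestCompareCohort:
    @staticmethod
    def _inputs(totals, chances, categories=None):
        scored = [
            ICRResult(f"p{i}", t, c)
            for i, (t, c) in enumerate(zip(totals, categories or ["Low"] * len(totals)))
        ]
        assessments = [assess(f"p{i}", ch) for i, ch in enumerate(chances)]
        return scored, assessments

    def test_affine_relation_gives_unit_correlation(self):
        totals = [0, 5, 10, 15, 20]
        chances = [100 - 4 * t for t in totals]  # risk = 4 * total
        scored, assessments = self._inputs(totals, chances)
        rep = compare_cohort(scored, assessments, ICR_CATEGORIES, CARIOGRAM_CATEGORIES)
        assert rep.correlation.r == pytest.approx(1.0)

    def test_three_record_hand_computed_bundle(self):
        # totals (4, 9, 14) -> Low/Moderate/High; chances (80, 50, 20)
        scored, assessments = self._inputs(
            [4, 9, 14], [80, 50, 20], ["Low", "Moderate", "High"]
        )
        rep = compare_cohort(scored, assessments, ICR_CATEGORIES, CARIOGRAM_CATEGORIES)
        assert rep.n == 3
        assert rep.icr_summary.mean == pytest.approx(9)
        assert rep.icr_summary.sd == pytest.approx(5)
        assert rep.cariogram_summary.mean == pytest.approx(50)  # risks 20, 50, 80
        assert rep.cariogram_summary.sd == pytest.approx(30)
        assert rep.correlation.r == pytest.approx(1.0)  # both exactly affine in rank
        assert rep.crosstab.grand_total == 3
        # diagonal pairing: Low/Low, Moderate/Moderate, High/High
        assert np.trace(rep.crosstab.cells[:3, :]) == 3

    def test_missing_instrument_listed_unless_allowed(self):
        scored, assessments = self._inputs([4, 9, 14, 7], [80, 50, 20, 60])
        orphan = scored + [ICRResult("extra", 3, "Low")]
        with pytest.raises(ValidationError, match="extra"):
            compare_cohort(orphan, assessments, ICR_CATEGORIES, CARIOGRAM_CATEGORIES)
        rep = compare_cohort(
            orphan, assessments, ICR_CATEGORIES, CARIOGRAM_CATEGORIES,
            allow_missing=True,
        )
        assert rep.excluded == ("extra",)
        assert rep.n == 4
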