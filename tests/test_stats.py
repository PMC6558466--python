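import math

import numpy as np
import pytest

from grskit import (
    AnalysisError,
    GRSVector,
    build_risk_table,
    categorize_risk,
    mean_grs_summary,
    odds_ratio_ci,
    risk_table_from_counts,
    tally_multi_cancer,
    trend_test,
    wilcoxon_rank_sum,
)
from grskit.stats import RiskCategories


def _grs(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"{prefix}{i}" for i in range(values.size))
    return GRSVector(ids, values, np.ones(values.size, dtype=int))


class TestCategorize:
    def test_cutpoint_boundaries_fall_in_average(self):
        cats = categorize_risk(_grs([0.49, 0.50, 1.50, 1.51, 1.0]))
        assert cats.categories == ("low", "average", "average", "high", "average")

    def test_all_average_for_unit_scores(self):
        cats = categorize_risk(_grs([1.0] * 4))
        assert set(cats.categories) == {"average"}

    def test_partition_every_subject_once(self, rng):
        cats = categorize_risk(_grs(rng.lognormal(0, 0.6, 500)))
        assert len(cats) == 500
        assert sum(cats.counts().values()) == 500

    def test_bad_cutpoints_rejected(self):
        with pytest.raises(AnalysisError):
            categorize_risk(_grs([1.0, 1.0]), 1.5, 0.5)


class TestOddsRatio:
    def test_identical_strata_give_unity(self):
        res = odds_ratio_ci(10, 100, 10, 100)
        assert res.oddsratio == pytest.approx(1.0)

    def test_cross_product_and_wald_ci(self):
        res = odds_ratio_ci(35, 903, 301, 12245)
        assert res.oddsratio == pytest.approx((35 * 12245) / (903 * 301), rel=1e-12)
        assert round(res.oddsratio, 2) == 1.58
        assert round(res.ci_low, 2) == 1.10
        assert round(res.ci_high, 2) == 2.25

    def test_zero_case_cell(self):
        res = odds_ratio_ci(0, 14, 886, 13044)
        assert res.oddsratio == 0.0
        assert res.ci_low == 0.0
        assert math.isnan(res.ci_high)
        assert res.p_value == pytest.approx(0.33, abs=0.005)

    def test_zero_control_cell(self):
        res = odds_ratio_ci(5, 0, 100, 1000)
        assert math.isinf(res.oddsratio)
        assert math.isnan(res.ci_low)

    def test_haldane_correction_finite(self):
        res = odds_ratio_ci(0, 14, 886, 13044, haldane=True)
        assert 0 < res.oddsratio < 1
        assert math.isfinite(res.ci_high)

    def test_swapping_strata_inverts_or(self):
        a = odds_ratio_ci(35, 903, 301, 12245)
        b = odds_ratio_ci(301, 12245, 35, 903)
        assert b.oddsratio == pytest.approx(1 / a.oddsratio, rel=1e-12)
        assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-9)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(AnalysisError):
            odds_ratio_ci(-1, 10, 10, 10)

    def test_empty_reference_rejected(self):
        with pytest.raises(AnalysisError):
            odds_ratio_ci(5, 5, 0, 10)


class TestTrend:
    def test_flat_proportions_give_zero(self):
        z, p = trend_test([5, 10, 20], [50, 100, 200])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_contingency_row(self):
        # frozen against R prop.trend.test on the same counts
        z, p = trend_test([7, 301, 35], [286, 12546, 938])
        assert z**2 == pytest.approx(4.7716, abs=2e-4)
        assert p == pytest.approx(0.02893, abs=1e-4)
        assert p == pytest.approx(0.02, abs=0.01)

    def test_permutation_null_agreement_on_small_table(self):
        # tables chosen so the permutation distribution has enough support
        # for the asymptotic approximation to land within Monte-Carlo error
        rng = np.random.default_rng(8)
        for cases, totals in [((1, 0, 7), (2, 1, 8)), ((0, 1, 0), (1, 3, 8))]:
            z, p = trend_test(cases, totals)
            labels = np.repeat([0, 1, 2], totals)
            n_case = sum(cases)
            hits = 0
            for _ in range(10000):
                chosen = rng.permutation(labels.size)[:n_case]
                x = np.bincount(labels[chosen], minlength=3)
                zp, _ = trend_test(x, totals)
                if abs(zp) >= abs(z) - 1e-12:
                    hits += 1
            p_perm = hits / 10000
            se = math.sqrt(p_perm * (1 - p_perm) / 10000)
            assert abs(p - p_perm) <= 3 * se

    def test_degenerate_table_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = trend_test([0, 0, 0], [10, 10, 10])
        assert math.isnan(z) and math.isnan(p)

    def test_zero_total_strata_dropped(self):
        z1, p1 = trend_test([5, 0, 20], [50, 0, 200], scores=(0, 1, 2))
        assert math.isfinite(p1)


class TestRiskTable:
    def test_published_row_reproduced(self):
        table = risk_table_from_counts(
            {"low": 7, "average": 301, "high": 35},
            {"low": 279, "average": 12245, "high": 903},
        )
        high = table.stratum("high")
        assert round(high.oddsratio, 2) == 1.58
        assert table.stratum("average").oddsratio == 1.0
        assert table.trend_p == pytest.approx(0.0289, abs=1e-3)

    def test_identical_distributions_give_unit_ors(self):
        counts = {"low": 20, "average": 100, "high": 30}
        table = risk_table_from_counts(counts, counts)
        assert table.stratum("low").oddsratio == pytest.approx(1.0)
        assert table.stratum("high").oddsratio == pytest.approx(1.0)

    def test_counts_match_direct_tabulation(self, rng):
        case_vals = rng.lognormal(0.3, 0.5, 300)
        ctrl_vals = rng.lognormal(0.0, 0.5, 800)
        case_cats = categorize_risk(_grs(case_vals, "case"))
        ctrl_cats = categorize_risk(_grs(ctrl_vals, "ctrl"))
        table = build_risk_table(case_cats, ctrl_cats)
        for cat, low, high in [("low", 0, 0.5), ("average", 0.5, 1.5), ("high", 1.5, np.inf)]:
            expect_cases = int(((case_vals >= low) & (case_vals <= high)).sum()) \
                if cat == "average" else int(((case_vals > low) & (case_vals < high)).sum())
            row = table.stratum(cat)
            assert row.cases == expect_cases
            # cross-check the control side by complementary counting
        assert sum(r.cases for r in table.strata) == 300
        assert sum(r.controls for r in table.strata) == 800

    def test_overlapping_arms_rejected(self):
        cats = categorize_risk(_grs([1.0, 1.0]))
        with pytest.raises(AnalysisError, match="both arms"):
            build_risk_table(cats, cats)

    def test_empty_reference_stratum_fatal(self):
        with pytest.raises(AnalysisError, match="reference"):
            risk_table_from_counts(
                {"low": 5, "average": 0, "high": 5},
                {"low": 50, "average": 100, "high": 50},
            )


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0] * 10, [1.0, 2.0, 3.0] * 10)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        # all C(6,3)=20 rank splits; only 2 are as extreme -> p = 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_large_shift_detected_with_direction(self, rng):
        x = rng.normal(1.0, 0.2, 400)
        y = rng.normal(0.0, 0.2, 400)
        stat, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-10
        assert stat > 400 * 400 / 2  # x stochastically larger

    def test_empty_sample_rejected(self):
        with pytest.raises(AnalysisError):
            wilcoxon_rank_sum([], [1.0])


class TestMeanSummary:
    def test_constant_vector_zero_width(self):
        s = mean_grs_summary(_grs([1.3] * 5), "ctrl")
        assert s.mean == pytest.approx(1.3)
        assert s.ci_low == pytest.approx(s.ci_high)

    def test_hand_computed_four_values(self):
        values = np.array([0.8, 1.0, 1.2, 1.4])
        s = mean_grs_summary(_grs(values), "x")
        half = 1.959963984540054 * values.std(ddof=1) / 2.0
        assert s.mean == pytest.approx(1.1)
        assert s.ci_low == pytest.approx(1.1 - half, rel=1e-9)
        assert s.ci_high == pytest.approx(1.1 + half, rel=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(AnalysisError):
            mean_grs_summary(_grs([1.0]), "x")


class TestMultiCancerTally:
    def _cats(self, assignments, low=0.5, high=1.5):
        ids = tuple(assignments)
        return RiskCategories(ids, tuple(assignments.values()), low, high)

    def test_single_high_subject_counted(self):
        cats = {
            "glioma": self._cats({"a": "high", "b": "average"}),
            "renal": self._cats({"a": "average", "b": "average"}),
        }
        tally = tally_multi_cancer(cats, {"a": "male", "b": "female"})
        assert tally.high_any["overall"] == pytest.approx(0.5)
        assert tally.high_any["male"] == pytest.approx(1.0)
        assert tally.high_any["female"] == pytest.approx(0.0)

    def test_all_average_everywhere_gives_zero(self):
        cats = {"glioma": self._cats({"a": "average", "b": "average"})}
        tally = tally_multi_cancer(cats, {"a": "male", "b": "female"})
        assert tally.extreme_any["overall"] == 0.0

    def test_ten_subject_fixture_manual_count(self):
        # sex-restricted cancers: breast counts only for the 5 females,
        # prostate only for the 5 males
        males = [f"m{i}" for i in range(5)]
        females = [f"f{i}" for i in range(5)]
        sex = {**{s: "male" for s in males}, **{s: "female" for s in females}}
        everyone = males + females
        glioma = {s: "average" for s in everyone}
        glioma["m0"] = "high"
        glioma["f0"] = "low"
        breast = {s: "high" if s == "f1" else "average" for s in everyone}
        prostate = {s: "low" if s == "m1" else "average" for s in everyone}
        cats = {
            "glioma": self._cats(glioma),
            "breast": self._cats(breast),
            "prostate": self._cats(prostate),
        }
        tally = tally_multi_cancer(cats, sex)
        # high>=1: m0 (glioma), f1 (breast) -> 2/10
        assert tally.high_any["overall"] == pytest.approx(0.2)
        # low>=1: f0 (glioma), m1 (prostate) -> 2/10
        assert tally.low_any["overall"] == pytest.approx(0.2)
        assert tally.extreme_any["overall"] == pytest.approx(0.4)
        assert tally.high_any["male"] == pytest.approx(0.2)
        assert tally.high_any["female"] == pytest.approx(0.2)
        # a male high only in breast would not count
        breast_m = dict(breast)
        breast_m["m2"] = "high"
        cats["breast"] = self._cats(breast_m)
        tally2 = tally_multi_cancer(cats, sex)
        assert tally2.high_any["male"] == pytest.approx(0.2)

    def test_unknown_sex_excluded_from_restricted(self):
        cats = {
            "prostate": self._cats({"a": "high", "b": "high"}),
            "glioma": self._cats({"a": "low", "b": "average"}),
        }
        with pytest.warns(UserWarning, match="unknown sex"):
            tally = tally_multi_cancer(cats, {"a": "unknown", "b": "male"})
        # subject a only counts for glioma (low), b counts for both
        assert tally.high_any["overall"] == pytest.approx(0.5)
        assert tally.low_any["overall"] == pytest.approx(0.5)
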