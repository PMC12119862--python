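import math
import random
from datetime import date as Date, timedelta

import numpy as np
import pytest

from rcdrecur.cohort import validation_window
from rcdrecur.metrics import (
    AgreementTable,
    DEFAULT_DEFINITIONS,
    PairClassLabel,
    classify_pair,
    compatibility_summary,
    date_diff_distribution,
    first_event_crosstab,
    km_risk,
    performance,
    within_window_performance,
)
from rcdrecur.model import OutcomeEvent, OutcomeType
from rcdrecur.reference import distant_agreement, initial_training_crosstab

R = Date(2004, 1, 1)  # randomisation
WINDOW = validation_window(R, R + timedelta(days=3650))
DISTANT = DEFAULT_DEFINITIONS["DISTANT_RECURRENCE"]


def ev(days, outcome):
    return OutcomeEvent("P", R + timedelta(days=days), outcome)


class TestClassifyPair:
    def test_event_on_both_sides(self):
        p = classify_pair(
            "P",
            [ev(730, OutcomeType.DISTANT_RECURRENCE)],
            [ev(766, OutcomeType.DISTANT_RECURRENCE)],
            DISTANT,
            WINDOW,
        )
        assert p.label is PairClassLabel.EVENT_BOTH
        assert (p.date_rcd - p.date_gold).days == 36

    def test_event_before_landmark_censors_that_side(self):
        p = classify_pair(
            "P",
            [ev(4 * 365, OutcomeType.DISTANT_RECURRENCE)],
            [],
            DISTANT,
            WINDOW,
            landmark_years=5,
        )
        assert p.label is PairClassLabel.CENSORED_TRIAL_ONLY

    def test_event_exactly_at_landmark_counts_inside(self):
        p = classify_pair(
            "P",
            [ev(5 * 365, OutcomeType.DISTANT_RECURRENCE)],
            [],
            DISTANT,
            WINDOW,
            landmark_years=5,
        )
        assert p.label is PairClassLabel.EVENT_TRIAL_ONLY

    def test_rcd_event_inside_post_visit_window_still_counts(self):
        # RCD event two months after the last visit is inside the 91-day tail
        short = validation_window(R, R + timedelta(days=1000))
        p = classify_pair(
            "P", [], [ev(1060, OutcomeType.DISTANT_RECURRENCE)], DISTANT, short
        )
        assert p.label is PairClassLabel.EVENT_RCD_ONLY

    def test_preceding_ignored_outcome_does_not_block_distant(self):
        p = classify_pair(
            "P",
            [ev(400, OutcomeType.LOCOREGIONAL_RECURRENCE), ev(900, OutcomeType.DISTANT_RECURRENCE)],
            [],
            DISTANT,
            WINDOW,
        )
        assert p.label is PairClassLabel.EVENT_TRIAL_ONLY

    def test_censoring_outcome_blocks_later_event(self):
        p = classify_pair(
            "P",
            [ev(400, OutcomeType.NON_BREAST_MALIGNANCY), ev(900, OutcomeType.DISTANT_RECURRENCE)],
            [],
            DISTANT,
            WINDOW,
        )
        assert p.label is PairClassLabel.NO_EVENT_EITHER


class TestPerformance:
    def test_published_distant_counts_reproduced(self):
        m = performance(distant_agreement("all_time"))
        assert m.sensitivity.round1()[0] == 95.6
        assert m.specificity.round1()[0] == 91.9
        assert m.ppv.round1()[0] == 82.2
        assert m.npv.round1()[0] == 98.2

    def test_wald_ci_pins_the_method(self):
        # 518 detected of 542 with the outcome -> CI must round to (93.8, 97.3)
        m = performance(distant_agreement("all_time"))
        assert m.sensitivity.round1() == (95.6, 93.8, 97.3)

    def test_wald_ci_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(518, 542, alpha=0.05, method="normal")
        m = performance(distant_agreement("all_time"))
        assert m.sensitivity.lower == pytest.approx(100 * lo, abs=1e-9)
        assert m.sensitivity.upper == pytest.approx(100 * hi, abs=1e-9)

    def test_perfect_agreement_scores_100_everywhere(self):
        t = AgreementTable.from_counts(50, 0, 0, 50)
        m = performance(t)
        assert [m.sensitivity.value, m.specificity.value, m.ppv.value, m.npv.value] == [100.0] * 4

    def test_zero_denominator_reported_as_undefined(self):
        t = AgreementTable.from_counts(0, 0, 5, 95)
        assert performance(t).sensitivity.value is None

    def test_random_counts_match_ratio_oracle(self):
        rng = random.Random(7)
        for _ in range(50):
            a, b, c, d = (rng.randint(1, 500) for _ in range(4))
            m = performance(AgreementTable.from_counts(a, b, c, d))
            assert m.sensitivity.value == pytest.approx(100 * a / (a + b))
            assert m.specificity.value == pytest.approx(100 * d / (d + c))
            assert m.ppv.value == pytest.approx(100 * a / (a + c))
            assert m.npv.value == pytest.approx(100 * d / (d + b))


class TestWithinWindowPerformance:
    def test_published_six_month_block_reproduced(self):
        m = within_window_performance(distant_agreement("all_time"))
        assert m.sensitivity.round1()[0] == 70.5
        assert m.specificity.round1()[0] == 91.9
        assert m.ppv.round1()[0] == 77.3
        assert m.npv.round1()[0] == 88.9

    def test_reduces_to_performance_when_all_matches_in_window(self):
        t = AgreementTable.from_counts(40, 5, 7, 100, diffs=[10] * 40)
        assert within_window_performance(t) == performance(t)

    def test_hand_built_toy_recount(self):
        # 10 matched pairs, 3 of them matched late (> 182 days apart)
        t = AgreementTable.from_counts(10, 2, 4, 30, diffs=[0] * 7 + [200, 300, 400])
        m = within_window_performance(t)
        assert m.sensitivity.value == pytest.approx(100 * 7 / 12)
        assert m.specificity.value == pytest.approx(100 * 30 / 34)
        assert m.ppv.value == pytest.approx(100 * 7 / 11)
        assert m.npv.value == pytest.approx(100 * 30 / 35)

    def test_monotone_in_match_window(self):
        rng = random.Random(3)
        for _ in range(20):
            n_both = rng.randint(5, 60)
            diffs = [rng.randint(0, 500) for _ in range(n_both)]
            t = AgreementTable.from_counts(
                n_both, rng.randint(0, 20), rng.randint(0, 20), rng.randint(10, 200), diffs=diffs
            )
            prev_sens = prev_ppv = prev_npv = 101.0
            spec0 = performance(t).specificity.value
            for w in (365, 182, 91, 30):
                m = within_window_performance(t, match_window_days=w)
                assert m.sensitivity.value <= prev_sens
                assert m.ppv.value <= prev_ppv
                assert m.npv.value <= prev_npv
                assert m.specificity.value == spec0
                prev_sens, prev_ppv, prev_npv = (
                    m.sensitivity.value, m.ppv.value, m.npv.value,
                )


class TestDateDiffDistribution:
    def test_published_distant_bins(self):
        # 382/518 = 73.745...; the published table rounds this to 73.8
        bins = date_diff_distribution(distant_agreement("all_time").diffs)
        assert bins.loc["<6 months", "percent"] == pytest.approx(100 * 382 / 518)
        within_12m = bins.loc["<6 months", "percent"] + bins.loc["6-12 months", "percent"]
        assert within_12m == pytest.approx(84.6, abs=0.05)

    def test_all_zero_diffs(self):
        bins = date_diff_distribution([0, 0, 0])
        assert list(bins["percent"]) == [100.0, 0.0, 0.0]

    def test_random_diffs_match_histogram_oracle(self):
        rng = np.random.default_rng(5)
        diffs = rng.integers(-800, 800, size=500)
        bins = date_diff_distribution(diffs)
        a = np.abs(diffs)
        assert bins.loc["<6 months", "count"] == int((a <= 182).sum())
        assert bins.loc["6-12 months", "count"] == int(((a > 182) & (a <= 365)).sum())
        assert bins.loc[">1 year", "count"] == int((a > 365).sum())


class TestFirstEventCrosstab:
    def test_published_compatibility_fractions(self):
        summary = compatibility_summary(initial_training_crosstab())
        assert summary["rcd_missed_pct"] == pytest.approx(1.5, abs=0.05)
        assert summary["locoregional_compatible_pct"] == pytest.approx(93.4, abs=0.05)
        assert summary["distant_compatible_pct"] == pytest.approx(97.9, abs=0.05)
        assert summary["other_same_pct"] == pytest.approx(99.9, abs=0.05)

    def test_identical_assignments_are_diagonal(self):
        rng = random.Random(1)
        assign = {
            f"W{i}": rng.choice(list(OutcomeType) + [None]) for i in range(60)
        }
        tab = first_event_crosstab(assign, assign)
        off_diag = tab.to_numpy().sum() - np.trace(tab.to_numpy())
        assert off_diag == 0
        s = compatibility_summary(tab)
        for key in ("locoregional_compatible_pct", "distant_compatible_pct", "other_same_pct"):
            assert math.isnan(s[key]) or s[key] == 100.0

    def test_random_assignments_match_counting_oracle(self):
        rng = random.Random(9)
        gold = {f"W{i}": rng.choice(list(OutcomeType) + [None]) for i in range(100)}
        rcd = {f"W{i}": rng.choice(list(OutcomeType) + [None]) for i in range(100)}
        tab = first_event_crosstab(gold, rcd)
        assert int(tab.to_numpy().sum()) == 100
        # brute-force tally of one arbitrary cell
        g, r = OutcomeType.DISTANT_RECURRENCE, OutcomeType.LOCOREGIONAL_RECURRENCE
        expected = sum(1 for pid in gold if gold[pid] is g and rcd[pid] is r)
        assert tab.loc[g.value, r.value] == expected

    def test_duplicate_roster_rejected(self):
        with pytest.raises(ValueError):
            first_event_crosstab({"A": None}, {"B": None})


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_cdf(self):
        # 3 events among 10 women before five years, nobody censored early
        durations = [400, 900, 1500] + [4000] * 7
        observed = [True, True, True] + [False] * 7
        curve = km_risk(durations, observed, horizons_years=(5,))
        assert curve.risk_at(5) == pytest.approx(30.0)

    def test_staggered_censoring_matches_hand_worksheet(self):
        # product-limit by hand: S = 7/8 * 5/6 * 3/4 = 0.546875
        durations = [100, 150, 200, 250, 300, 320, 340, 400]
        observed = [True, False, True, False, True, False, False, True]
        curve = km_risk(durations, observed, horizons_years=(340 / 365,))
        assert curve.risk[0] == pytest.approx(100 * (1 - 0.546875))

    def test_risk_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        durations = rng.integers(50, 4000, size=200)
        observed = rng.random(200) < 0.4
        curve = km_risk(durations, observed, horizons_years=(1, 3, 5, 10))
        vals = [r for r in curve.risk if r is not None]
        assert all(0 <= v <= 100 for v in vals)
        assert vals == sorted(vals)

    def test_horizon_beyond_follow_up_is_undefined(self):
        curve = km_risk([100, 200], [True, False], horizons_years=(5,))
        assert curve.risk_at(5) is None

    def test_delayed_entry_restricts_risk_set(self):
        # landmark at day 500: the early event is outside the risk set
        durations = [400, 900, 1500, 4000, 4000]
        observed = [True, True, True, False, False]
        entry = [500] * 5
        with pytest.raises(Exception):
            # entry after an event time is invalid input for delayed entry
            km_risk(durations, observed, horizons_years=(10,), entry_days=entry)
        curve = km_risk(durations[1:], observed[1:], horizons_years=(10,), entry_days=[500] * 4)
        # among 4 at risk after day 500: events at 900 and 1500
        assert curve.risk_at(10) == pytest.approx(100 * (1 - 0.75 * (2 / 3)))
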