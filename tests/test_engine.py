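import itertools
import random
from datetime import timedelta

import pytest

from rcdrecur.engine import (
    CandidateOutcome,
    EngineConfig,
    apply_post_validation_adjustment,
    candidates_from_diagnosis_codes,
    candidates_from_procedures,
    candidates_from_registrations,
    candidates_from_therapy,
    infusion_filter,
    reconstruction_filter,
    resolve_same_date,
    run_algorithm,
)
from rcdrecur.model import (
    DEFAULT_PRIORITY,
    DeathRecord,
    Intent,
    Laterality,
    OutcomeType,
    PriorityOrder,
    Source,
    CodingSystem,
)

from conftest import INDEX_DATE, make_event, make_history, make_registration

CFG = EngineConfig()


def outcomes(cands):
    return [(c.outcome, (c.date - INDEX_DATE).days) for c in cands]


class TestRegistrationCandidates:
    def test_opposite_side_after_three_months_is_contralateral(self):
        h = make_history(
            registrations=[make_registration("T1", day=400, laterality=Laterality.RIGHT)]
        )
        assert outcomes(candidates_from_registrations(h, CFG)) == [
            (OutcomeType.CONTRALATERAL_BREAST_CANCER, 400)
        ]

    def test_opposite_side_within_three_months_is_not_a_candidate(self):
        # synchronous bilateral disease is an upstream exclusion
        h = make_history(
            registrations=[make_registration("T1", day=60, laterality=Laterality.RIGHT)]
        )
        assert candidates_from_registrations(h, CFG) == []

    def test_lung_primary_is_non_breast_malignancy(self):
        h = make_history(
            registrations=[make_registration("T1", day=800, site_code="C34.1")]
        )
        assert outcomes(candidates_from_registrations(h, CFG)) == [
            (OutcomeType.NON_BREAST_MALIGNANCY, 800)
        ]

    def test_same_side_reregistration_is_locoregional(self):
        h = make_history(
            registrations=[make_registration("T1", day=700, laterality=Laterality.LEFT)]
        )
        assert outcomes(candidates_from_registrations(h, CFG)) == [
            (OutcomeType.LOCOREGIONAL_RECURRENCE, 700)
        ]

    def test_provisional_registration_ignored(self):
        h = make_history(
            registrations=[
                make_registration("T1", day=400, laterality=Laterality.RIGHT, provisional=True)
            ]
        )
        assert candidates_from_registrations(h, CFG) == []


class TestDiagnosisCodeCandidates:
    def test_liver_secondary_after_treatment_window(self):
        h = make_history(events=[make_event(900, "C78.7")])
        assert outcomes(candidates_from_diagnosis_codes(h, CFG)) == [
            (OutcomeType.DISTANT_RECURRENCE, 900)
        ]

    def test_secondary_at_diagnosis_is_not_a_recurrence(self):
        h = make_history(events=[make_event(30, "C78.0")])
        assert candidates_from_diagnosis_codes(h, CFG) == []

    def test_regional_node_code_is_locoregional(self):
        h = make_history(events=[make_event(700, "C77.3")])
        assert outcomes(candidates_from_diagnosis_codes(h, CFG)) == [
            (OutcomeType.LOCOREGIONAL_RECURRENCE, 700)
        ]

    def test_palliative_care_without_site_is_unknown_type(self):
        h = make_history(events=[make_event(600, "Z51.5")])
        assert outcomes(candidates_from_diagnosis_codes(h, CFG)) == [
            (OutcomeType.RECURRENCE_TYPE_UNKNOWN, 600)
        ]

    def test_palliative_care_near_site_code_yields_no_unknown(self):
        h = make_history(events=[make_event(600, "Z51.5"), make_event(605, "C78.7")])
        got = outcomes(candidates_from_diagnosis_codes(h, CFG))
        assert (OutcomeType.RECURRENCE_TYPE_UNKNOWN, 600) not in got
        assert (OutcomeType.DISTANT_RECURRENCE, 605) in got


def surgery(day, code="B28.3", lat=Laterality.LEFT):
    return make_event(day, code, system=CodingSystem.OPCS4, laterality=lat)


class TestProcedureCandidates:
    def test_late_ipsilateral_reexcision_is_locoregional(self):
        h = make_history(events=[surgery(10), surgery(1000, "B28.1")])
        assert outcomes(candidates_from_procedures(h, CFG)) == [
            (OutcomeType.LOCOREGIONAL_RECURRENCE, 1000)
        ]

    def test_reexcision_within_primary_treatment_window_ignored(self):
        h = make_history(events=[surgery(10), surgery(100, "B28.1")])
        assert candidates_from_procedures(h, CFG) == []

    def test_contralateral_mastectomy_is_contralateral_candidate(self):
        h = make_history(events=[surgery(10), surgery(1200, "B27.1", Laterality.RIGHT)])
        assert outcomes(candidates_from_procedures(h, CFG)) == [
            (OutcomeType.CONTRALATERAL_BREAST_CANCER, 1200)
        ]


def chemo(day, intent=Intent.UNKNOWN, **kw):
    return make_event(day, "CHEMOTHERAPY", source=Source.SACT, system=CodingSystem.TREATMENT, intent=intent, **kw)


def radio(day, site="breast", intent=Intent.CURATIVE):
    return make_event(
        day, "RADIOTHERAPY", source=Source.RTDS, system=CodingSystem.TREATMENT,
        intent=intent, attributes={"site": site},
    )


class TestTherapyCandidates:
    def test_palliative_chemotherapy_is_distant(self):
        h = make_history(events=[chemo(1500, Intent.PALLIATIVE)])
        assert (OutcomeType.DISTANT_RECURRENCE, 1500) in outcomes(
            candidates_from_therapy(h, CFG)
        )

    def test_palliative_bone_radiotherapy_is_distant(self):
        h = make_history(events=[radio(2000, site="bone", intent=Intent.PALLIATIVE)])
        assert outcomes(candidates_from_therapy(h, CFG)) == [
            (OutcomeType.DISTANT_RECURRENCE, 2000)
        ]

    def test_adjuvant_chemotherapy_alone_yields_nothing(self):
        h = make_history(events=[chemo(30 + 21 * k, Intent.CURATIVE) for k in range(6)])
        assert candidates_from_therapy(h, CFG) == []

    def test_late_unlabelled_chemotherapy_block_is_distant(self):
        events = [chemo(30 + 21 * k, Intent.CURATIVE) for k in range(6)] + [chemo(1500)]
        h = make_history(events=events)
        assert (OutcomeType.DISTANT_RECURRENCE, 1500) in outcomes(
            candidates_from_therapy(h, CFG)
        )


class TestReconstructionFilter:
    def test_reconstruction_coded_surgery_removed(self):
        h = make_history(events=[surgery(10), surgery(1200, "B30.1", Laterality.RIGHT)])
        cands = candidates_from_procedures(h, CFG)
        assert len(cands) == 1
        assert reconstruction_filter(cands, h, CFG) == []

    def test_resection_without_nearby_malignancy_code_removed(self):
        h = make_history(events=[surgery(10), surgery(1200, "B27.1", Laterality.RIGHT)])
        cands = candidates_from_procedures(h, CFG)
        assert reconstruction_filter(cands, h, CFG) == []

    def test_resection_with_malignancy_code_retained(self):
        h = make_history(
            events=[surgery(10), surgery(1000, "B28.1"), make_event(1010, "C50.4")]
        )
        cands = candidates_from_procedures(h, CFG)
        assert reconstruction_filter(cands, h, CFG) == cands

    def test_empty_input_is_identity(self):
        assert reconstruction_filter([], make_history(), CFG) == []


def infusion_series(start=300, monthly=6, quarterly=14):
    days, d = [], start
    for _ in range(monthly):
        days.append(d)
        d += 28
    for _ in range(quarterly):
        days.append(d)
        d += 91
    return [chemo(x) for x in days]


class TestInfusionFilter:
    def _candidates(self, history):
        return candidates_from_therapy(history, CFG)

    def test_regular_series_without_metastasis_codes_removed(self):
        h = make_history(events=infusion_series())
        cands = self._candidates(h)
        assert cands, "the eager therapy rule should fire before filtering"
        assert infusion_filter(h, cands, CFG) == []

    def test_metastasis_code_at_series_midpoint_retains_candidate(self):
        events = infusion_series() + [make_event(800, "C79.5")]
        h = make_history(events=events)
        cands = self._candidates(h)
        kept = infusion_filter(h, cands, CFG)
        assert any(c.outcome is OutcomeType.DISTANT_RECURRENCE for c in kept)

    def test_two_attendances_below_min_count_retained(self):
        h = make_history(events=[chemo(1500), chemo(1528)])
        cands = self._candidates(h)
        assert cands
        assert infusion_filter(h, cands, CFG) == cands

    def test_multi_day_palliative_admission_never_filtered(self):
        h = make_history(
            events=[chemo(1500, Intent.PALLIATIVE, attributes={"duration_days": "3"})]
        )
        cands = self._candidates(h)
        assert infusion_filter(h, cands, CFG) == cands


_CAND_CODES = {
    OutcomeType.DISTANT_RECURRENCE: "C78.7",
    OutcomeType.LOCOREGIONAL_RECURRENCE: "C77.3",
    OutcomeType.CONTRALATERAL_BREAST_CANCER: "C50.4",
}


def cand(day, outcome, pid="P1"):
    ev = make_event(day, _CAND_CODES.get(outcome, "C80.9"), patient_id=pid)
    return CandidateOutcome(pid, INDEX_DATE + timedelta(days=day), outcome, (ev,), "test")


class TestAdjustment:
    def test_first_year_locoregional_removed(self):
        kept = apply_post_validation_adjustment([cand(200, OutcomeType.LOCOREGIONAL_RECURRENCE)], INDEX_DATE)
        assert kept == []

    def test_first_year_distant_retained(self):
        c = cand(200, OutcomeType.DISTANT_RECURRENCE)
        assert apply_post_validation_adjustment([c], INDEX_DATE) == [c]

    def test_day_365_boundary_is_retained(self):
        c = cand(365, OutcomeType.CONTRALATERAL_BREAST_CANCER)
        assert apply_post_validation_adjustment([c], INDEX_DATE) == [c]
        assert apply_post_validation_adjustment([cand(364, OutcomeType.CONTRALATERAL_BREAST_CANCER)], INDEX_DATE) == []


def valid_priority_orders(rng, k):
    """Random valid priority permutations (distant before locoregional)."""
    perms = []
    labels = list(OutcomeType)
    while len(perms) < k:
        rng.shuffle(labels)
        if labels.index(OutcomeType.DISTANT_RECURRENCE) < labels.index(
            OutcomeType.LOCOREGIONAL_RECURRENCE
        ):
            perms.append(tuple(labels))
    return perms


class TestResolveSameDate:
    def test_distant_beats_locoregional_on_same_day(self):
        cands = [
            cand(900, OutcomeType.LOCOREGIONAL_RECURRENCE),
            cand(900, OutcomeType.DISTANT_RECURRENCE),
        ]
        out = resolve_same_date(cands)
        assert [c.outcome for c in out] == [OutcomeType.DISTANT_RECURRENCE]
        assert len(out[0].evidence) == 2  # evidence merged

    def test_single_candidate_unchanged(self):
        c = cand(900, OutcomeType.DISTANT_RECURRENCE)
        assert resolve_same_date([c])[0].outcome is c.outcome

    def test_matches_brute_force_argmin_over_random_priorities(self):
        rng = random.Random(42)
        for order in valid_priority_orders(rng, 30):
            priority = PriorityOrder(order)
            multiset = [
                cand(500, rng.choice(list(OutcomeType))) for _ in range(rng.randint(1, 6))
            ]
            out = resolve_same_date(multiset, priority)
            assert len(out) == 1
            # independent oracle: exhaustive pairwise comparison
            best = multiset[0].outcome
            for c in multiset[1:]:
                if order.index(c.outcome) < order.index(best):
                    best = c.outcome
            assert out[0].outcome is best


class TestRunAlgorithm:
    def test_empty_history_emits_nothing(self):
        assert run_algorithm(make_history()).events == []

    def test_adjuvant_treatment_and_reconstruction_only_yields_no_recurrence(self):
        events = (
            [surgery(14)]
            + [chemo(30 + 21 * k, Intent.CURATIVE) for k in range(6)]
            + [radio(200)]
            + [surgery(300, "B29.1")]  # reconstruction inside year one
        )
        h = make_history(events=events)
        assert run_algorithm(h).events == []

    def test_death_mapping_by_underlying_cause(self):
        h1 = make_history(death=DeathRecord("P1", INDEX_DATE + timedelta(days=2000), "C50.9"))
        assert [c.outcome for c in run_algorithm(h1).events] == [OutcomeType.BREAST_CANCER_DEATH]
        h2 = make_history(death=DeathRecord("P1", INDEX_DATE + timedelta(days=2000), "I21.9"))
        assert [c.outcome for c in run_algorithm(h2).events] == [OutcomeType.NON_BREAST_CANCER_DEATH]

    def test_determinism_under_event_reordering(self):
        events = [
            surgery(14),
            make_event(900, "C78.7"),
            chemo(900, Intent.PALLIATIVE, attributes={"duration_days": "3"}),
            make_event(700, "C77.3"),
        ]
        h1 = make_history(events=list(events))
        h2 = make_history(events=list(reversed(events)))
        r1, r2 = run_algorithm(h1), run_algorithm(h2)
        assert [(c.date, c.outcome) for c in r1.events] == [
            (c.date, c.outcome) for c in r2.events
        ]

    def test_first_event_applies_definition_semantics(self):
        from rcdrecur.cohort import validation_window
        from rcdrecur.metrics import DEFAULT_DEFINITIONS

        events = [
            surgery(14),
            make_event(700, "C77.3"),  # locoregional, ignored by the distant definition
            make_event(900, "C78.7"),
        ]
        result = run_algorithm(make_history(events=events))
        window = validation_window(INDEX_DATE, INDEX_DATE + timedelta(days=3650))
        status, date = result.first_event(DEFAULT_DEFINITIONS["DISTANT_RECURRENCE"], window)
        assert status == "EVENT"
        assert (date - INDEX_DATE).days == 900

    def test_filters_only_remove(self):
        h = make_history(events=infusion_series() + [surgery(10), surgery(1200, "B30.1")])
        cands = candidates_from_procedures(h, CFG) + candidates_from_therapy(h, CFG)
        assert len(reconstruction_filter(cands, h, CFG)) <= len(cands)
        assert len(infusion_filter(h, cands, CFG)) <= len(cands)
        assert len(apply_post_validation_adjustment(cands, INDEX_DATE)) <= len(cands)
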