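"""Person-level CSC/eCSC classification rules and their invariants."""

import itertools

import pandas as pd
import pytest

from ecsc import (
    ALL_OPERATED,
    FELLOW_IMPAIRED_ONLY,
    IndicatorConfig,
    classify_frame,
    classify_person,
    eye_operable,
    eye_operated,
    survey_counts,
)
from ecsc.vision import OUTCOME_CUTS, SURGICAL_CUTS
from conftest import (
    HEALTHY,
    OPERABLE,
    OPERATED_BAD,
    OPERATED_GOOD,
    eye,
    make_survey,
    person,
    random_participants_frame,
)

ALL_CONFIGS = [
    IndicatorConfig(surgical_threshold=st, outcome_threshold=ot)
    for st in SURGICAL_CUTS
    for ot in OUTCOME_CUTS
]


class TestEyeLevel:
    @pytest.mark.parametrize(
        "lens,expected",
        [("PSEUDOPHAKIA", True), ("APHAKIA", True), ("PHAKIC_CATARACT", False),
         ("PHAKIC_CLEAR", False), ("NO_VIEW", False), ("NA", False)],
    )
    def test_eye_operated(self, lens, expected):
        assert eye_operated(eye(lens=lens)) is expected

    def test_operable_cataract_below_threshold(self):
        e = eye("PHAKIC_CATARACT", "LT_6_18_GE_6_60", cause="CATARACT")
        assert eye_operable(e, "6/18") is True

    def test_good_vision_never_operable(self):
        e = eye("PHAKIC_CATARACT", "GE_6_12", cause="CATARACT")
        assert all(not eye_operable(e, st) for st in SURGICAL_CUTS)

    def test_non_cataract_eye_not_operable(self):
        e = eye("PHAKIC_CLEAR", "LT_3_60", cause="OTHER")
        assert eye_operable(e, "6/18") is False

    def test_cause_requirement_relaxable(self):
        e = eye("PHAKIC_CATARACT", "LT_3_60", cause="OTHER")
        assert eye_operable(e, "6/18") is False
        assert eye_operable(e, "6/18", require_cataract_cause=False) is True


class TestClassifyPerson:
    def test_bilateral_uses_better_eye_presenting_va(self):
        p = person(
            1,
            right=eye("PSEUDOPHAKIA", "GE_6_12"),
            left=eye("PSEUDOPHAKIA", "LT_6_12_GE_6_18"),
        )
        c = classify_person(p)
        assert c.operated == "BILATERAL"
        assert c.postop_pva.value == "GE_6_12"
        assert c.in_ecsc_numerator

    def test_healthy_person_not_in_denominator(self):
        c = classify_person(person(1))
        assert not c.in_denominator and not c.in_csc_numerator

    def test_unilateral_aphakia_worst_outcome_fails_every_cut(self):
        p = person(1, right=eye("APHAKIA", "LT_3_60"), left=HEALTHY)
        for ot in OUTCOME_CUTS:
            c = classify_person(p, IndicatorConfig(outcome_threshold=ot))
            assert c.operated == "UNILATERAL"
            assert c.in_csc_numerator and not c.in_ecsc_numerator

    def test_operable_person_in_denominator_only(self):
        c = classify_person(person(1, right=OPERABLE))
        assert c.in_denominator and not c.in_csc_numerator

    def test_fellow_impaired_rule_requires_impaired_fellow_eye(self):
        cfg = IndicatorConfig(unilateral_rule=FELLOW_IMPAIRED_ONLY)
        impaired_fellow = eye("PHAKIC_CATARACT", "LT_6_18_GE_6_60", cause="CATARACT")
        good_fellow = HEALTHY
        p_in = person(1, right=OPERATED_GOOD, left=impaired_fellow)
        p_out = person(2, right=OPERATED_GOOD, left=good_fellow)
        assert classify_person(p_in, cfg).in_csc_numerator
        assert not classify_person(p_out, cfg).in_csc_numerator
        # under the default rule both count
        assert classify_person(p_out).in_csc_numerator

    def test_unknown_fellow_eye_excluded_and_counted(self):
        cfg = IndicatorConfig(unilateral_rule=FELLOW_IMPAIRED_ONLY)
        unknown_fellow = eye("NO_VIEW", "NA")
        p = person(1, right=OPERATED_GOOD, left=unknown_fellow)
        c = classify_person(p, cfg)
        assert not c.in_csc_numerator
        s = make_survey([p, person(2, cluster="c2")])
        counts = survey_counts(s, cfg)
        assert counts.exclusions["unilateral_fellow_eye_unknown"] == 1

    def test_both_lenses_missing_is_undefined(self):
        p = person(1, right=eye("NA", "NA"), left=eye("NA", "NA"))
        assert classify_person(p).undefined

    def test_operated_without_postop_va_excluded_from_ecsc_only(self):
        p = person(1, right=eye("PSEUDOPHAKIA", "NA"), left=HEALTHY)
        c = classify_person(p)
        assert c.in_csc_numerator and c.in_denominator
        assert c.ecsc_undefined and not c.in_ecsc_numerator


class TestSurveyCounts:
    def test_single_numerator_member_lands_in_one_cell(self):
        s = make_survey(
            [person(1, cluster="c1", age=72, sex="M", right=OPERATED_GOOD),
             person(2, cluster="c2")]
        )
        counts = survey_counts(s)
        cells = counts.cells
        hit = cells[cells["csc_num"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["cluster_id"] == "c1"
        assert hit.iloc[0]["sex"] == "M"
        assert hit.iloc[0]["age_band"] == "70-79"
        assert counts.totals() == {"examined": 2, "denom": 1, "csc_num": 1, "ecsc_num": 1}

    def test_counts_invariant_to_participant_order(self):
        frame = random_participants_frame(200, seed=3)
        from ecsc import Survey, SurveyMeta

        meta = SurveyMeta(survey_id="s", country="T", year=2020)
        shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c1 = survey_counts(Survey(frame=frame, meta=meta))
        c2 = survey_counts(Survey(frame=shuffled, meta=meta))
        key = ["cluster_id", "sex", "age_band"]
        pd.testing.assert_frame_equal(
            c1.cells.sort_values(key).reset_index(drop=True),
            c2.cells.sort_values(key).reset_index(drop=True),
        )
        assert c1.exclusions == c2.exclusions

    def test_hand_tally_of_twelve_participants(self):
        """Twelve hand-classified participants at the default configuration.

        Expected membership worked by hand from the rules:
          1 bilateral pseudophakia, good    -> denom, csc, ecsc
          2 unilateral pseudophakia, good,
            fellow operable                 -> denom, csc, ecsc
          3 unilateral aphakia, pva <3/60   -> denom, csc
          4 bilateral operable cataract     -> denom
          5 unilateral operable, fellow ok  -> denom
          6 healthy                         -> none
          7 other-cause impairment          -> none
          8 cataract but BCVA 6/12 or better-> none (above surgical cut)
          9 operated, postop VA missing     -> denom, csc (eCSC excluded)
         10 both lenses missing             -> excluded entirely
         11 bilateral pseudophakia, bad va  -> denom, csc
         12 cataract <6/18 but cause OTHER  -> none (cause requirement)
        """
        people = [
            person(1, right=OPERATED_GOOD, left=OPERATED_GOOD),
            person(2, right=OPERATED_GOOD, left=OPERABLE),
            person(3, right=eye("APHAKIA", "LT_3_60"), left=HEALTHY),
            person(4, right=OPERABLE, left=OPERABLE),
            person(5, right=OPERABLE, left=HEALTHY),
            person(6),
            person(7, right=eye("PHAKIC_CLEAR", "LT_3_60", cause="OTHER"),
                   left=eye("PHAKIC_CLEAR", "LT_3_60", cause="OTHER")),
            person(8, right=eye("PHAKIC_CATARACT", "GE_6_12", cause="CATARACT")),
            person(9, right=eye("PSEUDOPHAKIA", "NA"), left=HEALTHY),
            person(10, right=eye("NA", "NA"), left=eye("NA", "NA")),
            person(11, right=OPERATED_BAD, left=OPERATED_BAD),
            person(12, right=eye("PHAKIC_CATARACT", "LT_6_18_GE_6_60", cause="OTHER")),
        ]
        # spread over two clusters to satisfy the design requirement
        people = [
            person(p.id, cluster="c1" if int(p.id) <= 6 else "c2", age=p.age,
                   sex=p.sex, right=p.right, left=p.left)
            for p in people
        ]
        counts = survey_counts(make_survey(people))
        assert counts.totals() == {
            "examined": 11,  # person 10 excluded
            "denom": 7,      # 1, 2, 3, 4, 5, 9, 11
            "csc_num": 5,    # 1, 2, 3, 9, 11
            "ecsc_num": 2,   # 1, 2
        }
        assert counts.exclusions["undefined_lens_both_eyes"] == 1
        assert counts.exclusions["ecsc_numerator_missing_postop_va"] == 1


class TestInvariants:
    def test_subset_chain_over_random_participants(self):
        frame = random_participants_frame(400, seed=7)
        for cfg in ALL_CONFIGS:
            cls = classify_frame(frame, cfg)
            assert (cls["in_ecsc_numerator"] <= cls["in_csc_numerator"]).all()
            assert (cls["in_csc_numerator"] <= cls["in_denominator"]).all()

    def test_subset_chain_under_fellow_rule(self):
        frame = random_participants_frame(400, seed=8)
        for st in SURGICAL_CUTS:
            cfg = IndicatorConfig(surgical_threshold=st,
                                  unilateral_rule=FELLOW_IMPAIRED_ONLY)
            cls = classify_frame(frame, cfg)
            assert (cls["in_ecsc_numerator"] <= cls["in_csc_numerator"]).all()
            assert (cls["in_csc_numerator"] <= cls["in_denominator"]).all()

    def test_tightening_outcome_threshold_shrinks_ecsc(self):
        frame = random_participants_frame(400, seed=9)
        for st in SURGICAL_CUTS:
            loose = classify_frame(frame, IndicatorConfig(st, "6/18"))
            tight = classify_frame(frame, IndicatorConfig(st, "6/12"))
            assert (tight["in_ecsc_numerator"] <= loose["in_ecsc_numerator"]).all()

    def test_relaxing_surgical_threshold_grows_denominator(self):
        frame = random_participants_frame(400, seed=10)
        for rule in (ALL_OPERATED, FELLOW_IMPAIRED_ONLY):
            for tight_cut, loose_cut in itertools.pairwise(SURGICAL_CUTS):
                a = classify_frame(frame, IndicatorConfig(tight_cut, unilateral_rule=rule))
                b = classify_frame(frame, IndicatorConfig(loose_cut, unilateral_rule=rule))
                assert (a["in_denominator"] <= b["in_denominator"]).all()

    def test_classification_is_pure(self):
        frame = random_participants_frame(100, seed=12)
        a = classify_frame(frame)
        b = classify_frame(frame.copy())
        pd.testing.assert_frame_equal(a, b)
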