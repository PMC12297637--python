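"""Revised-scale item scoring, boundaries, properties and the lookup oracle."""

import datetime
import itertools
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kumascale import (
    Assessment,
    AutonomicFindings,
    CardiacLevel,
    CodingError,
    GiLevel,
    MotorFinding,
    Movement,
    Region,
    SensoryFinding,
    Side,
    VisceralFindings,
    gi_score,
    heart_score,
    kidney_score,
    limb_sensory_score,
    motor_subscore,
    mrc_to_kumamoto,
    nisll_to_kumamoto,
    orthostasis_score,
    score_assessment,
    sensory_subscore,
    sicca_scores,
    trunk_sensory_score,
    urination_score,
)
from kumascale.model import (
    LOWER_LIMB_LEVELS,
    Modality,
    TRUNK_HEAD_LEVELS,
    UPPER_LIMB_LEVELS,
)
from kumascale.scoring_revised import OrthostasisConfig


def _auto(**kw):
    return AutonomicFindings(**kw)


def _ortho(drop, **kw):
    return _auto(sbp_supine=130.0, sbp_standing_1min=130.0,
                 sbp_standing_3min=130.0 - drop, **kw)


class TestSensoryLadders:
    @pytest.mark.parametrize("region, levels", [
        (Region.LOWER_LIMB, LOWER_LIMB_LEVELS),
        (Region.UPPER_LIMB, UPPER_LIMB_LEVELS),
    ])
    def test_limb_ladder_scores(self, region, levels):
        """Six ordered levels score exactly 0, 1, 1.5, 2, 2.5, 3."""
        assert [limb_sensory_score(region, lv) for lv in levels] \
            == [0, 1, 1.5, 2, 2.5, 3]

    @pytest.mark.parametrize("level, expected", [
        ("none", 0), ("midline_trunk", 1), ("midclavicular_line", 2),
        ("neck_and_face", 3),
        # original 1997 labels map by rank
        ("umbilical", 1), ("clavicular", 2),
    ])
    def test_trunk_ladder_scores(self, level, expected):
        assert trunk_sensory_score(level) == expected

    def test_unknown_level_names_the_ladder(self):
        with pytest.raises(CodingError, match="upper_limb"):
            limb_sensory_score(Region.UPPER_LIMB, "ankle")
        with pytest.raises(CodingError, match="trunk/head"):
            trunk_sensory_score("chest")

    def test_vignette_sensory_subscore(self, vignette):
        assert sensory_subscore(vignette.sensory) == 4.5

    def test_no_findings_scores_zero(self):
        assert sensory_subscore([]) == 0.0

    def test_all_items_maximal_scores_24(self, all_worst):
        assert sensory_subscore(all_worst.sensory) == 24.0

    def test_worse_side_counts(self):
        findings = [
            SensoryFinding(modality=Modality.COLD, region=Region.LOWER_LIMB,
                           side=Side.LEFT, level="toes"),
            SensoryFinding(modality=Modality.COLD, region=Region.LOWER_LIMB,
                           side=Side.RIGHT, level="knee"),
        ]
        assert sensory_subscore(findings) == 2.5

    def test_trunk_light_touch_excluded_not_scored(self):
        findings = [SensoryFinding(modality=Modality.LIGHT_TOUCH,
                                   region=Region.TRUNK_HEAD,
                                   level="neck_and_face")]
        assert sensory_subscore(findings) == 0.0


class TestMotor:
    def test_mrc_mapping(self):
        """MRC 5..0 map to the Kumamoto ladder 0,2,3,4,5,6 (1 unreachable)."""
        assert [mrc_to_kumamoto(g) for g in (5, 4, 3, 2, 1, 0)] \
            == [0, 2, 3, 4, 5, 6]

    def test_nisll_mapping(self):
        assert [nisll_to_kumamoto(g) for g in (0, 2, 3.25, 3.50, 3.75, 4)] \
            == [0, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("bad", [-1, 6, 2.5, "4", None, True])
    def test_bad_mrc_grade_rejected(self, bad):
        with pytest.raises(CodingError):
            mrc_to_kumamoto(bad)

    def test_bad_nisll_grade_rejected(self):
        with pytest.raises(CodingError):
            nisll_to_kumamoto(3.0)

    def test_normal_power_scores_zero(self, vignette):
        assert motor_subscore(vignette.motor) == 0.0

    def test_plegia_scores_24(self):
        findings = [MotorFinding(movement=mv, mrc_grade=0) for mv in Movement]
        assert motor_subscore(findings) == 24.0

    def test_single_weak_movement(self):
        findings = [MotorFinding(movement=mv, mrc_grade=3
                                 if mv is Movement.ANKLE_DORSIFLEXION else 5)
                    for mv in Movement]
        assert motor_subscore(findings) == 3.0

    def test_worse_side_counts(self):
        findings = [MotorFinding(movement=mv, mrc_grade=5) for mv in Movement]
        findings.append(MotorFinding(movement=Movement.ELBOW_FLEXION,
                                     side=Side.LEFT, mrc_grade=2))
        assert motor_subscore(findings) == 4.0

    def test_untested_movement_is_missing(self):
        with pytest.raises(CodingError, match="mot_knee_extension"):
            motor_subscore([MotorFinding(movement=Movement.ANKLE_DORSIFLEXION,
                                         mrc_grade=5)])


class TestGi:
    def test_no_symptoms_scores_zero(self):
        assert gi_score(_auto(stools_per_week=7, stools_hard=False)).score == 0

    @pytest.mark.parametrize("per_week, expected", [
        (2, 1.0),  # chronic constipation
        (3, 0.0),  # boundary: "fewer than three" is strict
    ])
    def test_constipation_boundary(self, per_week, expected):
        res = gi_score(_auto(stools_per_week=per_week, stools_hard=True))
        assert res.score == expected

    @pytest.mark.parametrize("loose_per_day, expected", [
        (2, 0.0),  # below the >=3/day diarrhoea definition
        (3, 2.0), (6, 4.0), (10, 6.0),
    ])
    def test_diarrhoea_tiers_from_frequency(self, loose_per_day, expected):
        assert gi_score(_auto(loose_stools_per_day=loose_per_day)).score \
            == expected

    @pytest.mark.parametrize("code, expected", [
        (GiLevel.NONE, 0), (GiLevel.CONSTIPATION, 1),
        (GiLevel.DIARRHOEA_MILD, 2), (GiLevel.DIARRHOEA_MODERATE, 4),
        (GiLevel.DIARRHOEA_SEVERE, 6),
    ])
    def test_precoded_tiers(self, code, expected):
        assert gi_score(_auto(gi_level_code=code)).score == expected

    def test_raw_wins_over_conflicting_code(self):
        res = gi_score(_auto(stools_per_week=2, stools_hard=True,
                             gi_level_code=GiLevel.DIARRHOEA_SEVERE))
        assert res.score == 1.0
        assert any("conflict" in n for n in res.notes)

    def test_alternating_pattern_scores_worst_tier(self):
        res = gi_score(_auto(stools_per_week=2, loose_stools_per_day=6))
        assert res.score == 4.0

    def test_all_fields_absent_is_missing(self):
        assert gi_score(_auto()).score is None


class TestOrthostasis:
    @pytest.mark.parametrize("drop, expected", [
        (0, 0.0), (5, 0.0), (9, 0.0),
        (10, 2.0), (15, 2.0), (20, 2.0),
        (21, 4.0), (40, 4.0),
    ])
    def test_revised_bands(self, drop, expected):
        assert orthostasis_score(_ortho(drop)).score == expected

    def test_worst_of_the_two_standing_readings(self):
        res = orthostasis_score(_auto(sbp_supine=130, sbp_standing_1min=115,
                                      sbp_standing_3min=128))
        assert res.score == 2.0

    def test_syncope_flag_scores_six(self):
        assert orthostasis_score(_ortho(25, orthostatic_syncope=True)).score \
            == 6.0

    def test_supine_hypertension_raises_onset_to_30(self):
        assert orthostasis_score(_ortho(25, supine_hypertension=True)).score \
            == 0.0
        assert orthostasis_score(_ortho(35, supine_hypertension=True)).score \
            == 2.0
        assert orthostasis_score(_ortho(45, supine_hypertension=True)).score \
            == 4.0

    def test_missing_supine_pressure_is_missing_item(self):
        assert orthostasis_score(_auto(sbp_standing_3min=120)).score is None

    def test_antihypertensive_confounder_noted(self):
        res = orthostasis_score(_ortho(15, on_antihypertensives=True))
        assert any("antihypertensives" in n for n in res.notes)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            OrthostasisConfig(two_point_drop_low=25.0)


class TestUrination:
    @pytest.mark.parametrize("residual, expected", [
        (100, 0.0), (149, 0.0),
        (150, 2.0), (200, 2.0), (299, 2.0),
        (300, 4.0), (400, 4.0), (500, 4.0),
        (501, 6.0),
    ])
    def test_residual_bands(self, residual, expected):
        assert urination_score(_auto(residual_urine_ml=residual)).score \
            == expected

    def test_catheter_scores_six(self):
        assert urination_score(_auto(catheterized=True)).score == 6.0

    def test_sporadic_incontinence_scores_two(self):
        assert urination_score(_auto(residual_urine_ml=50,
                                     sporadic_incontinence=True)).score == 2.0

    def test_retention_outranks_incontinence(self):
        assert urination_score(_auto(residual_urine_ml=400,
                                     sporadic_incontinence=True)).score == 4.0

    def test_no_scan_and_no_catheter_is_missing(self):
        assert urination_score(_auto()).score is None

    def test_prostate_caution_note(self):
        res = urination_score(_auto(residual_urine_ml=200,
                                    prostate_hyperplasia_excluded=False))
        assert any("prostate" in n for n in res.notes)


class TestSicca:
    def test_grades_pass_through(self):
        eyes, mouth = sicca_scores(_auto(dry_eyes_grade=1, dry_mouth_grade=3,
                                         dry_mouth_drug_induced=False))
        assert (eyes.score, mouth.score) == (1.0, 3.0)

    def test_both_zero(self):
        eyes, mouth = sicca_scores(_auto(dry_eyes_grade=0, dry_mouth_grade=0))
        assert (eyes.score, mouth.score) == (0.0, 0.0)

    def test_drug_induced_dry_mouth_excluded(self):
        _, mouth = sicca_scores(_auto(dry_eyes_grade=0, dry_mouth_grade=3,
                                      dry_mouth_drug_induced=True))
        assert mouth.score == 0.0
        assert any("side effect" in n for n in mouth.notes)

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(CodingError):
            sicca_scores(_auto(dry_eyes_grade=4, dry_mouth_grade=0))


class TestVisceral:
    @pytest.mark.parametrize("code, expected", [
        (CardiacLevel.NORMAL, 0), (CardiacLevel.CONDUCTION_DISTURBANCE, 4),
        (CardiacLevel.ADVANCED_CONDUCTION, 8),
        (CardiacLevel.DEVICE_OR_CHF, 12),
    ])
    def test_heart_ladder(self, code, expected):
        assert heart_score(
            VisceralFindings(cardiac_level_code=code)).score == expected

    def test_heart_missing_without_code(self):
        assert heart_score(VisceralFindings()).score is None

    def test_kidney_ladder(self):
        assert kidney_score(VisceralFindings()).score == 0.0
        assert kidney_score(
            VisceralFindings(dipstick_proteinuria=True)).score == 4.0
        nephrotic = VisceralFindings(proteinuria_g_per_24h=4.0,
                                     hypoalbuminemia=True, oedema=True)
        assert kidney_score(nephrotic).score == 8.0
        assert kidney_score(VisceralFindings(on_dialysis=True)).score == 12.0

    def test_nephrotic_syndrome_requires_all_three_components(self):
        # proteinuria above 3.5 g/24 h without oedema stays in the 4-band
        partial = VisceralFindings(proteinuria_g_per_24h=4.0,
                                   hypoalbuminemia=True)
        assert kidney_score(partial).score == 4.0
        # proteinuria at exactly 3.5 g/24 h is not nephrotic-range
        borderline = VisceralFindings(proteinuria_g_per_24h=3.5,
                                      hypoalbuminemia=True, oedema=True)
        assert kidney_score(borderline).score == 4.0


class TestScoreAssessment:
    def test_vignette_breakdown(self, vignette):
        b = score_assessment(vignette)
        assert b.subscores() == {"sensory": 4.5, "motor": 0.0,
                                 "autonomic": 4.0, "visceral": 8.0}
        assert b.total == 16.5
        assert b.complete

    def test_all_normal_scores_zero(self, all_normal):
        b = score_assessment(all_normal)
        assert b.total == 0.0 and b.complete

    def test_all_worst_scores_96(self, all_worst):
        b = score_assessment(all_worst)
        assert b.total == 96.0
        assert set(b.subscores().values()) == {24.0}

    def test_total_is_sum_of_subscores(self, vignette):
        b = score_assessment(vignette)
        assert b.total == sum(b.subscores().values())

    def test_missing_items_flagged_not_prorated(self, vignette):
        a = vignette.model_copy(deep=True)
        a.motor = a.motor[:2]
        a.autonomic.residual_urine_ml = None
        b = score_assessment(a)
        assert not b.complete
        assert set(b.missing_items) == {"mot_knee_extension",
                                        "mot_elbow_flexion",
                                        "auto_urination"}
        assert b.total == 16.5  # partial sum over scoreable items

    def test_invalid_assessment_raises(self, vignette):
        from kumascale import InvalidAssessmentError
        a = vignette.model_copy(deep=True)
        a.motor[0] = MotorFinding(movement=Movement.ANKLE_DORSIFLEXION,
                                  mrc_grade=9)
        with pytest.raises(InvalidAssessmentError):
            score_assessment(a)

    @given(st.randoms(use_true_random=False))
    def test_order_independence(self, rnd):
        """Shuffling the finding lists never changes the breakdown."""
        from kumascale import example_moderate_assessment
        a = example_moderate_assessment()
        shuffled = a.model_copy(deep=True)
        rnd.shuffle(shuffled.sensory)
        rnd.shuffle(shuffled.motor)
        assert score_assessment(shuffled) == score_assessment(a)

    def test_determinism_bit_for_bit(self, vignette):
        assert score_assessment(vignette) == score_assessment(vignette)


class TestMonotonicity:
    """Worsening any single raw finding never decreases a score."""

    @pytest.mark.parametrize("region, levels", [
        (Region.LOWER_LIMB, LOWER_LIMB_LEVELS),
        (Region.UPPER_LIMB, UPPER_LIMB_LEVELS),
    ])
    def test_limb_sensory_monotone(self, region, levels):
        scores = [limb_sensory_score(region, lv) for lv in levels]
        assert scores == sorted(scores)

    def test_trunk_sensory_monotone(self):
        scores = [trunk_sensory_score(lv) for lv in TRUNK_HEAD_LEVELS]
        assert scores == sorted(scores)

    def test_mrc_monotone_in_weakness(self):
        scores = [mrc_to_kumamoto(g) for g in (5, 4, 3, 2, 1, 0)]
        assert scores == sorted(scores)

    @given(st.floats(0, 60), st.floats(0, 60))
    def test_orthostasis_monotone_in_drop(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert orthostasis_score(_ortho(lo)).score \
            <= orthostasis_score(_ortho(hi)).score

    @given(st.integers(0, 800), st.integers(0, 800))
    def test_urination_monotone_in_residual(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert urination_score(_auto(residual_urine_ml=lo)).score \
            <= urination_score(_auto(residual_urine_ml=hi)).score

    @given(st.integers(0, 20), st.integers(0, 20))
    def test_gi_monotone_in_loose_stools(self, n1, n2):
        lo, hi = sorted([n1, n2])
        assert gi_score(_auto(loose_stools_per_day=lo)).score \
            <= gi_score(_auto(loose_stools_per_day=hi)).score

    def test_total_monotone_under_single_item_worsening(self, vignette):
        base = score_assessment(vignette).total
        worse = vignette.model_copy(deep=True)
        worse.sensory[1] = worse.sensory[1].model_copy(
            update={"level": "lower_leg"})  # pinprick foot -> lower leg
        assert score_assessment(worse).total >= base


# ---------------------------------------------------------------------------
# Independent table-lookup oracle over the item registry
# ---------------------------------------------------------------------------

# literal score tables, kept independent of the package's internals
_ORACLE_LIMB = [0.0, 1.0, 1.5, 2.0, 2.5, 3.0]
_ORACLE_TRUNK = [0.0, 1.0, 2.0, 3.0]
_ORACLE_MOTOR = [0.0, 2.0, 3.0, 4.0, 5.0, 6.0]
_ORACLE_GI = [0.0, 1.0, 2.0, 4.0, 6.0]
_ORACLE_246 = [0.0, 2.0, 4.0, 6.0]
_ORACLE_SICCA = [0.0, 1.0, 2.0, 3.0]
_ORACLE_VISC = [0.0, 4.0, 8.0, 12.0]


def _precoded_assessment(rnd: random.Random):
    """Random assessment built purely from pre-coded item levels, plus its
    brute-force expected score (sum of literal table lookups)."""
    expected = 0.0
    sensory = []
    for modality, region, ladder, levels in [
        (m, r, _ORACLE_LIMB, LOWER_LIMB_LEVELS if r is Region.LOWER_LIMB
         else UPPER_LIMB_LEVELS)
        for m in Modality for r in (Region.LOWER_LIMB, Region.UPPER_LIMB)
    ] + [(m, Region.TRUNK_HEAD, _ORACLE_TRUNK, TRUNK_HEAD_LEVELS)
         for m in (Modality.COLD, Modality.PINPRICK)]:
        idx = rnd.randrange(len(ladder))
        sensory.append(SensoryFinding(modality=modality, region=region,
                                      level=levels[idx]))
        expected += ladder[idx]

    motor = []
    for mv in Movement:
        idx = rnd.randrange(6)
        motor.append(MotorFinding(movement=mv, mrc_grade=5 - idx))
        expected += _ORACLE_MOTOR[idx]

    gi_idx = rnd.randrange(5)
    ortho_idx = rnd.randrange(4)
    urine_idx = rnd.randrange(4)
    eyes_idx = rnd.randrange(4)
    mouth_idx = rnd.randrange(4)
    expected += (_ORACLE_GI[gi_idx] + _ORACLE_246[ortho_idx]
                 + _ORACLE_246[urine_idx] + _ORACLE_SICCA[eyes_idx]
                 + _ORACLE_SICCA[mouth_idx])
    autonomic = AutonomicFindings(
        gi_level_code=list(GiLevel)[gi_idx],
        sbp_supine=130.0,
        sbp_standing_1min=130.0 - [0.0, 15.0, 25.0, 25.0][ortho_idx],
        sbp_standing_3min=130.0,
        orthostatic_syncope=(ortho_idx == 3),
        residual_urine_ml=[50.0, 200.0, 400.0, 600.0][urine_idx],
        dry_eyes_grade=eyes_idx, dry_mouth_grade=mouth_idx,
    )

    heart_idx = rnd.randrange(4)
    kidney_idx = rnd.randrange(4)
    expected += _ORACLE_VISC[heart_idx] + _ORACLE_VISC[kidney_idx]
    visceral = VisceralFindings(
        cardiac_level_code=list(CardiacLevel)[heart_idx],
        dipstick_proteinuria=(kidney_idx == 1),
        proteinuria_g_per_24h=4.0 if kidney_idx == 2 else None,
        hypoalbuminemia=(kidney_idx == 2), oedema=(kidney_idx == 2),
        on_dialysis=(kidney_idx == 3),
    )
    a = Assessment(patient_id="oracle", visit_date=datetime.date(2024, 1, 1),
                   sensory=sensory, motor=motor, autonomic=autonomic,
                   visceral=visceral)
    return a, expected


def test_oracle_equivalence_on_random_precoded_assessments():
    """score_assessment agrees with a brute-force table-lookup-and-sum
    oracle on 1,000 random pre-coded assessments."""
    rnd = random.Random(20240106)
    for _ in range(1000):
        a, expected = _precoded_assessment(rnd)
        b = score_assessment(a)
        assert b.complete
        assert b.total == pytest.approx(expected, abs=0)
        assert b.total == sum(b.subscores().values())
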