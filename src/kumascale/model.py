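"""Domain types, item registry and validation for Kumamoto-scale assessments.

The Kumamoto scale grades hereditary transthyretin (ATTRv) amyloidosis in
four subdomains — sensory abnormalities, motor function, autonomic
dysfunction, and visceral organ involvement — each worth 0-24 points, for a
total of 0-96.  This module defines the raw clinical findings that feed both
the original (1997) and the revised scoring engines, the closed registry of
scoreable items, and a validator that reports problems as findings rather
than exceptions so that a whole case-report form can be checked in one pass.

Numeric range rules (e.g. MRC grades 0-5) are deliberately enforced by
:func:`validate_assessment`, not by the pydantic models, so that an
out-of-range form can still be constructed, inspected and reported on.
"""

from __future__ import annotations

import datetime as _dt
import enum
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Enumerations and ordered ladders
# ---------------------------------------------------------------------------

class Modality(str, enum.Enum):
    """Sensory modality tested at the bedside."""

    COLD = "cold"
    PINPRICK = "pinprick"
    LIGHT_TOUCH = "light_touch"


class Region(str, enum.Enum):
    LOWER_LIMB = "lower_limb"
    UPPER_LIMB = "upper_limb"
    TRUNK_HEAD = "trunk_head"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    #: a single combined judgement over both sides
    UNSPECIFIED = "unspecified"


class Movement(str, enum.Enum):
    """The four single-joint movements tested for motor function."""

    ANKLE_DORSIFLEXION = "ankle_dorsiflexion"
    KNEE_EXTENSION = "knee_extension"
    ELBOW_FLEXION = "elbow_flexion"
    WRIST_DORSIFLEXION = "wrist_dorsiflexion"


class GiLevel(str, enum.Enum):
    """Pre-coded gastrointestinal symptom tier.

    ``CONSTIPATION`` scores 1 point on the revised scale only; the three
    diarrhoea tiers score 2/4/6 on both scales.
    """

    NONE = "none"
    CONSTIPATION = "constipation"
    DIARRHOEA_MILD = "diarrhoea_mild"
    DIARRHOEA_MODERATE = "diarrhoea_moderate"
    DIARRHOEA_SEVERE = "diarrhoea_severe"


class CardiacLevel(str, enum.Enum):
    """Ordered cardiac involvement category (0 / 4 / 8 / 12 points).

    ``DEVICE_OR_CHF`` is third-degree AV block or a pacemaker; heart failure
    counts only in combination with one of those, which is why it shares the
    worst category.  ``ADVANCED_CONDUCTION`` is an intermediate category
    (e.g. second-degree AV block) assignable only by explicit coding.
    """

    NORMAL = "normal"
    CONDUCTION_DISTURBANCE = "conduction_disturbance"
    ADVANCED_CONDUCTION = "advanced_conduction"
    DEVICE_OR_CHF = "device_or_chf"


class ScaleVersion(str, enum.Enum):
    ORIGINAL = "original"
    REVISED = "revised"


#: Anatomical ladders for the most proximal level of LOST sensation,
#: ordered strictly distal → proximal.  ``normal`` / ``none`` means no loss.
LOWER_LIMB_LEVELS = ("normal", "toes", "foot", "lower_leg", "knee", "thigh")
UPPER_LIMB_LEVELS = ("normal", "fingers", "hand", "forearm", "upper_arm",
                     "shoulder")
#: Revised trunk/head ladder: intercostal neuropathy starts at the anterior
#: midline and spreads to the periphery.
TRUNK_HEAD_LEVELS = ("none", "midline_trunk", "midclavicular_line",
                     "neck_and_face")
#: Original 1997 trunk/head labels; same ranks and the same 0/1/2/3 scores.
TRUNK_HEAD_LEVELS_ORIGINAL = ("none", "umbilical", "clavicular",
                              "neck_and_face")

#: Original-label → revised-label aliases accepted on input.
_TRUNK_ALIASES = {
    "umbilical": "midline_trunk",
    "clavicular": "midclavicular_line",
}

REGION_LADDERS = {
    Region.LOWER_LIMB: LOWER_LIMB_LEVELS,
    Region.UPPER_LIMB: UPPER_LIMB_LEVELS,
    Region.TRUNK_HEAD: TRUNK_HEAD_LEVELS,
}

#: NIS-LL motor grades accepted as an alternative to MRC.
NIS_LL_GRADES = (0.0, 2.0, 3.25, 3.50, 3.75, 4.0)


def normalize_trunk_level(level: str) -> str:
    """Map original trunk/head labels (umbilical, clavicular) onto the
    revised ladder; revised labels pass through unchanged."""
    return _TRUNK_ALIASES.get(level, level)


# ---------------------------------------------------------------------------
# Item registry
# ---------------------------------------------------------------------------

#: Sensory items: 3 modalities on each limb region, cold and pinprick on
#: trunk/head (light touch on the trunk is not a scoreable item).
SENSORY_ITEMS = (
    ("sens_cold_lower_limb", Modality.COLD, Region.LOWER_LIMB),
    ("sens_pinprick_lower_limb", Modality.PINPRICK, Region.LOWER_LIMB),
    ("sens_touch_lower_limb", Modality.LIGHT_TOUCH, Region.LOWER_LIMB),
    ("sens_cold_upper_limb", Modality.COLD, Region.UPPER_LIMB),
    ("sens_pinprick_upper_limb", Modality.PINPRICK, Region.UPPER_LIMB),
    ("sens_touch_upper_limb", Modality.LIGHT_TOUCH, Region.UPPER_LIMB),
    ("sens_cold_trunk_head", Modality.COLD, Region.TRUNK_HEAD),
    ("sens_pinprick_trunk_head", Modality.PINPRICK, Region.TRUNK_HEAD),
)

MOTOR_ITEMS = (
    ("mot_ankle_dorsiflexion", Movement.ANKLE_DORSIFLEXION),
    ("mot_wrist_dorsiflexion", Movement.WRIST_DORSIFLEXION),
    ("mot_knee_extension", Movement.KNEE_EXTENSION),
    ("mot_elbow_flexion", Movement.ELBOW_FLEXION),
)

AUTONOMIC_ITEMS = ("auto_gi", "auto_orthostasis", "auto_urination",
                   "auto_dry_eyes", "auto_dry_mouth")

VISCERAL_ITEMS = ("visc_heart", "visc_kidney")

#: All item codes in score-sheet order.
ITEM_CODES = (
    tuple(code for code, *_ in SENSORY_ITEMS)
    + tuple(code for code, _ in MOTOR_ITEMS)
    + AUTONOMIC_ITEMS
    + VISCERAL_ITEMS
)

SENSORY_ITEM_CODE = {(m, r): code for code, m, r in SENSORY_ITEMS}
MOTOR_ITEM_CODE = {mv: code for code, mv in MOTOR_ITEMS}

#: Maximum attainable points per item, identical under both scale versions.
ITEM_MAXIMA = {
    **{code: 3.0 for code, *_ in SENSORY_ITEMS},
    **{code: 6.0 for code, _ in MOTOR_ITEMS},
    "auto_gi": 6.0, "auto_orthostasis": 6.0, "auto_urination": 6.0,
    "auto_dry_eyes": 3.0, "auto_dry_mouth": 3.0,
    "visc_heart": 12.0, "visc_kidney": 12.0,
}

SUBDOMAINS = ("sensory", "motor", "autonomic", "visceral")
SUBDOMAIN_ITEMS = {
    "sensory": tuple(code for code, *_ in SENSORY_ITEMS),
    "motor": tuple(code for code, _ in MOTOR_ITEMS),
    "autonomic": AUTONOMIC_ITEMS,
    "visceral": VISCERAL_ITEMS,
}


# ---------------------------------------------------------------------------
# Findings (pydantic models)
# ---------------------------------------------------------------------------

class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SensoryFinding(_StrictModel):
    """Most proximal anatomical level of *lost* sensation for one modality
    in one body region (optionally one side).

    ``level`` must lie on the region's ladder; ``normal`` / ``none`` records
    an explicitly tested region without sensory loss.
    """

    modality: Modality
    region: Region
    side: Side = Side.UNSPECIFIED
    level: str
    instrument: Optional[str] = None

    def normalized_level(self) -> str:
        if self.region is Region.TRUNK_HEAD:
            return normalize_trunk_level(self.level)
        return self.level


class MotorFinding(_StrictModel):
    """MRC grade (0 = no contraction … 5 = normal power) and/or NIS-LL grade
    for one of the four tested movements."""

    movement: Movement
    side: Side = Side.UNSPECIFIED
    mrc_grade: Optional[int] = None
    nis_ll_grade: Optional[float] = None


class AutonomicFindings(_StrictModel):
    """Raw autonomic measurements and coded findings for one visit.

    Blood pressures in mm Hg; residual urine in ml.  The supine pressure is
    taken after 5 min of rest, standing pressures after 1 and 3 min upright.
    """

    # gastrointestinal
    stools_per_week: Optional[int] = None
    stools_hard: Optional[bool] = None
    loose_stools_per_day: Optional[int] = None
    gi_level_code: Optional[GiLevel] = None
    # orthostasis
    sbp_supine: Optional[float] = None
    sbp_standing_1min: Optional[float] = None
    sbp_standing_3min: Optional[float] = None
    dbp_supine: Optional[float] = None
    dbp_standing: Optional[float] = None
    supine_hypertension: bool = False
    orthostatic_syncope: bool = False
    on_antihypertensives: bool = False
    # urination
    residual_urine_ml: Optional[float] = None
    sporadic_incontinence: bool = False
    catheterized: bool = False
    prostate_hyperplasia_excluded: Optional[bool] = None
    # sicca
    dry_eyes_grade: Optional[int] = None
    dry_mouth_grade: Optional[int] = None
    dry_mouth_drug_induced: Optional[bool] = None


class VisceralFindings(_StrictModel):
    """Cardiac and renal involvement for one visit."""

    cardiac_level_code: Optional[CardiacLevel] = None
    cardiac_finding_text: Optional[str] = None
    dipstick_proteinuria: bool = False
    proteinuria_g_per_24h: Optional[float] = None
    hypoalbuminemia: bool = False
    oedema: bool = False
    on_dialysis: bool = False

    def nephrotic_syndrome(self) -> bool:
        """Proteinuria >3.5 g/24 h plus hypoalbuminemia plus oedema."""
        return (self.proteinuria_g_per_24h is not None
                and self.proteinuria_g_per_24h > 3.5
                and self.hypoalbuminemia and self.oedema)


class Assessment(_StrictModel):
    """One patient-visit bundle of findings plus follow-up metadata."""

    patient_id: str
    visit_date: _dt.date
    sensory: list[SensoryFinding] = Field(default_factory=list)
    motor: list[MotorFinding] = Field(default_factory=list)
    autonomic: AutonomicFindings = Field(default_factory=AutonomicFindings)
    visceral: VisceralFindings = Field(default_factory=VisceralFindings)
    weight_kg: Optional[float] = None
    height_m: Optional[float] = None
    serum_albumin_g_per_L: Optional[float] = None
    subjective_deterioration: Optional[bool] = None
    new_organ_involvement: Optional[bool] = None


class ScoreBreakdown(_StrictModel):
    """Per-item scores, the four subdomain subscores and the total.

    ``missing_items`` lists item codes that could not be scored; when it is
    non-empty the subscores cover only the scoreable items and the result is
    flagged incomplete rather than prorated.  ``notes`` is the audit trail of
    every non-obvious coding rule applied.
    """

    scale_version: ScaleVersion
    item_scores: dict[str, float] = Field(default_factory=dict)
    sensory_subscore: float = 0.0
    motor_subscore: float = 0.0
    autonomic_subscore: float = 0.0
    visceral_subscore: float = 0.0
    total: float = 0.0
    missing_items: list[str] = Field(default_factory=list)
    notes: list[str] = Field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing_items

    def subscores(self) -> dict[str, float]:
        return {
            "sensory": self.sensory_subscore,
            "motor": self.motor_subscore,
            "autonomic": self.autonomic_subscore,
            "visceral": self.visceral_subscore,
        }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

class ValidationFinding(_StrictModel):
    """One problem detected on an assessment: the offending field and the
    rule it breaks.  Never raised — collected and returned."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.field}: {self.message} [{self.rule}]"


class InvalidAssessmentError(ValueError):
    """Raised by scoring entry points when the assessment fails validation."""

    def __init__(self, findings: list[ValidationFinding]):
        self.findings = findings
        super().__init__(
            "invalid assessment: " + "; ".join(str(f) for f in findings))


class CodingError(ValueError):
    """A value outside the coding ladder of an item (e.g. unknown sensory
    level, non-integer MRC grade) passed directly to a scoring operation."""


def _check_nonneg(value, field, rule, out):
    if value is not None and value < 0:
        out.append(ValidationFinding(
            field=field, rule=rule, message=f"must be non-negative, got {value}"))


def validate_assessment(a: Assessment) -> list[ValidationFinding]:
    """Check every type invariant on an assessment.

    Returns an empty list iff the assessment is well formed.  Each finding
    names the offending field and the violated rule; all problems are
    reported, not just the first.
    """
    out: list[ValidationFinding] = []

    seen_sensory: set[tuple] = set()
    for i, f in enumerate(a.sensory):
        prefix = f"sensory[{i}]"
        ladder = REGION_LADDERS[f.region]
        level = f.normalized_level()
        if level not in ladder:
            out.append(ValidationFinding(
                field=f"{prefix}.level", rule="level-on-ladder",
                message=(f"level {f.level!r} is not on the {f.region.value} "
                         f"ladder {ladder}")))
        key = (f.modality, f.region, f.side)
        if key in seen_sensory:
            out.append(ValidationFinding(
                field=prefix, rule="unique-item",
                message=(f"duplicate finding for ({f.modality.value}, "
                         f"{f.region.value}, {f.side.value})")))
        seen_sensory.add(key)

    seen_motor: set[tuple] = set()
    for i, f in enumerate(a.motor):
        prefix = f"motor[{i}]"
        if f.mrc_grade is None and f.nis_ll_grade is None:
            out.append(ValidationFinding(
                field=f"{prefix}.mrc_grade", rule="grade-present",
                message="neither mrc_grade nor nis_ll_grade given"))
        if f.mrc_grade is not None and f.mrc_grade not in range(6):
            out.append(ValidationFinding(
                field=f"{prefix}.mrc_grade", rule="mrc-range",
                message=f"MRC grade must be an integer 0-5, got {f.mrc_grade}"))
        if f.nis_ll_grade is not None and f.nis_ll_grade not in NIS_LL_GRADES:
            out.append(ValidationFinding(
                field=f"{prefix}.nis_ll_grade", rule="nisll-ladder",
                message=(f"NIS-LL grade must be one of {NIS_LL_GRADES}, "
                         f"got {f.nis_ll_grade}")))
        if (f.mrc_grade in range(6) and f.nis_ll_grade in NIS_LL_GRADES):
            # both grades given: they must agree on the Kumamoto score
            from .scoring_revised import mrc_to_kumamoto, nisll_to_kumamoto
            if mrc_to_kumamoto(f.mrc_grade) != nisll_to_kumamoto(f.nis_ll_grade):
                out.append(ValidationFinding(
                    field=f"{prefix}.nis_ll_grade", rule="grade-consistency",
                    message=(f"MRC {f.mrc_grade} and NIS-LL {f.nis_ll_grade} "
                             "map to different Kumamoto scores")))
        key = (f.movement, f.side)
        if key in seen_motor:
            out.append(ValidationFinding(
                field=prefix, rule="unique-item",
                message=(f"duplicate finding for ({f.movement.value}, "
                         f"{f.side.value})")))
        seen_motor.add(key)

    au = a.autonomic
    for field in ("sbp_supine", "sbp_standing_1min", "sbp_standing_3min",
                  "dbp_supine", "dbp_standing"):
        _check_nonneg(getattr(au, field), f"autonomic.{field}",
                      "pressure-nonneg", out)
    _check_nonneg(au.residual_urine_ml, "autonomic.residual_urine_ml",
                  "volume-nonneg", out)
    for field in ("stools_per_week", "loose_stools_per_day"):
        _check_nonneg(getattr(au, field), f"autonomic.{field}",
                      "count-nonneg", out)
    for field in ("dry_eyes_grade", "dry_mouth_grade"):
        v = getattr(au, field)
        if v is not None and v not in (0, 1, 2, 3):
            out.append(ValidationFinding(
                field=f"autonomic.{field}", rule="grade-range",
                message=f"grade must be in 0-3, got {v}"))

    _check_nonneg(a.visceral.proteinuria_g_per_24h,
                  "visceral.proteinuria_g_per_24h", "mass-nonneg", out)

    for field in ("weight_kg", "height_m", "serum_albumin_g_per_L"):
        v = getattr(a, field)
        if v is not None and v <= 0:
            out.append(ValidationFinding(
                field=field, rule="positive",
                message=f"must be positive when given, got {v}"))

    return out
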