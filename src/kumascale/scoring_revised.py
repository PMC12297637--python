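"""Revised Kumamoto scale scoring.

The revision refines the limb sensory ladders to five levels of loss
(half-point steps: 0, 1, 1.5, 2, 2.5, 3), adds constipation as a 1-point
gastrointestinal symptom, raises the onset of the 2-point orthostatic band
from a 0 mm Hg to a 10 mm Hg systolic drop, and maps motor testing onto the
MRC (or NIS-LL) grading of four single-joint movements.  Subdomain maxima
(24 points each) and the 0-96 total are unchanged from the 1997 scale.

Every scoring operation returns plain numbers; :func:`score_assessment`
assembles them into a :class:`~kumascale.model.ScoreBreakdown` with an audit
trail of the non-obvious rules applied (worse-side merging, drug-induced
sicca exclusion, raw-vs-code conflicts, missing items).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

from .model import (
    Assessment,
    AutonomicFindings,
    CardiacLevel,
    CodingError,
    GiLevel,
    InvalidAssessmentError,
    ITEM_MAXIMA,
    LOWER_LIMB_LEVELS,
    Modality,
    MotorFinding,
    MOTOR_ITEM_CODE,
    MOTOR_ITEMS,
    Movement,
    NIS_LL_GRADES,
    Region,
    REGION_LADDERS,
    ScaleVersion,
    ScoreBreakdown,
    SENSORY_ITEM_CODE,
    SENSORY_ITEMS,
    SensoryFinding,
    TRUNK_HEAD_LEVELS,
    UPPER_LIMB_LEVELS,
    VisceralFindings,
    validate_assessment,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OrthostasisConfig:
    """Thresholds for grading the orthostatic systolic blood-pressure drop.

    The drop is supine systolic pressure minus the lowest standing systolic
    pressure (measured after 1 and 3 min upright).  Defaults implement the
    revised scale: drop < 10 mm Hg scores 0, a drop in the closed band
    [10, 20] scores 2, a drop > 20 scores 4, and 6 points require an
    explicit severe-symptom flag (syncope/presyncope needing
    countermeasures).  With supine hypertension the 2-point band onset moves
    to 30 mm Hg (consensus definition of orthostatic hypotension), band
    width preserved.
    """

    two_point_drop_low: float = 10.0   # mm Hg, inclusive
    two_point_drop_high: float = 20.0  # mm Hg, inclusive
    four_point_drop_threshold: float = 20.0  # mm Hg, exclusive
    supine_hypertension_drop_threshold: float = 30.0  # mm Hg
    diastolic_drop_threshold: float = 10.0  # mm Hg, note only

    def __post_init__(self):
        if not (0 < self.two_point_drop_low < self.two_point_drop_high
                <= self.four_point_drop_threshold
                < self.supine_hypertension_drop_threshold):
            raise ValueError("orthostasis thresholds must be positive and "
                             "strictly increasing")
        if self.diastolic_drop_threshold <= 0:
            raise ValueError("diastolic_drop_threshold must be positive")


#: Loose-stools-per-day bands for the 2/4/6-point diarrhoea tiers.  The
#: scale sheets define the tiers as coded categories; these raw-frequency
#: bands are a package convention (diarrhoea itself requires at least three
#: loose stools per day) and can be overridden per call.
DEFAULT_DIARRHOEA_BANDS = ((3, 2.0), (6, 4.0), (10, 6.0))

DEFAULT_ORTHO_CONFIG = OrthostasisConfig()


@dataclasses.dataclass
class ItemResult:
    """Score of one item; ``score is None`` marks a missing item."""

    score: Optional[float]
    notes: list[str] = dataclasses.field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.score is None


# ---------------------------------------------------------------------------
# Sensory items
# ---------------------------------------------------------------------------

#: Revised limb ladder scores: each new intermediate level (foot, knee /
#: hand, upper arm) added 0.5 point between the original integer levels.
_REVISED_LIMB_SCORES = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0)
_TRUNK_SCORES = (0.0, 1.0, 2.0, 3.0)


def limb_sensory_score(region: Region, level: str) -> float:
    """Score the most proximal level of lost sensation in a limb.

    normal -> 0; toes/fingers -> 1; foot/hand -> 1.5; lower leg/forearm -> 2;
    knee/upper arm -> 2.5; thigh/shoulder -> 3.
    """
    region = Region(region)
    if region is Region.TRUNK_HEAD:
        raise CodingError("limb_sensory_score applies to limb regions; use "
                          "trunk_sensory_score for trunk/head")
    ladder = REGION_LADDERS[region]
    try:
        rank = ladder.index(level)
    except ValueError:
        raise CodingError(
            f"level {level!r} is not on the {region.value} ladder {ladder}")
    return _REVISED_LIMB_SCORES[rank]


def trunk_sensory_score(level: str) -> float:
    """Score trunk/head sensory loss: none -> 0, midline trunk -> 1,
    midclavicular line -> 2, neck and face -> 3 (unchanged from 1997;
    original labels umbilical/clavicular are accepted)."""
    from .model import normalize_trunk_level

    level = normalize_trunk_level(level)
    try:
        rank = TRUNK_HEAD_LEVELS.index(level)
    except ValueError:
        raise CodingError(
            f"level {level!r} is not on the trunk/head ladder "
            f"{TRUNK_HEAD_LEVELS}")
    return _TRUNK_SCORES[rank]


def _sensory_item_results(
    findings: Iterable[SensoryFinding],
    level_score,
    trunk_score,
) -> dict[str, ItemResult]:
    """Shared worse-side merge used by both scale versions.

    Items without any recorded finding score 0 (only deficits are recorded);
    when both sides are recorded the worse (more proximal) one counts.
    Light touch on the trunk/head is not a scoreable item: such a finding is
    acknowledged with a note and excluded.
    """
    per_item: dict[str, float] = {code: 0.0 for code, *_ in SENSORY_ITEMS}
    notes: dict[str, list[str]] = {code: [] for code in per_item}
    extra_notes: list[str] = []

    for f in sorted(findings, key=lambda f: (f.modality.value, f.region.value,
                                             f.side.value)):
        if f.region is Region.TRUNK_HEAD and f.modality is Modality.LIGHT_TOUCH:
            extra_notes.append(
                "trunk/head light-touch finding recorded but not a scoreable "
                "item; excluded from the sensory subscore")
            continue
        code = SENSORY_ITEM_CODE[(f.modality, f.region)]
        if f.region is Region.TRUNK_HEAD:
            s = trunk_score(f.normalized_level())
        else:
            s = level_score(f.region, f.level)
        if s > per_item[code]:
            per_item[code] = s
    results = {code: ItemResult(score=score, notes=notes[code])
               for code, score in per_item.items()}
    if extra_notes:
        first = next(iter(results.values()))
        first.notes.extend(extra_notes)
    return results


def sensory_subscore(findings: Iterable[SensoryFinding]) -> float:
    """Sum of the 8 sensory items (worse side per item), 0-24 in half-point
    steps under the revised scale."""
    results = _sensory_item_results(findings, limb_sensory_score,
                                    trunk_sensory_score)
    return sum(r.score for r in results.values())


# ---------------------------------------------------------------------------
# Motor items
# ---------------------------------------------------------------------------

#: MRC grade -> Kumamoto motor score (Kumamoto score 1 is unreachable by
#: design: normal power scores 0 and the first deficit tier scores 2).
_MRC_TO_KUMAMOTO = {5: 0.0, 4: 2.0, 3: 3.0, 2: 4.0, 1: 5.0, 0: 6.0}
_NISLL_TO_KUMAMOTO = dict(zip(NIS_LL_GRADES, (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)))


def mrc_to_kumamoto(mrc_grade: int) -> float:
    """Map an MRC muscle-power grade (5 = normal … 0 = no contraction) onto
    the Kumamoto motor ladder {0, 2, 3, 4, 5, 6}."""
    if not isinstance(mrc_grade, int) or isinstance(mrc_grade, bool) \
            or mrc_grade not in _MRC_TO_KUMAMOTO:
        raise CodingError(f"MRC grade must be an integer 0-5, got {mrc_grade!r}")
    return _MRC_TO_KUMAMOTO[mrc_grade]


def nisll_to_kumamoto(nis_grade: float) -> float:
    """Map a NIS-LL motor grade {0, 2, 3.25, 3.50, 3.75, 4} onto the
    Kumamoto motor ladder {0, 2, 3, 4, 5, 6}."""
    try:
        return _NISLL_TO_KUMAMOTO[float(nis_grade)]
    except (KeyError, TypeError, ValueError):
        raise CodingError(
            f"NIS-LL grade must be one of {NIS_LL_GRADES}, got {nis_grade!r}")


def _motor_item_results(findings: Iterable[MotorFinding]) -> dict[str, ItemResult]:
    per_item: dict[str, Optional[float]] = {code: None for code, _ in MOTOR_ITEMS}
    for f in sorted(findings, key=lambda f: (f.movement.value, f.side.value)):
        if f.mrc_grade is not None:
            s = mrc_to_kumamoto(f.mrc_grade)
        else:
            s = nisll_to_kumamoto(f.nis_ll_grade)
        code = MOTOR_ITEM_CODE[f.movement]
        prev = per_item[code]
        per_item[code] = s if prev is None else max(prev, s)
    results = {}
    for code, score in per_item.items():
        notes = [] if score is not None else []
        results[code] = ItemResult(score=score, notes=notes)
        if score is None:
            results[code].notes.append(f"{code}: movement not tested")
    return results


def motor_subscore(findings: Iterable[MotorFinding]) -> float:
    """Sum of the four movement scores (worse side per movement), 0-24.

    Raises :class:`CodingError` via the grade maps on bad grades; an
    untested movement makes the subscore undefined here (use
    :func:`score_assessment` for missing-item bookkeeping).
    """
    results = _motor_item_results(findings)
    missing = [c for c, r in results.items() if r.missing]
    if missing:
        raise CodingError(f"untested movements: {missing}")
    return sum(r.score for r in results.values())


# ---------------------------------------------------------------------------
# Autonomic items
# ---------------------------------------------------------------------------

_GI_CODE_SCORE_REVISED = {
    GiLevel.NONE: 0.0,
    GiLevel.CONSTIPATION: 1.0,
    GiLevel.DIARRHOEA_MILD: 2.0,
    GiLevel.DIARRHOEA_MODERATE: 4.0,
    GiLevel.DIARRHOEA_SEVERE: 6.0,
}


def _gi_raw_score(findings: AutonomicFindings, constipation_score: float,
                  diarrhoea_bands) -> tuple[Optional[float], list[str]]:
    """Score GI symptoms from the raw stool pattern; None when no raw
    field is present."""
    notes: list[str] = []
    raw_given = any(v is not None for v in (
        findings.stools_per_week, findings.stools_hard,
        findings.loose_stools_per_day))
    if not raw_given:
        return None, notes

    score = 0.0
    loose = findings.loose_stools_per_day
    if loose is not None and loose >= 3:
        for low, band_score in reversed(diarrhoea_bands):
            if loose >= low:
                score = max(score, band_score)
                break
        notes.append(f"diarrhoea: {loose} loose stools/day")
    elif loose is not None and loose > 0:
        notes.append(f"{loose} loose stools/day below the diarrhoea "
                     "definition (>=3/day); not scored as diarrhoea")
    if findings.stools_per_week is not None and findings.stools_per_week < 3:
        if findings.stools_hard is None:
            notes.append("constipation scored on stool frequency alone; "
                         "stool consistency not recorded")
        elif findings.stools_hard is False:
            notes.append("fewer than 3 stools/week but stools not hard; "
                         "scored as constipation on frequency")
        score = max(score, constipation_score)
    return score, notes


def gi_score(findings: AutonomicFindings,
             diarrhoea_bands=DEFAULT_DIARRHOEA_BANDS) -> ItemResult:
    """Gastrointestinal symptom score on the revised ladder {0, 1, 2, 4, 6}.

    Constipation — fewer than three (hard) stools per week — scores 1;
    diarrhoea (at least three loose stools per day) scores 2/4/6 by tier.
    When an alternating pattern qualifies for both, the worst applicable
    tier counts.  Raw stool-pattern fields win over a conflicting pre-coded
    ``gi_level_code`` (with a conflict note).
    """
    return _gi_score_impl(findings, _GI_CODE_SCORE_REVISED, 1.0,
                          diarrhoea_bands)


def _gi_score_impl(findings: AutonomicFindings, code_scores: dict,
                   constipation_score: float, diarrhoea_bands) -> ItemResult:
    raw_score, notes = _gi_raw_score(findings, constipation_score,
                                     diarrhoea_bands)
    code_score = None
    if findings.gi_level_code is not None:
        code_score = code_scores[findings.gi_level_code]
    if raw_score is not None:
        if code_score is not None and code_score != raw_score:
            notes.append(
                f"gi_level_code {findings.gi_level_code.value!r} conflicts "
                f"with raw stool pattern; raw measurement wins "
                f"({raw_score:g} over {code_score:g})")
        return ItemResult(score=raw_score, notes=notes)
    if code_score is not None:
        return ItemResult(score=code_score, notes=notes)
    notes.append("auto_gi: no stool-pattern fields or gi_level_code given")
    return ItemResult(score=None, notes=notes)


def orthostatic_drop(findings: AutonomicFindings) -> Optional[float]:
    """Systolic drop: supine pressure minus the lowest standing pressure
    (worst of the 1- and 3-min measurements); None if not measurable."""
    if findings.sbp_supine is None:
        return None
    standing = [p for p in (findings.sbp_standing_1min,
                            findings.sbp_standing_3min) if p is not None]
    if not standing:
        return None
    return findings.sbp_supine - min(standing)


def orthostasis_score(findings: AutonomicFindings,
                      cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG) -> ItemResult:
    """Orthostatic hypotension score on the ladder {0, 2, 4, 6}.

    Revised bands: systolic drop < 10 mm Hg -> 0; 10-20 (inclusive) -> 2;
    > 20 -> 4; 6 requires the severe-symptom flag (orthostatic syncope).
    With supine hypertension the 2-point onset moves to 30 mm Hg.
    """
    notes: list[str] = []
    drop = orthostatic_drop(findings)
    if drop is None:
        notes.append("auto_orthostasis: supine and standing systolic "
                     "pressures required")
        return ItemResult(score=None, notes=notes)

    low, high = cfg.two_point_drop_low, cfg.two_point_drop_high
    four_at = cfg.four_point_drop_threshold
    if findings.supine_hypertension:
        shift = cfg.supine_hypertension_drop_threshold - low
        low, high, four_at = low + shift, high + shift, four_at + shift
        notes.append("supine hypertension: 2-point band onset raised to "
                     f"{low:g} mm Hg")
    if findings.orthostatic_syncope:
        score = 6.0
        notes.append("orthostatic syncope/presyncope requiring "
                     "countermeasures: 6 points")
    elif drop > four_at:
        score = 4.0
    elif low <= drop <= high:
        score = 2.0
    else:
        score = 0.0
    if (findings.dbp_supine is not None and findings.dbp_standing is not None
            and findings.dbp_supine - findings.dbp_standing
            >= cfg.diastolic_drop_threshold):
        notes.append("diastolic drop meets the orthostatic-hypotension "
                     "definition (>=10 mm Hg); systolic bands govern the score")
    if findings.on_antihypertensives:
        notes.append("on antihypertensives: other causes of hypotension "
                     "should be considered")
    return ItemResult(score=score, notes=notes)


def urination_score(findings: AutonomicFindings) -> ItemResult:
    """Urination-problem score on the ladder {0, 2, 4, 6}.

    Post-void residual urine (double voiding then bladder scan): < 150 ml
    -> 0; sporadic incontinence or residual in [150, 300) ml -> 2; retention
    with residual in [300, 500] ml -> 4; catheterisation or > 500 ml -> 6.
    Band edges follow the documented low-inclusive convention.
    """
    notes: list[str] = []
    residual = findings.residual_urine_ml
    if residual is None and not findings.catheterized:
        notes.append("auto_urination: residual urine volume (bladder scan) "
                     "or catheter status required")
        return ItemResult(score=None, notes=notes)
    score = 0.0
    if findings.catheterized or (residual is not None and residual > 500):
        score = 6.0
    elif residual is not None and 300 <= residual <= 500:
        score = 4.0
    elif findings.sporadic_incontinence or (
            residual is not None and 150 <= residual < 300):
        score = 2.0
    if findings.prostate_hyperplasia_excluded is False:
        notes.append("benign prostate hyperplasia not excluded as a cause "
                     "of urinary retention")
    return ItemResult(score=score, notes=notes)


def sicca_scores(findings: AutonomicFindings) -> tuple[ItemResult, ItemResult]:
    """Dry-eyes and dry-mouth grades (0 none / 1 mild / 2 moderate /
    3 severe).  Drug-induced dry mouth is excluded (scored 0 with a note)."""
    def _one(grade: Optional[int], name: str) -> ItemResult:
        if grade is None:
            return ItemResult(score=None, notes=[f"{name}: grade not recorded"])
        if grade not in (0, 1, 2, 3):
            raise CodingError(f"{name} grade must be in 0-3, got {grade!r}")
        return ItemResult(score=float(grade))

    eyes = _one(findings.dry_eyes_grade, "auto_dry_eyes")
    mouth = _one(findings.dry_mouth_grade, "auto_dry_mouth")
    if (mouth.score is not None and mouth.score > 0
            and findings.dry_mouth_drug_induced):
        mouth = ItemResult(score=0.0, notes=[
            "dry mouth judged a medication side effect; excluded (0 points)"])
    return eyes, mouth


def _autonomic_item_results(
    findings: AutonomicFindings,
    cfg: OrthostasisConfig,
    gi,
    ortho,
    diarrhoea_bands,
) -> dict[str, ItemResult]:
    eyes, mouth = sicca_scores(findings)
    return {
        "auto_gi": gi(findings, diarrhoea_bands),
        "auto_orthostasis": ortho(findings, cfg),
        "auto_urination": urination_score(findings),
        "auto_dry_eyes": eyes,
        "auto_dry_mouth": mouth,
    }


def autonomic_subscore(findings: AutonomicFindings,
                       cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG) -> float:
    """GI + orthostasis + urination + dry eyes + dry mouth, 0-24."""
    results = _autonomic_item_results(findings, cfg, _gi_dispatch_revised,
                                      orthostasis_score,
                                      DEFAULT_DIARRHOEA_BANDS)
    missing = [c for c, r in results.items() if r.missing]
    if missing:
        raise CodingError(f"autonomic items not computable: {missing}")
    return sum(r.score for r in results.values())


def _gi_dispatch_revised(findings, bands):
    return gi_score(findings, bands)


# ---------------------------------------------------------------------------
# Visceral items
# ---------------------------------------------------------------------------

_CARDIAC_SCORE = {
    CardiacLevel.NORMAL: 0.0,
    CardiacLevel.CONDUCTION_DISTURBANCE: 4.0,
    CardiacLevel.ADVANCED_CONDUCTION: 8.0,
    CardiacLevel.DEVICE_OR_CHF: 12.0,
}


def heart_score(findings: VisceralFindings) -> ItemResult:
    """Cardiac involvement on the ladder {0, 4, 8, 12}.

    normal -> 0; conduction disturbance (e.g. first-degree AV block) -> 4;
    advanced conduction disturbance -> 8; third-degree AV block or pacemaker
    (with or without heart failure, which only counts alongside them) -> 12.
    """
    if findings.cardiac_level_code is None:
        return ItemResult(score=None, notes=[
            "visc_heart: cardiac_level_code required"])
    return ItemResult(score=_CARDIAC_SCORE[findings.cardiac_level_code])


def kidney_score(findings: VisceralFindings) -> ItemResult:
    """Renal involvement on the ladder {0, 4, 8, 12}.

    On dialysis -> 12; nephrotic syndrome (proteinuria > 3.5 g/24 h plus
    hypoalbuminemia plus oedema) -> 8; proteinuria alone (dipstick or
    quantified) -> 4; otherwise 0.
    """
    notes: list[str] = []
    if findings.on_dialysis:
        return ItemResult(score=12.0, notes=notes)
    if findings.nephrotic_syndrome():
        notes.append("nephrotic syndrome: proteinuria >3.5 g/24 h + "
                     "hypoalbuminemia + oedema")
        return ItemResult(score=8.0, notes=notes)
    if findings.dipstick_proteinuria or (
            findings.proteinuria_g_per_24h is not None
            and findings.proteinuria_g_per_24h > 0):
        return ItemResult(score=4.0, notes=notes)
    return ItemResult(score=0.0, notes=notes)


def _visceral_item_results(findings: VisceralFindings) -> dict[str, ItemResult]:
    return {"visc_heart": heart_score(findings),
            "visc_kidney": kidney_score(findings)}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _assemble(a: Assessment, scale: ScaleVersion,
              sensory_results, motor_results, autonomic_results,
              visceral_results) -> ScoreBreakdown:
    groups = {
        "sensory": sensory_results,
        "motor": motor_results,
        "autonomic": autonomic_results,
        "visceral": visceral_results,
    }
    item_scores: dict[str, float] = {}
    missing: list[str] = []
    notes: list[str] = []
    subscores: dict[str, float] = {}
    for domain, results in groups.items():
        total = 0.0
        for code, res in results.items():
            notes.extend(res.notes)
            if res.missing:
                missing.append(code)
            else:
                item_scores[code] = res.score
                total += res.score
        subscores[domain] = total
    if missing:
        notes.append("incomplete: missing items " + ", ".join(missing)
                     + "; subscores cover scoreable items only, no proration")
    return ScoreBreakdown(
        scale_version=scale,
        item_scores=item_scores,
        sensory_subscore=subscores["sensory"],
        motor_subscore=subscores["motor"],
        autonomic_subscore=subscores["autonomic"],
        visceral_subscore=subscores["visceral"],
        total=sum(subscores.values()),
        missing_items=missing,
        notes=notes,
    )


def score_assessment(a: Assessment,
                     cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG,
                     diarrhoea_bands=DEFAULT_DIARRHOEA_BANDS) -> ScoreBreakdown:
    """Score one assessment under the revised Kumamoto scale.

    Deterministic and independent of finding order.  Raises
    :class:`InvalidAssessmentError` when validation finds problems; items
    whose required inputs are absent are reported in ``missing_items`` and
    the result is flagged incomplete.
    """
    findings = validate_assessment(a)
    if findings:
        raise InvalidAssessmentError(findings)
    return _assemble(
        a, ScaleVersion.REVISED,
        _sensory_item_results(a.sensory, limb_sensory_score,
                              trunk_sensory_score),
        _motor_item_results(a.motor),
        _autonomic_item_results(a.autonomic, cfg, _gi_dispatch_revised,
                                orthostasis_score, diarrhoea_bands),
        _visceral_item_results(a.visceral),
    )
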