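"""Original (1997) Kumamoto scale scoring and original-vs-revised comparison.

Only three parts of the instrument changed in the revision: the limb sensory
ladders (three integer levels originally; the original score is the floor of
the revised half-point score), the gastrointestinal item (constipation is
not a separate symptom in the original scale), and the orthostatic band
(2 points for any systolic drop in the 0-20 mm Hg interval, taken literally;
a measured drop of exactly 0 scores 0).  Motor, urination, sicca, heart,
kidney and trunk/head sensory scoring are shared with the revised engine.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

from .model import (
    Assessment,
    AutonomicFindings,
    GiLevel,
    InvalidAssessmentError,
    Region,
    ScaleVersion,
    ScoreBreakdown,
    SensoryFinding,
    validate_assessment,
)
from .scoring_revised import (
    DEFAULT_DIARRHOEA_BANDS,
    DEFAULT_ORTHO_CONFIG,
    ItemResult,
    OrthostasisConfig,
    _assemble,
    _autonomic_item_results,
    _gi_score_impl,
    _motor_item_results,
    _sensory_item_results,
    _visceral_item_results,
    limb_sensory_score,
    orthostatic_drop,
    trunk_sensory_score,
)


def limb_sensory_score_original(region: Region, level: str) -> float:
    """Original three-level limb score: the coarsening of the revised
    ladder — normal -> 0; toes/foot -> 1; lower leg/knee -> 2; thigh -> 3
    (fingers/hand -> 1; forearm/upper arm -> 2; shoulder -> 3).

    Equals ``floor`` of the revised half-point score.
    """
    return float(math.floor(limb_sensory_score(region, level)))


_GI_CODE_SCORE_ORIGINAL = {
    GiLevel.NONE: 0.0,
    GiLevel.CONSTIPATION: 0.0,
    GiLevel.DIARRHOEA_MILD: 2.0,
    GiLevel.DIARRHOEA_MODERATE: 4.0,
    GiLevel.DIARRHOEA_SEVERE: 6.0,
}


def gi_score_original(findings: AutonomicFindings,
                      diarrhoea_bands=DEFAULT_DIARRHOEA_BANDS) -> ItemResult:
    """Original GI ladder {0, 2, 4, 6}: constipation alone scores 0 (it is
    not a symptom of the 1997 scale); diarrhoea tiers as in the revision."""
    res = _gi_score_impl(findings, _GI_CODE_SCORE_ORIGINAL, 0.0,
                         diarrhoea_bands)
    if (res.score == 0.0 and findings.stools_per_week is not None
            and findings.stools_per_week < 3):
        res.notes.append("constipation present but not a scoreable symptom "
                         "of the original scale")
    return res


def orthostasis_score_original(
        findings: AutonomicFindings,
        cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG) -> ItemResult:
    """Original orthostatic ladder {0, 2, 4, 6}: any measured systolic drop
    in (0, 20] mm Hg scores 2; a drop > 20 scores 4; the severe-symptom
    flag scores 6.  A drop of exactly 0 (or a rise) scores 0."""
    notes: list[str] = []
    drop = orthostatic_drop(findings)
    if drop is None:
        notes.append("auto_orthostasis: supine and standing systolic "
                     "pressures required")
        return ItemResult(score=None, notes=notes)
    if findings.orthostatic_syncope:
        score = 6.0
        notes.append("orthostatic syncope/presyncope requiring "
                     "countermeasures: 6 points")
    elif drop > cfg.four_point_drop_threshold:
        score = 4.0
    elif drop > 0:
        score = 2.0
    else:
        score = 0.0
    if findings.on_antihypertensives:
        notes.append("on antihypertensives: other causes of hypotension "
                     "should be considered")
    return ItemResult(score=score, notes=notes)


def sensory_subscore_original(findings: Iterable[SensoryFinding]) -> float:
    """Sum of the 8 sensory items under the original integer ladders."""
    results = _sensory_item_results(findings, limb_sensory_score_original,
                                    trunk_sensory_score)
    return sum(r.score for r in results.values())


def _gi_dispatch_original(findings, bands):
    return gi_score_original(findings, bands)


def score_assessment_original(
        a: Assessment,
        cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG,
        diarrhoea_bands=DEFAULT_DIARRHOEA_BANDS) -> ScoreBreakdown:
    """Score one assessment under the original 1997 Kumamoto scale.

    Motor, urination, sicca, heart and kidney items are scored identically
    to the revised engine (those scorings were left unchanged); sensory, GI
    and orthostasis use the original rules.
    """
    findings = validate_assessment(a)
    if findings:
        raise InvalidAssessmentError(findings)
    return _assemble(
        a, ScaleVersion.ORIGINAL,
        _sensory_item_results(a.sensory, limb_sensory_score_original,
                              trunk_sensory_score),
        _motor_item_results(a.motor),
        _autonomic_item_results(a.autonomic, cfg, _gi_dispatch_original,
                                orthostasis_score_original, diarrhoea_bands),
        _visceral_item_results(a.visceral),
    )


@dataclasses.dataclass
class ScaleComparison:
    """Paired original/revised breakdowns with item-wise and subdomain-wise
    deltas (revised minus original)."""

    original: ScoreBreakdown
    revised: ScoreBreakdown
    item_deltas: dict[str, float]
    subscore_deltas: dict[str, float]
    total_delta: float


def compare_scales(a: Assessment,
                   cfg: OrthostasisConfig = DEFAULT_ORTHO_CONFIG,
                   diarrhoea_bands=DEFAULT_DIARRHOEA_BANDS) -> ScaleComparison:
    """Score one assessment under both scale versions and report deltas.

    Items missing under either engine are omitted from the item deltas;
    incompleteness is visible on the contained breakdowns.
    """
    from .scoring_revised import score_assessment

    original = score_assessment_original(a, cfg, diarrhoea_bands)
    revised = score_assessment(a, cfg, diarrhoea_bands)
    item_deltas = {
        code: revised.item_scores[code] - original.item_scores[code]
        for code in original.item_scores
        if code in revised.item_scores
    }
    subscore_deltas = {
        domain: revised.subscores()[domain] - original.subscores()[domain]
        for domain in original.subscores()
    }
    return ScaleComparison(
        original=original,
        revised=revised,
        item_deltas=item_deltas,
        subscore_deltas=subscore_deltas,
        total_delta=revised.total - original.total,
    )
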