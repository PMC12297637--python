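"""Multi-visit score trajectories and disease-progression evaluation.

Swedish follow-up guidelines for ATTRv amyloidosis define significant
disease progression as subjective deterioration together with a more than
4-point increase on the Kumamoto score, unintentional weight loss of at
least 5% of the body weight, and/or onset of new symptoms or signs of
further organ involvement (the eyes excluded).  The "together with" clause
is read as binding subjective deterioration to the score criterion only;
weight loss and new organ involvement stand alone (the printed "and/or"
list).  Both readings are configurable.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Literal, Optional, Sequence

from .model import Assessment, ScaleVersion, ScoreBreakdown
from .scoring_original import score_assessment_original
from .scoring_revised import score_assessment


@dataclasses.dataclass(frozen=True)
class ProgressionCriteria:
    """Thresholds of the progression rule.

    ``score_increase_threshold`` is a strict inequality: a delta of exactly
    4 points does not flag progression (half-point revised-scale deltas
    such as 4.5 compare numerically and do).
    """

    score_increase_threshold: float = 4.0   # points, strict ">"
    weight_loss_fraction: float = 0.05      # fraction of baseline weight
    require_subjective_deterioration: bool = True  # score criterion only
    exclude_eye_involvement: bool = True

    def __post_init__(self):
        if self.score_increase_threshold <= 0:
            raise ValueError("score_increase_threshold must be positive")
        if not 0 < self.weight_loss_fraction < 1:
            raise ValueError("weight_loss_fraction must be in (0, 1)")


@dataclasses.dataclass
class Visit:
    """One scored visit inside a trajectory."""

    assessment: Assessment
    breakdown: ScoreBreakdown
    delta_vs_baseline: Optional[float]  # None at baseline
    delta_vs_previous: Optional[float]


@dataclasses.dataclass
class Trajectory:
    patient_id: str
    scale_version: ScaleVersion
    visits: list[Visit]

    @property
    def totals(self) -> list[float]:
        return [v.breakdown.total for v in self.visits]

    @property
    def deltas_vs_baseline(self) -> list[float]:
        return [v.delta_vs_baseline for v in self.visits[1:]]


def trajectory(assessments: Sequence[Assessment],
               scale: ScaleVersion | str = ScaleVersion.REVISED) -> Trajectory:
    """Score an ordered visit series for one patient.

    Requires at least one assessment, a single patient id and strictly
    increasing visit dates.  Deltas are total-score differences; incomplete
    visits keep their partial totals and stay flagged via the breakdowns.
    """
    if not assessments:
        raise ValueError("trajectory requires at least one assessment")
    scale = ScaleVersion(scale)
    pid = assessments[0].patient_id
    for a in assessments[1:]:
        if a.patient_id != pid:
            raise ValueError(
                f"mixed patient ids in trajectory: {pid!r} vs {a.patient_id!r}")
    dates = [a.visit_date for a in assessments]
    if any(d2 <= d1 for d1, d2 in zip(dates, dates[1:])):
        raise ValueError("visit dates must be strictly increasing")

    score = (score_assessment if scale is ScaleVersion.REVISED
             else score_assessment_original)
    visits: list[Visit] = []
    baseline_total: Optional[float] = None
    prev_total: Optional[float] = None
    for a in assessments:
        b = score(a)
        visits.append(Visit(
            assessment=a,
            breakdown=b,
            delta_vs_baseline=(None if baseline_total is None
                               else b.total - baseline_total),
            delta_vs_previous=(None if prev_total is None
                               else b.total - prev_total),
        ))
        if baseline_total is None:
            baseline_total = b.total
        prev_total = b.total
    return Trajectory(patient_id=pid, scale_version=scale, visits=visits)


@dataclasses.dataclass
class ProgressionVerdict:
    """Per-visit verdict: whether progression is flagged and which
    criteria fired."""

    visit_date: _dt.date
    progressed: bool
    criteria_fired: list[str]
    notes: list[str]


def evaluate_progression(
    traj: Trajectory,
    criteria: ProgressionCriteria = ProgressionCriteria(),
    baseline: Literal["first", "previous"] = "first",
) -> list[ProgressionVerdict]:
    """Apply the progression rule to every follow-up visit of a trajectory.

    A visit is flagged iff (score delta > threshold AND subjective
    deterioration, when required) OR weight loss >= the configured fraction
    of baseline weight OR new organ involvement (eyes excluded by flag
    semantics).  Score and weight deltas are taken against the first visit
    by default, or against the previous visit with ``baseline="previous"``.
    Missing weights disable only the weight criterion, with a note.
    """
    verdicts: list[ProgressionVerdict] = []
    first = traj.visits[0]
    baseline_weight = first.assessment.weight_kg
    for i, v in enumerate(traj.visits):
        notes = ['score criterion parsed as "subjective deterioration '
                 'together with >%g-point increase"; weight loss and new '
                 'organ involvement stand alone'
                 % criteria.score_increase_threshold]
        fired: list[str] = []
        if i == 0:
            verdicts.append(ProgressionVerdict(
                visit_date=v.assessment.visit_date, progressed=False,
                criteria_fired=[], notes=["baseline visit"]))
            continue
        ref = first if baseline == "first" else traj.visits[i - 1]
        delta = v.breakdown.total - ref.breakdown.total
        ref_weight = (baseline_weight if baseline == "first"
                      else traj.visits[i - 1].assessment.weight_kg)

        deteriorated = bool(v.assessment.subjective_deterioration)
        score_fires = delta > criteria.score_increase_threshold
        if criteria.require_subjective_deterioration:
            score_fires = score_fires and deteriorated
        if score_fires:
            fired.append("score_increase")

        if ref_weight is None or v.assessment.weight_kg is None:
            notes.append("weight criterion disabled: weight missing at "
                         "reference or current visit")
        else:
            loss = ref_weight - v.assessment.weight_kg
            if loss >= criteria.weight_loss_fraction * ref_weight:
                fired.append("weight_loss")

        if v.assessment.new_organ_involvement:
            fired.append("new_organ_involvement")
            if criteria.exclude_eye_involvement:
                notes.append("new_organ_involvement flag must already "
                             "exclude eye involvement")

        verdicts.append(ProgressionVerdict(
            visit_date=v.assessment.visit_date,
            progressed=bool(fired),
            criteria_fired=fired,
            notes=notes,
        ))
    return verdicts


def mbmi(weight_kg: float, height_m: float,
         serum_albumin_g_per_L: float) -> float:
    """Modified body mass index: BMI (kg/m^2) times serum albumin (g/L).

    The standard nutritional marker in ATTRv follow-up; corrects BMI for
    oedema-driven weight.  All inputs must be positive.
    """
    if weight_kg <= 0 or height_m <= 0 or serum_albumin_g_per_L <= 0:
        raise ValueError("mbmi inputs must all be positive")
    return weight_kg / height_m ** 2 * serum_albumin_g_per_L
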