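"""Synthetic multi-visit ATTRv cohorts for exercising the scoring engines.

No public dataset of Kumamoto-scale case-report forms exists, so testing
relies on simulation.  Each patient carries a latent severity in [0, 24]
per subdomain that advances linearly with time (clamped); the latent value
is converted to raw clinical findings by inverting the item ladders —
distal-to-proximal spread of sensory loss, MRC decline, threshold crossings
for blood-pressure drop, residual urine and stool pattern.  Rater noise
miscodes an item to an adjacent ordinal level with a configurable
probability, mimicking inter-rater disagreement on neighbouring anatomical
levels.  Identical seeds give identical cohorts.

The latent-to-ladder mapping allocates the domain latent greedily across
the domain's items in registry order and quantises each item's load to the
largest ladder score not exceeding it.  With zero noise the scored
subscore therefore equals the latent severity quantised to the scale's
grid exactly (:func:`expected_subscore` computes that quantisation), which
is the round-trip property the test suite checks.

The defaults emulate a moderate polyneuropathy cohort under annual
follow-up: baseline severities centred near the worked comparison case
(sensory approx. 4.5, visceral 8 across two items), sensory progression of
2 points/year — fastest, as sensory neuropathy dominates early disease —
and slower autonomic/visceral/motor progression.  These are simulation
conventions: the instrument's sources provide no natural-history increments.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import (
    Assessment,
    AutonomicFindings,
    CardiacLevel,
    Modality,
    MotorFinding,
    Movement,
    Region,
    ScaleVersion,
    SensoryFinding,
    VisceralFindings,
    LOWER_LIMB_LEVELS,
    UPPER_LIMB_LEVELS,
    TRUNK_HEAD_LEVELS,
)
from .scoring_original import sensory_subscore_original
from .scoring_revised import sensory_subscore

SUBDOMAIN_NAMES = ("sensory", "motor", "autonomic", "visceral")


class CohortConfig(BaseModel):
    """Simulation parameters for one synthetic cohort.

    Latent severities are points on the 0-24 subdomain scale; progression
    rates are points/year; ``rater_noise_prob`` is the per-item probability
    of an adjacent-level miscoding.
    """

    model_config = ConfigDict(extra="forbid")

    n_patients: int = 50
    n_visits: int = 4
    visit_interval_months: float = 12.0
    start_date: _dt.date = _dt.date(2024, 1, 6)
    baseline_severity_mean: dict[str, float] = Field(
        default_factory=lambda: {"sensory": 4.0, "motor": 1.0,
                                 "autonomic": 4.0, "visceral": 4.0})
    baseline_severity_sd: float = 2.0
    annual_progression_rate: dict[str, float] = Field(
        default_factory=lambda: {"sensory": 2.0, "motor": 1.0,
                                 "autonomic": 1.5, "visceral": 1.0})
    rater_noise_prob: float = 0.05
    baseline_weight_mean_kg: float = 75.0
    baseline_weight_sd_kg: float = 10.0
    annual_weight_change_frac: float = -0.02
    serum_albumin_g_per_L: float = 40.0
    seed: int = 0

    def check(self) -> None:
        if self.n_patients < 1 or self.n_visits < 1:
            raise ValueError("n_patients and n_visits must be >= 1")
        if self.visit_interval_months <= 0:
            raise ValueError("visit_interval_months must be positive")
        if not 0 <= self.rater_noise_prob <= 1:
            raise ValueError("rater_noise_prob must be in [0, 1]")
        for d in SUBDOMAIN_NAMES:
            if self.annual_progression_rate.get(d, 0.0) < 0:
                raise ValueError(f"progression rate for {d} must be >= 0")
            if not 0 <= self.baseline_severity_mean.get(d, 0.0) <= 24:
                raise ValueError(f"baseline mean for {d} must be in [0, 24]")


# ---------------------------------------------------------------------------
# Item ladders as seen by the generator
# ---------------------------------------------------------------------------

#: (ladder of revised scores, per-item capacity) per domain, in the greedy
#: allocation order.  The generator picks the ordinal *index*; realisation
#: into raw findings and the scored value follow from the index.
_LIMB_LADDER = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0)
_TRUNK_LADDER = (0.0, 1.0, 2.0, 3.0)
_MOTOR_LADDER = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)
_GI_LADDER = (0.0, 1.0, 2.0, 4.0, 6.0)
_AUTO246_LADDER = (0.0, 2.0, 4.0, 6.0)
_SICCA_LADDER = (0.0, 1.0, 2.0, 3.0)
_VISC_LADDER = (0.0, 4.0, 8.0, 12.0)

#: Original-scale score of each ordinal index, for expected-value grids.
_LIMB_LADDER_ORIGINAL = (0.0, 1.0, 1.0, 2.0, 2.0, 3.0)
_GI_LADDER_ORIGINAL = (0.0, 0.0, 2.0, 4.0, 6.0)

_DOMAIN_LADDERS = {
    "sensory": [_LIMB_LADDER] * 6 + [_TRUNK_LADDER] * 2,
    "motor": [_MOTOR_LADDER] * 4,
    "autonomic": [_GI_LADDER, _AUTO246_LADDER, _AUTO246_LADDER,
                  _SICCA_LADDER, _SICCA_LADDER],
    "visceral": [_VISC_LADDER, _VISC_LADDER],
}


def _quantise_index(u: float, ladder: tuple[float, ...]) -> int:
    """Index of the largest ladder score <= u (u clamped below at 0)."""
    idx = 0
    for i, s in enumerate(ladder):
        if u >= s:
            idx = i
    return idx


def _allocate(latent: float, ladders) -> list[float]:
    """Greedy sequential allocation of a domain latent across its items."""
    loads = []
    offset = 0.0
    for ladder in ladders:
        cap = ladder[-1]
        loads.append(min(cap, max(0.0, latent - offset)))
        offset += cap
    return loads


def latent_to_indices(domain: str, latent: float) -> list[int]:
    """Ordinal level index per item of ``domain`` for a latent severity."""
    ladders = _DOMAIN_LADDERS[domain]
    return [_quantise_index(u, lad)
            for u, lad in zip(_allocate(latent, ladders), ladders)]


def expected_subscore(domain: str, latent: float,
                      scale: ScaleVersion | str = ScaleVersion.REVISED) -> float:
    """Noise-free subscore implied by a latent severity: the latent
    quantised to the scale's step grid through the item ladders."""
    scale = ScaleVersion(scale)
    indices = latent_to_indices(domain, latent)
    ladders = _DOMAIN_LADDERS[domain]
    if scale is ScaleVersion.REVISED:
        return sum(lad[i] for i, lad in zip(indices, ladders))
    out = 0.0
    for i, lad in zip(indices, ladders):
        if domain == "sensory" and lad is _LIMB_LADDER:
            out += _LIMB_LADDER_ORIGINAL[i]
        elif domain == "autonomic" and lad is _GI_LADDER:
            out += _GI_LADDER_ORIGINAL[i]
        else:
            out += lad[i]
    return out


# ---------------------------------------------------------------------------
# Realisation of ordinal indices into raw findings
# ---------------------------------------------------------------------------

_SENSORY_ORDER = (
    (Modality.COLD, Region.LOWER_LIMB),
    (Modality.PINPRICK, Region.LOWER_LIMB),
    (Modality.LIGHT_TOUCH, Region.LOWER_LIMB),
    (Modality.COLD, Region.UPPER_LIMB),
    (Modality.PINPRICK, Region.UPPER_LIMB),
    (Modality.LIGHT_TOUCH, Region.UPPER_LIMB),
    (Modality.COLD, Region.TRUNK_HEAD),
    (Modality.PINPRICK, Region.TRUNK_HEAD),
)
_MOTOR_ORDER = (Movement.ANKLE_DORSIFLEXION, Movement.WRIST_DORSIFLEXION,
                Movement.KNEE_EXTENSION, Movement.ELBOW_FLEXION)
#: Kumamoto motor index -> MRC grade
_INDEX_TO_MRC = (5, 4, 3, 2, 1, 0)
#: Orthostatic systolic drops realising indices 0-3 (mm Hg); index 3 adds
#: the severe-symptom flag.  Index 0 uses a drop of 0 so that an
#: asymptomatic patient scores 0 under both scale versions.
_ORTHO_DROPS = (0.0, 15.0, 25.0, 25.0)
_URINE_RESIDUALS = (50.0, 200.0, 400.0, 600.0)
_CARDIAC_CODES = (CardiacLevel.NORMAL, CardiacLevel.CONDUCTION_DISTURBANCE,
                  CardiacLevel.ADVANCED_CONDUCTION, CardiacLevel.DEVICE_OR_CHF)


def _sensory_findings(indices: list[int]) -> list[SensoryFinding]:
    findings = []
    for (modality, region), idx in zip(_SENSORY_ORDER, indices):
        if region is Region.LOWER_LIMB:
            level = LOWER_LIMB_LEVELS[idx]
        elif region is Region.UPPER_LIMB:
            level = UPPER_LIMB_LEVELS[idx]
        else:
            level = TRUNK_HEAD_LEVELS[idx]
        findings.append(SensoryFinding(modality=modality, region=region,
                                       level=level))
    return findings


def _motor_findings(indices: list[int]) -> list[MotorFinding]:
    return [MotorFinding(movement=mv, mrc_grade=_INDEX_TO_MRC[idx])
            for mv, idx in zip(_MOTOR_ORDER, indices)]


def _autonomic_findings(indices: list[int]) -> AutonomicFindings:
    gi_idx, ortho_idx, urine_idx, eyes_idx, mouth_idx = indices
    kw: dict = {}
    if gi_idx == 0:
        kw.update(stools_per_week=7, stools_hard=False)
    elif gi_idx == 1:
        kw.update(stools_per_week=2, stools_hard=True)
    else:
        # diarrhoea tiers 2/4/6: frequencies at the default band edges
        kw.update(stools_per_week=21,
                  loose_stools_per_day=(3, 6, 10)[gi_idx - 2])
    drop = _ORTHO_DROPS[ortho_idx]
    kw.update(sbp_supine=130.0, sbp_standing_1min=130.0 - drop,
              sbp_standing_3min=130.0 - drop / 2,
              orthostatic_syncope=(ortho_idx == 3))
    kw.update(residual_urine_ml=_URINE_RESIDUALS[urine_idx],
              catheterized=(urine_idx == 3))
    kw.update(dry_eyes_grade=eyes_idx, dry_mouth_grade=mouth_idx,
              dry_mouth_drug_induced=False)
    return AutonomicFindings(**kw)


def _visceral_findings(indices: list[int]) -> VisceralFindings:
    heart_idx, kidney_idx = indices
    kw: dict = {"cardiac_level_code": _CARDIAC_CODES[heart_idx]}
    if kidney_idx == 1:
        kw.update(dipstick_proteinuria=True)
    elif kidney_idx == 2:
        kw.update(dipstick_proteinuria=True, proteinuria_g_per_24h=4.0,
                  hypoalbuminemia=True, oedema=True)
    elif kidney_idx == 3:
        kw.update(dipstick_proteinuria=True, on_dialysis=True)
    return VisceralFindings(**kw)


def _apply_noise(indices: list[int], ladders, prob: float,
                 rng: np.random.Generator) -> list[int]:
    """Flip each item to an adjacent ordinal level with probability prob."""
    if prob <= 0:
        return indices
    out = []
    for idx, ladder in zip(indices, ladders):
        if rng.random() < prob:
            step = -1 if rng.random() < 0.5 else 1
            idx = int(np.clip(idx + step, 0, len(ladder) - 1))
        out.append(idx)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: CohortConfig) -> list[list[Assessment]]:
    """Generate one synthetic cohort: a list of per-patient visit series.

    Latent per-domain severity advances linearly with time (clamped to
    [0, 24]); body weight follows a deterministic per-patient trajectory.
    Reproducible: identical configs (including the seed) give identical
    cohorts.
    """
    cfg.check()
    rng = np.random.default_rng(cfg.seed)
    cohort: list[list[Assessment]] = []
    start = pd.Timestamp(cfg.start_date)
    for p in range(cfg.n_patients):
        pid = f"SIM{p + 1:04d}"
        baseline = {
            d: float(np.clip(rng.normal(cfg.baseline_severity_mean.get(d, 0.0),
                                        cfg.baseline_severity_sd), 0.0, 24.0))
            for d in SUBDOMAIN_NAMES
        }
        weight0 = max(40.0, rng.normal(cfg.baseline_weight_mean_kg,
                                       cfg.baseline_weight_sd_kg))
        height = float(np.clip(rng.normal(1.72, 0.09), 1.45, 2.05))
        visits: list[Assessment] = []
        for k in range(cfg.n_visits):
            years = k * cfg.visit_interval_months / 12.0
            # mean month length keeps dates strictly increasing for any
            # positive interval, including fractional months
            date = (start + pd.Timedelta(
                days=round(k * cfg.visit_interval_months * 30.4375))).date()
            latents = {
                d: float(np.clip(
                    baseline[d]
                    + cfg.annual_progression_rate.get(d, 0.0) * years,
                    0.0, 24.0))
                for d in SUBDOMAIN_NAMES
            }
            idx = {d: _apply_noise(latent_to_indices(d, latents[d]),
                                   _DOMAIN_LADDERS[d],
                                   cfg.rater_noise_prob, rng)
                   for d in SUBDOMAIN_NAMES}
            weight = weight0 * (1.0 + cfg.annual_weight_change_frac) ** years
            visits.append(Assessment(
                patient_id=pid,
                visit_date=date,
                sensory=_sensory_findings(idx["sensory"]),
                motor=_motor_findings(idx["motor"]),
                autonomic=_autonomic_findings(idx["autonomic"]),
                visceral=_visceral_findings(idx["visceral"]),
                weight_kg=round(weight, 1),
                height_m=round(height, 2),
                serum_albumin_g_per_L=cfg.serum_albumin_g_per_L,
            ))
        cohort.append(visits)
    return cohort


# ---------------------------------------------------------------------------
# Granularity experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GranularitySummary:
    """First visit at which each scale's sensory subscore departs from its
    baseline value, per simulated patient.

    ``first_change_*`` hold 1-based follow-up visit numbers, or None when a
    scale never registers a change within the simulated horizon.  The lead
    time of the revised over the original scale treats a never-detecting
    original scale as censored at one visit past the horizon.
    """

    n_patients: int
    n_visits: int
    visit_interval_months: float
    first_change_revised: list[Optional[int]]
    first_change_original: list[Optional[int]]
    n_detected_revised: int
    n_detected_original: int
    fraction_revised_no_later: float
    mean_lead_visits: Optional[float]
    mean_lead_months: Optional[float]


def granularity_experiment(cfg: CohortConfig) -> GranularitySummary:
    """Quantify the revised scale's finer sensory grading.

    Simulates a cohort, scores every visit's sensory findings under both
    scale versions, and records the first follow-up visit at which each
    scale's sensory subscore differs from its own baseline.  With zero
    rater noise the revised scale can never detect later than the original
    (its ladder refines the original's), and a latent crossing such as
    toes -> foot (1 -> 1.5 points) is visible to the revised scale only.
    """
    cohort = generate_cohort(cfg)
    first_rev: list[Optional[int]] = []
    first_orig: list[Optional[int]] = []
    for visits in cohort:
        rev = [sensory_subscore(a.sensory) for a in visits]
        orig = [sensory_subscore_original(a.sensory) for a in visits]
        first_rev.append(next(
            (k for k in range(1, len(rev)) if rev[k] != rev[0]), None))
        first_orig.append(next(
            (k for k in range(1, len(orig)) if orig[k] != orig[0]), None))

    horizon = cfg.n_visits  # censoring index: one past the last follow-up
    no_later = [
        (r if r is not None else horizon) <= (o if o is not None else horizon)
        for r, o in zip(first_rev, first_orig)
    ]
    leads = [(o if o is not None else horizon) - r
             for r, o in zip(first_rev, first_orig) if r is not None]
    mean_lead = float(np.mean(leads)) if leads else None
    return GranularitySummary(
        n_patients=cfg.n_patients,
        n_visits=cfg.n_visits,
        visit_interval_months=cfg.visit_interval_months,
        first_change_revised=first_rev,
        first_change_original=first_orig,
        n_detected_revised=sum(r is not None for r in first_rev),
        n_detected_original=sum(o is not None for o in first_orig),
        fraction_revised_no_later=float(np.mean(no_later)),
        mean_lead_visits=mean_lead,
        mean_lead_months=(mean_lead * cfg.visit_interval_months
                          if mean_lead is not None else None),
    )


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

def example_moderate_assessment(patient_id: str = "EXAMPLE",
                                visit_date: _dt.date = _dt.date(2024, 1, 6),
                                ) -> Assessment:
    """A typical moderate ATTRv polyneuropathy case-report form.

    Loss of cold sensation in the feet, lower legs and fingers; loss of
    pinprick sensation in the feet; normal power in all four movements; a
    5 mm Hg systolic drop after 3 min standing; chronic constipation (two
    hard stools per week); severe dry mouth; proteinuria on urine dipsticks;
    and a first-degree AV block on ECG.  Scores 16.5 points on the revised
    scale (subscores 4.5/0/4/8) and 17 on the original (4/0/5/8).
    """
    return Assessment(
        patient_id=patient_id,
        visit_date=visit_date,
        sensory=[
            # feet and lower legs: most proximal level of cold loss = lower leg
            SensoryFinding(modality=Modality.COLD, region=Region.LOWER_LIMB,
                           level="lower_leg", instrument="Rolltemp II"),
            SensoryFinding(modality=Modality.PINPRICK,
                           region=Region.LOWER_LIMB, level="foot",
                           instrument="Neuropen"),
            SensoryFinding(modality=Modality.LIGHT_TOUCH,
                           region=Region.LOWER_LIMB, level="normal",
                           instrument="cotton"),
            SensoryFinding(modality=Modality.COLD, region=Region.UPPER_LIMB,
                           level="fingers", instrument="Rolltemp II"),
            SensoryFinding(modality=Modality.PINPRICK,
                           region=Region.UPPER_LIMB, level="normal"),
            SensoryFinding(modality=Modality.LIGHT_TOUCH,
                           region=Region.UPPER_LIMB, level="normal"),
            SensoryFinding(modality=Modality.COLD, region=Region.TRUNK_HEAD,
                           level="none"),
            SensoryFinding(modality=Modality.PINPRICK,
                           region=Region.TRUNK_HEAD, level="none"),
        ],
        motor=[MotorFinding(movement=mv, mrc_grade=5) for mv in _MOTOR_ORDER],
        autonomic=AutonomicFindings(
            stools_per_week=2, stools_hard=True,
            sbp_supine=125.0, sbp_standing_1min=122.0,
            sbp_standing_3min=120.0,  # worst drop: 5 mm Hg
            residual_urine_ml=50.0,
            dry_eyes_grade=0, dry_mouth_grade=3, dry_mouth_drug_induced=False,
        ),
        visceral=VisceralFindings(
            cardiac_level_code=CardiacLevel.CONDUCTION_DISTURBANCE,
            cardiac_finding_text="first-degree AV block on ECG",
            dipstick_proteinuria=True,
        ),
        weight_kg=72.0, height_m=1.80, serum_albumin_g_per_L=40.0,
    )


def all_normal_assessment(patient_id: str = "NORMAL",
                          visit_date: _dt.date = _dt.date(2024, 1, 6),
                          ) -> Assessment:
    """An explicitly examined, fully normal assessment (scores 0)."""
    return generate_cohort(CohortConfig(
        n_patients=1, n_visits=1, rater_noise_prob=0.0,
        baseline_severity_mean={d: 0.0 for d in SUBDOMAIN_NAMES},
        baseline_severity_sd=0.0,
        annual_progression_rate={d: 0.0 for d in SUBDOMAIN_NAMES},
        start_date=visit_date,
    ))[0][0].model_copy(update={"patient_id": patient_id})


def all_worst_assessment(patient_id: str = "WORST",
                         visit_date: _dt.date = _dt.date(2024, 1, 6),
                         ) -> Assessment:
    """Every item at its worst category (scores 96, each subscore 24)."""
    return generate_cohort(CohortConfig(
        n_patients=1, n_visits=1, rater_noise_prob=0.0,
        baseline_severity_mean={d: 24.0 for d in SUBDOMAIN_NAMES},
        baseline_severity_sd=0.0,
        annual_progression_rate={d: 0.0 for d in SUBDOMAIN_NAMES},
        start_date=visit_date,
    ))[0][0].model_copy(update={"patient_id": patient_id})
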