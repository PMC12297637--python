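# Methods

## Scope and model

`kumascale` treats the Kumamoto scale as a deterministic function from a
structured case-report form (an `Assessment`) to a `ScoreBreakdown`:
per-item ordinal scores, four subdomain subscores (0–24 each) and their
exact sum (0–96), plus an audit trail of every non-obvious coding rule
applied. Both scale versions run off the same input model; the original
1997 engine differs only in the three places the revision changed
(limb sensory ladders, the GI item, the orthostatic bands) and shares all
other item scorers with the revised engine, so cross-scale comparisons are
item-by-item meaningful.

Scoring is pure and order-independent: findings are canonically sorted
before merging, identical assessments give bit-identical breakdowns, and
no randomness enters anywhere in the scoring path.

## Conventions where the published instrument is silent

The published description of the scale leaves several operational gaps.
The package resolves them as follows; each choice is surfaced in the
breakdown's `notes` so a reviewer can see which rules fired.

* **Laterality.** The instrument does not say how to combine left and
  right. Each item is scored from the worse side (most proximal sensory
  level, lowest MRC grade); a finding with `side="unspecified"` is taken
  as the examiner's combined judgement. This is the usual worst-deficit
  convention of impairment scales and preserves the 24-point subdomain
  maxima.
* **Trunk/head light touch** is not a scoreable item (only cold and
  pinprick are; 2 × 3 trunk points are exactly what makes the sensory
  maximum 24). A supplied trunk light-touch finding is recorded with a
  note and excluded from the subscore.
* **Missing items.** Sensory items with no recorded finding score 0 —
  sensory recording is deficit-based. Motor, autonomic and visceral items
  whose required measurements are absent (no MRC grade, no supine blood
  pressure, no bladder scan or catheter status, no cardiac code, no sicca
  grade) are reported in `missing_items`; subscores then cover the
  scoreable items only and the breakdown is flagged incomplete. There is
  no imputation or proration — prorated subscores would corrupt
  longitudinal deltas.
* **Boundary conventions.** Residual-urine bands are low-inclusive:
  [150, 300) → 2, [300, 500] → 4, > 500 → 6. The revised 2-point
  orthostatic band is the closed interval [10, 20] mm Hg with 4 points
  strictly above 20. Constipation is strictly fewer than 3 stools per
  week (3/week scores 0); diarrhoea requires at least 3 loose stools per
  day. Nephrotic-range proteinuria is strictly above 3.5 g/24 h.
* **Orthostatic drop.** Measured supine after 5 min rest and standing
  after 1 and 3 min; the drop is supine minus the *lowest* standing
  systolic value (worst drop). With supine hypertension the 2-point onset
  moves from 10 to 30 mm Hg (consensus orthostatic-hypotension
  definition), band width preserved. A diastolic drop ≥ 10 mm Hg is noted
  but the systolic bands govern the score. The 6-point category requires
  an explicit severe-symptom flag (syncope/presyncope needing
  countermeasures); no blood-pressure value alone reaches it. All
  thresholds sit in `OrthostasisConfig`.
* **Original orthostatic band.** The original scale's 0–20 mm Hg 2-point
  interval is taken literally — a 5 mm Hg drop scores 2 — except that a
  drop of exactly 0 (or a rise) scores 0, keeping a fully normal patient
  at total 0. The engine reproduces the band for comparability even
  though its clinical value below 10 mm Hg is doubtful.
* **Diarrhoea tiers.** The 2/4/6-point tiers are coded categories
  (`gi_level_code`); as an optional raw mapping, loose-stool frequencies
  of 3–5 / 6–9 / ≥ 10 per day map to 2/4/6. The bands are a package
  convention, overridable per call. Constipation (1 point, revised only)
  and diarrhoea never add: the single worst applicable tier counts.
* **Sicca grades** 1 and 2 are not defined by the instrument; the
  codebook fixes 0 none / 1 mild / 2 moderate / 3 severe. Dry mouth
  judged a medication side effect scores 0 with an exclusion note.
* **Heart 8-point category.** Only 0 (normal), 4 (conduction
  disturbance) and 12 (third-degree AV block or pacemaker, the only
  context in which heart failure counts) are pinned down; the 8-point
  `advanced_conduction` category is assignable only by explicit coding.
* **Raw vs pre-coded input.** Every autonomic/visceral item accepts raw
  measurements or a pre-coded category; when both are present and
  disagree, the raw measurement wins and a conflict note is emitted.

## Progression rule

A follow-up visit is flagged when *(a)* the total-score delta exceeds the
threshold (default 4 points, strict inequality, so a 4.0-point delta does
not flag but a revised-scale 4.5 does) **and** the patient reports
subjective deterioration; or *(b)* weight loss since the reference visit
reaches the configured fraction of reference weight (default 5 %,
inclusive); or *(c)* new organ involvement appears (the flag's semantics
already exclude the eyes). The guideline's "together with … and/or"
phrasing is ambiguous; binding deterioration to the score criterion only
is the package's reading, is stated in every verdict's notes, and both the
conjunction requirement and the thresholds are configurable. Deltas are
taken against the first visit by default (`baseline="previous"`
switches); missing weights disable only the weight criterion, with a
note. `mbmi` implements the standard modified body mass index,
BMI × serum albumin (kg/m² · g/L), used to track nutrition alongside the
score.

## Synthetic cohorts

Each simulated patient carries a latent severity in [0, 24] per subdomain
that advances linearly in time (points/year, clamped). The latent value is
spread greedily over the subdomain's items in registry order — filling the
distal-to-proximal sensory ladders first-to-last, degrading MRC grades,
crossing the blood-pressure/residual-urine/stool thresholds — and each
item's latent load is quantised to the largest ladder score not exceeding
it. Raw findings are then emitted that realise exactly that ordinal level,
so with zero rater noise the scored subscore equals the latent severity
quantised to the scale's grid (`expected_subscore` computes the
quantisation; the suite asserts the round trip). Rater noise miscodes an
item to an adjacent ordinal level with a configurable probability,
mimicking inter-rater disagreement between neighbouring anatomical levels;
there are no long-range errors.

Defaults (a convention, not a natural-history calibration, which the
simulator deliberately does not attempt): 50 patients, 4 visits at
12-month intervals, baseline severities drawn from truncated normals
centred at 4/1/4/4 points (sensory/motor/autonomic/visceral, sd 2),
progression 2/1/1.5/1 points/year, 5 % per-item noise, weight declining
2 %/year from a 75 ± 10 kg baseline, albumin fixed at 40 g/L. All
randomness flows from a single seed; identical configs give identical
cohorts.

`granularity_experiment` quantifies the revision's finer sensory grading:
it records, per patient, the first follow-up visit at which each scale's
sensory subscore departs from its own baseline. Because the revised limb
ladder refines the original (original = floor of revised, verified
exhaustively), the revised scale can never detect later when noise is
zero; a latent crossing such as toes → foot (1 → 1.5 points) is visible
to the revised scale only. Lead times treat an original scale that never
detects within the horizon as censored one visit past it, so reported
mean leads are conservative lower bounds.

What the simulator does **not** emulate: asymmetric or patchy
(non-length-dependent) sensory presentations, correlated rater error
across items, missing data, treatment effects, or mortality. Passing
round-trip and lead-time tests therefore demonstrates the engines'
correctness on the constructed mapping, not clinical sensitivity of the
instrument on real patients.

## Numerical notes

All scores are small multiples of 0.5 and exactly representable as binary
floats, so subscores and totals are compared with equality, never
tolerances. Validation never raises on out-of-range content — it returns
an exhaustive list of findings naming field and rule — while the scoring
entry points refuse invalid forms (`InvalidAssessmentError`) and coding
errors on direct item calls raise `CodingError` naming the ladder. Test
problem sizes (1,000 oracle assessments, 200 simulated progressing
patients, 5-visit horizons) keep the full suite under a few seconds while
covering every ladder level, band edge and progression branch.

## Known limitations

Inter-rater variability of the instrument itself is untested here (no
validation study exists yet); the original scale's image-only category
wordings (GI and sicca tiers, heart categories) are represented as coded
categories rather than prose; upper-GI, genitourinary and heart-failure
symptoms are outside the instrument; and the CSV interchange format holds
one finding per sensory/motor item (per-side duplicates need JSON).
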