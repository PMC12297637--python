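# kumascale

A deterministic scoring engine for the **Kumamoto scale**, the 0–96-point
clinical instrument used to monitor hereditary transthyretin (ATTRv)
amyloidosis. The package implements both the original 1997 scale and its
revised version side by side, evaluates longitudinal disease progression
against the Swedish follow-up criteria, and ships a synthetic cohort
simulator so every scoring and progression path can be exercised without
patient data.

It is written for clinicians and registry/trial data managers who record
structured case-report forms (JSON or long-format CSV) and want
reproducible, auditable scores rather than hand tallies.

## The instrument

The scale has four subdomains, each scored 0–24, summing to a 0–96 total:

| Subdomain | Items | Item ladders |
|---|---|---|
| Sensory | cold / pinprick / light touch per limb region; cold / pinprick on trunk & head | revised limbs: 0, 1, 1.5, 2, 2.5, 3 by the most proximal level of *lost* sensation (toes → foot → lower leg → knee → thigh; fingers → hand → forearm → upper arm → shoulder); original limbs: 0–3 integers; trunk/head: 0–3 |
| Motor | ankle dorsiflexion, knee extension, elbow flexion, wrist dorsiflexion | MRC grade 5…0 → 0, 2, 3, 4, 5, 6 (NIS-LL grades 0, 2, 3.25, 3.50, 3.75, 4 map identically) |
| Autonomic | GI symptoms, orthostasis, urination, dry eyes, dry mouth | GI 0/1/2/4/6 (constipation = 1, revised only); orthostatic systolic drop: revised 0 below 10 mm Hg, 2 for 10–20, 4 above 20, 6 with syncope (original: 2 for any drop in 0–20); residual urine <150 / 150–300 / 300–500 / >500 ml or catheter → 0/2/4/6; sicca items 0–3 |
| Visceral | heart, kidneys | 0/4/8/12 each; kidney: proteinuria 4, nephrotic syndrome (>3.5 g/24 h + hypoalbuminemia + oedema) 8, dialysis 12 |

Bilateral findings are scored from the worse side. Progression at a
follow-up visit is flagged when subjective deterioration coincides with a
total-score increase of **more than** 4 points, when unintentional weight
loss reaches 5 % of body weight, or when new organ involvement (eyes
excluded) appears.

## Worked example

The typical moderate-polyneuropathy case — loss of cold sensation in the
feet, lower legs and fingers, loss of pinprick sensation in the feet,
normal motor power, a 5 mm Hg orthostatic systolic drop, chronic
constipation (two hard stools per week), severe dry mouth, dipstick
proteinuria and a first-degree AV block:

```python
from kumascale import example_moderate_assessment, write_assessments
write_assessments([example_moderate_assessment()], "vignette.json")
```

```console
$ kumascale score --in vignette.json --scale both
EXAMPLE 2024-01-06  original total: 17  revised total: 16.5
  original: sensory/motor/autonomic/visceral = 4/0/5/8
  revised: sensory/motor/autonomic/visceral = 4.5/0/4/8

$ kumascale compare --in vignette.json
EXAMPLE 2024-01-06  original 17 -> revised 16.5 (delta -0.5)
  sens_pinprick_lower_limb: 1 -> 1.5 (+0.5)
  auto_gi: 0 -> 1 (+1)
  auto_orthostasis: 2 -> 0 (-2)
```

Reading the deltas: the finer revised sensory ladder credits the
foot-confined pinprick loss with an extra half point; constipation becomes
a scoreable symptom (+1); and the clinically questionable 2 points the
original scale awarded for a 5 mm Hg drop disappear because the revised
2-point band starts at 10 mm Hg.

Other subcommands: `kumascale progression` (per-visit verdicts against the
progression criteria), `kumascale simulate` (seeded synthetic cohorts) and
`kumascale validate` (exhaustive schema/range checking). The same
functionality is available as a library: `score_assessment`,
`score_assessment_original`, `compare_scales`, `trajectory`,
`evaluate_progression`, `generate_cohort`, `granularity_experiment`,
`mbmi`.

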