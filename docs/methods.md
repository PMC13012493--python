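# Methods

## Risk model

The daily score is an additive rubric for drug-associated QT-interval
prolongation in hospitalized patients. Components and default points:
age ≥ 68 y (1), female sex (1), diuretic use that day (1), serum potassium
≤ 3.5 mmol/L (2), QT interval ≥ 450 ms (2), QT-prolonging drugs (3 for one,
3 + 3 for two or more — the drug term saturates at 6 regardless of further
co-prescriptions), history of acute myocardial infarction (2), congestive
heart failure with reduced ejection fraction (3), sepsis that day (3);
maximum 21. Weights are configurable non-negative integers and the band
boundaries (low ≤ `low_max` = 6 < moderate ≤ `moderate_max` = 10 < high) are
configurable too, because published uses of this rubric differ in small
adaptations. A total of exactly 6 is classified **low**, following the
original "≤ 6 low" convention of the score; the printed "low < 6 /
moderate 7–10" phrasing leaves 6 unassigned and we resolve it downward
rather than invent a fourth band.

Assumptions worth stating explicitly:

* **The QT column is taken as given.** No Bazett/Fridericia rate correction
  is computed; the input is expected to be the corrected interval if the
  site records one.
* **Missing labs score zero.** After last-observation-carried-forward
  (LOCF, unbounded horizon) imputation, any still-missing potassium or QT
  contributes no points — risk is never inflated from absent data. This
  matters for real charts where bedside ECGs are often not transcribed.
* **Patient-level class = worst day.** The per-day series is the primary
  object; the patient summary takes the day with the maximal total (ties to
  the earliest day), i.e. maximum exposure over the stay.
* **Only in-ICU administrations count.** Chronic medication and
  pre-admission self-medication are stored for characterization and
  excluded from both the score and the ADE drug inventories.
* Sepsis is handled as a per-day boolean, the finest granularity the daily
  chart supports.

## Knowledge base

Each drug carries a therapeutic class and binary flags: QT prolongation,
Torsades de pointes (implies QT — it is the aggravated phenotype), serotonin
syndrome, diuretic, plus a non-scoring `cv_caution` marker for drugs with
non-QT cardiovascular liabilities (fentanyl, dexmedetomidine). Flags are
binary per drug: no dose, route or pharmacokinetic interaction modeling. The
bundled base covers the 33 drugs of the motivating ICU cohort's printed
characterization; Torsades/serotonin-syndrome flags are assigned only where
explicitly established (methadone and tramadol carry all three). The
replacement drugs (morphine, fentanyl, hydromorphone, metoclopramide,
propofol, midazolam, dexmedetomidine, ketamine) are non-QT by construction —
a validated invariant, since the intervention's monotone risk reduction
depends on it. "Benzodiazepines" as a replacement class is represented by
midazolam, the canonical ICU benzodiazepine. Unknown drug names never abort
a run; they are normalized, counted and reported.

## Intervention semantics

Rules fire per patient-day on the medication set. Replace-rules substitute
the policy-selected candidate (default: first listed; a fixed per-rule
choice is configurable) without duplicating a drug already present that day;
withdraw-rules drop the drug with no substitute, mirroring the withdrawal of
therapies that lacked clinical evidence. Labs, sepsis and comorbidities are
held fixed — the counterfactual isolates prescribing. The transformation is
idempotent (no replacement is itself a rule source) and deterministic.

## Statistics

* **Prevalence ratio.** PR = (k₁/n₁)/(k₂/n₂) directly from the 2×2 counts;
  CI from the log-normal approximation with var(log PR) = 1/k₁ − 1/n₁ +
  1/k₂ − 1/n₂. A univariate Poisson log-link GLM on the aggregated counts is
  provided as a cross-check route; it is algebraically the same estimate.
  Zero reference events raise (infinite PR) rather than divide silently.
  The binary outcome "score increased" used for stratified tables is
  operationalized as: the patient's maximum daily total strictly exceeds
  their admission-day total.
* **Paired Wilcoxon signed-rank.** Differences are pre − post. Zero
  differences use the Pratt method by default (ranked with the rest, then
  dropped; classic zero-drop selectable) — appropriate when many identical
  pairs are expected, as in before/after scores of untouched patients. The
  null is exact for ≤ 25 nonzero differences, computed by a subset-sum
  dynamic program over doubled midranks that is identical to full
  enumeration of the 2^m sign assignments (ties handled by midranks);
  beyond that, a normal approximation with tie-consistent variance
  Var = Σr²/4 and continuity correction. All-zero difference vectors return
  p = 1. Reported statistic is W⁺, the positive-difference rank sum.

## Synthetic cohort generator

The generator emulates the marginal structure of a 2020 COVID-19 ICU
population: 65% male; age bands 25–39/40–49/50–59/60–90 with probabilities
equal to the source cohort's exact count fractions (8, 15, 24, 59)/106
(printed rounded percentages sum to 99%, the count fractions to 100%);
hypertension 58%, diabetes 36%, obesity 39.6% (of the two inconsistent
printed obesity figures, 39.6% vs 58%, the explicitly stated cohort
fraction is used), AMI 8%, CHF 2%, arrhythmia 5%; chronic-medication use
65% (with QT-prolonging chronic drugs at the 14%-of-cohort rate),
self-medication 20% (QT self-medication 17%); length of stay drawn by band
((18, 13, 29, 18, 28)/106 over <7/7–13/14–20/21–27/≥28 days, uniform within
band, ≥28 capped at 45); outcomes at the printed frequencies (death 74%).

Each day draws a drug *set* — Poisson-sized around 8 drugs/day, weighted
sampling without replacement via the Gumbel-top-k device, with named
administration frequencies (fentanyl 0.048, ondansetron 0.033,
dexmedetomidine 0.018, azithromycin 0.013) and the residual mass uniform
over the rest of the knowledge base — plus potassium (hypokalemic ≤ 3.5
with per-day probability 0.15, drawn N(3.1, 0.25) clipped to (1.5, 3.5];
otherwise N(4.2, 0.4) clipped above 3.5), QT interval (≥ 450 ms with
probability 0.25, N(465, 12) clipped to [450, 650]; otherwise N(410, 20)
clipped below 450) and sepsis (0.20/day). The per-day lab/sepsis rates are
calibration knobs — no per-day prevalences are published — chosen so the
baseline scenario lands in the source regime of majority high risk. All
randomness flows from one integer seed; identical parameters and seed give
byte-identical cohorts.

What the generator does **not** emulate, hence what passing tests do not
show about real data: no correlation between drugs within a day (no
sedation bundles), no longitudinal disease trajectory (days are
conditionally independent given the patient), no link between comorbidities
and prescriptions or labs, no missing labs (LOCF is exercised on explicit
fixtures instead), and real charts contain drugs outside the bundled
knowledge base, which would be counted as unknowns.

Presets: `baseline_covid_icu` is the calibration above. `low_risk`
restricts sampling to non-QT drugs with near-normal labs and rare sepsis.
`qt_saturated` forces ≥ 2 QT-prolonging drugs into every day, raises the
hypokalemia/long-QT/sepsis rates (0.35/0.60/0.50), excludes sub-week stays,
and concentrates administration mass on the drug classes the substitution
rules target (antiemetics, typical antipsychotics, opioid narcotics,
repurposed antimalarials/antivirals, plus the sedation backbone and
furosemide) — the prescribing pattern of the motivating cohort. It emulates
the near-saturated high-risk regime whose risk collapses under the
intervention: ~100% high before, ~40% after at n ≈ 100–200.

## Numerical and design choices

* Day sets are stored in stable pool order; all set semantics (dedup of
  replacements, distinct QT-drug counts) are order-invariant, and the score
  is invariant to medication order and duplication.
* Report floats are rounded half-even to 3 decimals at serialization so
  identical runs produce byte-identical artifacts.
* Problem sizes used by the default verification runs: exhaustive rubric
  enumeration (2⁸ × 4 cases), Wilcoxon enumeration oracles at n ≤ 10,
  marginal calibration at n = 10,000 patients, intervention property sweeps
  over 100 cohorts of n = 50, and the saturated-regime demonstration at
  n = 200.

## Known limitations

* The rubric's female-sex point encodes the classical risk factor; cohorts
  with male-skewed outcomes (as in severe COVID-19) may find the score's
  sex weighting counter to their observed gradient.
* Confidence intervals for prevalence ratios use the Wald log-normal form;
  small-count strata (e.g. a 3-subject arm) give very wide, poorly
  calibrated intervals, and point estimates should be preferred there.
* Binary per-drug flags cannot express dose-dependent QT liability or
  pharmacokinetic interactions (CYP inhibition), both clinically relevant.
* The intervention applies the rules as stated without modeling clinical
  appropriateness (e.g. benzodiazepines can worsen delirium); it is a
  counterfactual bound on prescribing-attributable risk, not a care
  recommendation.
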