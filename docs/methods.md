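# Methods

## Time and calendar conventions

All within-admission times are integer minutes from admission start, and
every admission is taken to begin at midnight of its calendar day 0, so the
calendar day of an event is `time_min // 1440`. This matters because the
Adult Sepsis Event (ASE) rules are calendar-day based: qualifying
antimicrobial days (QADs) are distinct calendar days with ≥ 1 qualifying
antimicrobial administration, and the culture window is ±2 calendar days.
`admit_min`/`discharge_min` sit on a shared absolute axis used only for
inter-admission spacing (the 30-day readmission exclusion). No wall-clock
or timezone handling is attempted.

## Reference-standard phenotype

An admission is **ASE sepsis** when some blood culture has a qualifying QAD
episode starting within ±2 calendar days and ≥ 1 eSOFA organ-dysfunction
event occurs. Decisions taken where the surveillance definition leaves
room:

* **QAD episodes** are maximal runs of consecutive QAD calendar days; by
  default no gap days are allowed inside an episode (`qad_gap_days = 0`,
  configurable). An episode qualifies with ≥ 4 days, or with fewer when the
  admission ended in death and the run reaches the day of death or the day
  before (`death_exemption = True`, configurable).
* **eSOFA baselines** are the first recorded in-admission value of the lab
  (creatinine, bilirubin, platelets); comparisons are inclusive at the
  printed cutoffs (lactate ≥ 2.0 mmol/L, creatinine ≥ 2× baseline,
  bilirubin ≥ 2.0 mg/dL *and* ≥ 2× baseline, platelets < 100 ×10³/µL with a
  decline of ≥ 50 % from a baseline ≥ 100). A lab never measured simply
  yields no event (missingness = non-contribution). The eSOFA search window
  is the whole admission by default, restrictable to the culture ±2-day
  window (`esofa_window = "culture"`).
* **COVID-19 sepsis** is ICD-10 U07.1x plus ≥ 1 eSOFA event, with no
  culture/antimicrobial requirement. An admission meeting both definitions
  is labeled COVID-19 sepsis (`covid_precedence = True`, configurable), so
  the three categories partition every cohort.
* **Septic shock** is any sepsis label plus a shock code (R65.21,
  T81.12XA) or ≥ 1 vasopressor order.
* The **exclusion cascade** applies six rules in a fixed order — burn
  service, length of stay strictly > 30 days, left against medical advice,
  external/internal transfer, readmission within 30 days of a
  sepsis-related index admission of the same patient, and neither blood
  pressure nor temperature ever recorded — with first-matching-rule
  attribution, so input = retained + Σ removed. "Sepsis-related" defaults
  to the phenotype label of the index admission (computed provisionally on
  the full cohort; phenotyping does not depend on exclusions) and can be
  switched to an ICD-10 code list.
* The **Charlson Comorbidity Index** uses the Quan ICD-10 prefix map with
  the original weights (1/2/3/6), a 2-year lookback through the end of the
  admission, the usual severity hierarchy (complicated diabetes over
  uncomplicated, metastatic tumor over malignancy, severe over mild liver
  disease), and bins 0–1 / 2–5 / ≥ 6. The map, and the qualifying
  antimicrobial and vasopressor lists, are package data (CSV), not code.

## Score streams

Scores are right-continuous step functions over element snapshots. A
snapshot at time *t* holds, per element, the most recent observation whose
age is within the element's validity window — vitals and GCS 480 min, labs
1440 min by default, inclusive at the boundary. Values failing plausibility
bounds (e.g. GCS 0) are dropped before scoring, with a log entry. An
element with no in-window value is absent and contributes no points: a
criterion that cannot be computed would not alert anyone, so it reads as
non-septic at that time point. A consequence worth knowing: removing an
entire element can only lower SIRS/qSOFA scores, but removing a *single*
observation can expose an older abnormal value within the window — the
monotonicity property holds element-wise, not observation-wise.

* **SIRS** (0–4), strict inequalities: temperature > 38 or < 36 °C;
  HR > 90; RR > 20 or PaCO₂ < 32 mmHg; WBC > 12 or < 4 ×10³/µL or
  bands > 10 %.
* **qSOFA** (0–3), conventional boundaries: RR ≥ 22; SBP ≤ 100 mmHg;
  GCS < 15.
* **SOFA** (0–24): the standard six-organ 0–4 bands, with two documented
  simplifications — respiration bands are applied to P/F without the
  ventilation co-requirement for 3–4 points, and the cardiovascular band is
  dose-free (MAP < 70 → 1; any active vasopressor → 3), because order data
  carry no doses. Urine output and FiO₂ imputation are out of scope.
  Positivity is the rise over baseline ≥ 2; the baseline is 0 (so delta =
  total) by default, or the first computed total
  (`sofa_baseline = "first"`).
* SIRS/qSOFA/SOFA are recomputed at every element-update time (plus
  vasopressor order times for SOFA); threshold upcrossings can only occur
  at such times, since expiry between events only lowers scores.

**The surrogate predictive score (PSS)** is explicitly *not* a
reconstruction of any proprietary model — no coefficients of deployed
vendor scores are public. It exists so the threshold/timeliness machinery
(including order-driven score inflation) can be exercised by a fully
transparent stand-in:

```
score(t) = scale · logistic(intercept + Σᵢ wᵢ fᵢ(snapshot(t)))
         + bump · exp(−(t − t_last_abx_order)/decay)
```

on a 15-minute grid, with hinge-shaped abnormality features (e.g.
max(0, (HR−90)/10), max(0, lactate−2)) each scaled to ≈ 1 point per unit of
clinical concern. Defaults — intercept −3, unit weights, scale 12, bump 3,
decay 240 min — put the score on a 0–15 range so alert thresholds of 5–10
are meaningful: an all-normal snapshot scores 12·σ(−3) ≈ 0.57, a florid
septic signature ≈ 12. The bump term makes the score rise after any
antimicrobial order regardless of physiology, which is exactly why
timeliness is anchored 15 minutes *before* the first order.

## Timeliness

Time zero = min(first antimicrobial order, first blood-culture order) − 15
min; undefined (and excluded, with a logged count) when neither order
exists. Signed offset = first crossing − time zero, negative before time
zero; an offset of exactly 0 counts as before-or-at. The default
timeliness cohort is ASE-sepsis admissions only (COVID-19 sepsis may lack
qualifying orders entirely); one episode per admission — only the first
clinician action anchors it. Medians and IQRs are computed over
threshold-met admissions only, while category counts
(before-or-at / after / not-met) cover the full anchored cohort and must
sum to it — the pipeline asserts this conservation identity. The
cumulative-crossing table sorts met admissions by offset with ties broken
by admission id, and flags never-met admissions. The anchor can be
replaced by the first eSOFA event time to measure timing against organ
dysfunction instead of clinician action.

## Classification metrics

Whole-stay prediction: positive iff the threshold is ever met during the
admission (empty stream → negative, by the missingness rule). Balanced
accuracy and the DOR are reported because at ~2.7 % prevalence plain
accuracy is dominated by the negatives. CI choices, made here because no
single convention is universal: Wilson for proportions; the log method
exp(ln DOR ± 1.96·√(ΣCELL⁻¹)) for the DOR; balanced-accuracy interval =
endpoint-wise mean of the sensitivity and specificity intervals (a
pragmatic band, not an exact interval). A zero cell makes the DOR
infinite/undefined and its CI NaN unless the Haldane–Anscombe 0.5
correction is enabled (off by default). McNemar compares two criteria's
*correctness* against the phenotype: continuity-corrected
χ² = (|b−c|−1)²/(b+c) on the discordant counts, with the exact binomial
test when b + c < 25 (statistic then min(b, c)), and (0, 1) when b + c = 0.
No multiple-testing correction is applied. Report rounding: 2 decimals for
rates, 1 for percentages. Cohort description uses chi-square tests for
categorical variables and Kruskal–Wallis for skewed continuous ones.

A note on metric algebra: FN proportion ≡ 1 − sensitivity and FP
proportion ≡ 1 − specificity exactly; swapping the positive/negative class
on both truth and prediction swaps sensitivity ↔ specificity and leaves
the DOR invariant (it is symmetric in the two), whereas inverting only the
prediction maps DOR → 1/DOR.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis consumes —
event cadences, order behavior, label structure — not bedside physiology.
Defaults encode the study conditions: sepsis prevalence 2.7 % (Bernoulli
per admission), 20.4 % of sepsis COVID-19, log-normal length of stay
(median 3.2 days nonsepsis / 9.2 days sepsis, σ_log 0.65), exponential
inter-observation gaps (vitals mean 240 min, labs 720 min), log-normal
order latency from physiologic onset to first clinician action (median
120 min, σ_log 0.8). One RNG stream seeded once drives everything; a fixed
seed reproduces byte-identical CSVs (set iteration is avoided anywhere the
RNG is consumed, so outputs are independent of hash randomization).

Two constructions make the generator a usable oracle:

* **Nonsepsis admissions are airtight negatives.** Their draws are clamped
  inside eSOFA-silent ranges (lactate ≤ 1.9, no lab doubling or 50 %
  platelet fall, no vasopressors/ventilation), so phenotyping can never
  fire on noise; some still get blood cultures with short (1–3 day)
  antimicrobial runs, transient strong-vitals flares, U07.1 codes without
  organ dysfunction, and the service/disposition/source quirks the
  exclusion cascade needs. **Septic admissions are airtight positives**: a
  guaranteed lactate ≥ 2.1 anchors organ dysfunction, the antimicrobial
  run is consecutive by construction and begins the day of the culture,
  and physiology ramps (over ~6 h) from baseline toward a strong or muted
  post-onset signature. Phenotyping therefore recovers the truth label for
  100 % of admissions — a property the tests assert, and the reason
  phenotype-level recovery is a meaningful end-to-end check.
* **The surrogate's separation is generative.** A configured fraction of
  septic admissions (default 0.85) get the strong signature, which crosses
  the default alert threshold of 8 with a wide margin; the rest get the
  muted signature (organ dysfunction on labs, near-normal vitals), which
  stays well below it. A configured fraction of nonsepsis admissions
  (default 0.27) get the flare, which crosses 8 without organ dysfunction.
  Estimated sensitivity/specificity at threshold 8 therefore recover
  0.85/0.73 up to binomial noise — the parameter-recovery test checks
  containment in the Wilson 95 % CI at n = 2000.

What the generator does *not* model — and hence what passing tests do not
show about real data: correlated multi-organ trajectories, treatment
response (scores stay elevated after therapy), repeat sepsis episodes
within one admission, inter-site variation, urine output, FiO₂, dose
titration, documentation artifacts, and any resemblance between the
surrogate's feature weights and a real vendor model's. Results on this
cohort validate the *machinery*, not any clinical claim.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) uses 2000 admissions — at
2.7 % prevalence that yields ~50 septic admissions, enough for stable
classification metrics while timeliness medians stay visibly noisy; the
package reports `n` alongside every quantity so that uncertainty is
legible. The test suite uses cohorts of 120–2000 admissions, brute-force
oracles over 1000 random small admissions, and derandomized property
tests. All entry points accept a seed; every derived RNG stays below 2³¹.

## Known limitations

Single-episode timeliness per admission; no ICD-9 or claims-based sepsis
definitions; no AUC/calibration reporting (the compared criteria have
single prespecified thresholds, making those comparisons ill-posed in this
design); exclusion logging is per-rule counts rather than full audit
trails; the "assessed at 1 hour" reading of element concurrency is
resolved via validity windows (8 h vitals / 24 h labs) rather than a 1-hour
co-occurrence requirement — both are expressible through
`ScoringConfig`, and neither is asserted to be the only defensible choice.
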