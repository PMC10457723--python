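# sepsisbench

Benchmarking the **validity** and **timeliness** of sepsis screening
criteria — SIRS, qSOFA, SOFA, and a transparent 15-minute predictive score
stream — against the CDC **Adult Sepsis Event (ASE)** surveillance
phenotype, on synthetic EHR-style event data.

Hospitals increasingly run proprietary sepsis prediction models that
recompute a risk score every 15 minutes and fire threshold-based alerts.
Evaluating such a score fairly requires more than a confusion matrix: the
score must also beat the clinician to the diagnosis. `sepsisbench`
implements the full evaluation pipeline — cohort simulation, reference-
standard phenotyping, score-stream computation, time-zero anchoring, and
classification/timeliness reporting — for methodologists who want to study
how this kind of evaluation behaves end to end, with every rule explicit
and testable.

## What it computes

**Reference standard (per admission).** EHR-confirmed sepsis by the CDC ASE
definition: a blood culture with ≥ 4 qualifying antimicrobial days (QADs)
beginning within ±2 calendar days of the culture (fewer days qualify when
therapy runs through the day of death), plus ≥ 1 EHR-optimized organ
dysfunction (eSOFA) event: vasopressor initiation, mechanical-ventilation
initiation, creatinine ≥ 2× baseline, bilirubin ≥ 2.0 mg/dL and ≥ 2×
baseline, platelets < 100 ×10³/µL with ≥ 50 % decline from a baseline
≥ 100, or lactate ≥ 2.0 mmol/L. A COVID-19-specific definition (ICD-10
U07.1x + eSOFA, no culture/antimicrobial requirement), septic shock
(R65.21/T81.12XA or vasopressor use during a sepsis admission), a six-rule
exclusion cascade, and the Charlson Comorbidity Index (Quan ICD-10 map)
complete the phenotype.

**Score streams.** SIRS (0–4), qSOFA (0–3) and SOFA (0–24, positivity =
rise ≥ 2 over baseline) are recomputed at every element update; a
transparent surrogate for a proprietary predictive sepsis score (PSS) is
recomputed on a 15-minute grid as a logistic transform of hinge-shaped
abnormality features, plus an additive decaying bump after each
antimicrobial order (order-driven score inflation). Elements carry forward
within validity windows (vitals 8 h, labs 24 h); an element with no
in-window value contributes nothing — a criterion that cannot be computed
reads as non-septic at that time point.

**Validity.** Whole-stay classification against the phenotype:
sensitivity, specificity, false-negative/false-positive proportions,
balanced accuracy ((sens + spec)/2), and the diagnostic odds ratio
(DOR = LR⁺/LR⁻ = TP·TN/(FP·FN)) — the latter two chosen because prevalence
is low (~2.7 %). Wilson 95 % CIs for proportions, log-method CI for the
DOR, McNemar tests for paired criterion comparisons.

**Timeliness.** Time zero is 15 minutes before the first clinician action
(earliest antimicrobial or blood-culture order): an order at 2:00 pm puts
time zero at 1:45 pm. Each criterion's first threshold crossing gets a
signed offset (negative = before time zero, i.e. a prospectively useful
alert), summarized as before/after/not-met counts, median (IQR) offsets,
and a cumulative-crossing curve; the anchor can be switched to the first
eSOFA event.

## Worked example

```python
import pandas as pd
from sepsisbench.config import CohortConfig, PipelineConfig
from sepsisbench.pipeline import run_pipeline

cfg = PipelineConfig(cohort=CohortConfig(
    n_admissions=500, sepsis_prevalence=0.08, seed=7))
run_pipeline(cfg, "out/")

t2 = pd.read_csv("out/table2.csv")
print(t2[["criterion", "threshold", "sensitivity", "specificity",
          "balanced_accuracy", "diagnostic_odds_ratio"]].round(2))
```

```text
criterion  threshold  sensitivity  specificity  balanced_accuracy  diagnostic_odds_ratio
      PSS          5         1.00         0.71               0.86                    inf
      PSS          6         0.98         0.73               0.85                 116.49
      PSS          7         0.96         0.73               0.84                  56.92
      PSS          8         0.91         0.73               0.82                  27.14
      PSS          9         0.91         0.73               0.82                  27.14
      PSS         10         0.91         0.73               0.82                  27.14
     SIRS          2         1.00         0.61               0.81                    inf
    qSOFA          2         0.96         0.92               0.94                 237.08
     SOFA          2         1.00         0.98               0.99                    inf
```

Raising the surrogate threshold trades sensitivity for specificity; an
infinite DOR is the flagged degenerate case of a zero cell (no false
negatives at that threshold in this small cohort). The timeliness summary
for the same run (`out/timeliness_summary.csv`, ASE admissions only):

```text
criterion   n  pct_before_or_at  pct_after  pct_not_met  median_offset_min
     SIRS  33              36.4       63.6          0.0                 74
    qSOFA  33              21.2       72.7          6.1                137
     SOFA  33               9.1       90.9          0.0                195
      PSS  33              21.2       66.7         12.1                 91
```

Before/after/not-met always sum to the anchored cohort size. The median
PSS crossing here comes 91 minutes *after* time zero: on this synthetic
cohort, as in deployed systems, a score can classify admissions well yet
still trail the clinician's first action.

The same stages are available from the shell:

```bash
sepsisbench simulate --config cfg.yaml --out out/cohort --seed 7
sepsisbench phenotype --cohort out/cohort --out out
sepsisbench score --cohort out/cohort --criteria sirs,qsofa,sofa,pss --out out
sepsisbench run-all --config cfg.yaml --out out --seed 7
```

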