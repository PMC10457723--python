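"""Admission-level classification metrics and paired comparisons.

An admission is predicted positive by a criterion when its score stream
ever meets the positivity threshold during the whole stay (SOFA on the
rise-over-baseline scale). The reference standard is the sepsis phenotype;
both EHR-confirmed (ASE) and COVID-19 sepsis count as positive.

Because prevalence is low (~3%), plain accuracy is dominated by the
negatives; balanced accuracy ((sensitivity + specificity)/2) and the
diagnostic odds ratio (positive likelihood ratio / negative likelihood
ratio = TP*TN / (FP*FN)) are reported as prevalence-independent measures.
Proportions carry Wilson 95% CIs; the DOR carries a log-method CI,
exp(ln DOR +/- 1.96 * sqrt(1/TP + 1/FP + 1/FN + 1/TN)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError
from .phenotyping import NONSEPSIS
from .scoring import ScoreStream

SEPSIS_POSITIVE = ("ASE_SEPSIS", "COVID_SEPSIS")


def admission_prediction(stream: ScoreStream, threshold: float,
                         mode: str = "absolute") -> bool:
    """Positive iff the threshold is ever met during the admission."""
    values = stream.delta() if mode == "delta" else stream.scores
    if len(values) == 0:
        return False  # nothing computable -> nonsepsis at every time point
    return bool(np.nanmax(values) >= threshold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: pd.DataFrame, predictions: dict[str, bool]
              ) -> ConfusionCounts:
    """Cell counts of predictions against the sepsis reference standard.

    ``labels`` is the phenotype table (admission_id, category);
    ``predictions`` maps admission_id -> bool. The two must cover the same
    admissions; orphans on either side raise.
    """
    truth = {str(a): c != NONSEPSIS
             for a, c in zip(labels["admission_id"], labels["category"])}
    orphans = sorted(set(truth) ^ set(predictions))
    if orphans:
        raise DomainError(
            "admission ids not present on both sides: " + ", ".join(orphans[:20]))
    tp = fp = tn = fn = 0
    for aid, t in truth.items():
        p = predictions[aid]
        if t and p:
            tp += 1
        elif t:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def wilson_ci(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Sensitivity plus specificity, divided by 2."""
    return (sensitivity + specificity) / 2.0


def diagnostic_odds_ratio(sensitivity: float, specificity: float) -> float:
    """Positive likelihood ratio divided by negative likelihood ratio."""
    plr = sensitivity / (1.0 - specificity)
    nlr = (1.0 - sensitivity) / specificity
    return plr / nlr


@dataclass
class MetricSet:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    false_negative_prop: float   # FN / (TP + FN) = 1 - sensitivity
    false_positive_prop: float   # FP / (FP + TN) = 1 - specificity
    balanced_accuracy: float
    diagnostic_odds_ratio: float
    ci: dict[str, tuple[float, float]]


def metric_set(counts: ConfusionCounts, continuity: bool = False) -> MetricSet:
    """Classification metrics with 95% CIs from a confusion table.

    With a zero cell the DOR is undefined (inf or nan) unless ``continuity``
    enables the Haldane-Anscombe 0.5 correction. The balanced-accuracy CI
    averages the endpoint pairs of the sensitivity and specificity Wilson
    intervals.
    """
    if counts.n == 0:
        raise DomainError("empty confusion table")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n_pos, n_neg = tp + fn, fp + tn
    acc = (tp + tn) / counts.n
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")

    ci = {
        "accuracy": wilson_ci(tp + tn, counts.n),
        "sensitivity": wilson_ci(tp, n_pos),
        "specificity": wilson_ci(tn, n_neg),
        "false_negative_prop": wilson_ci(fn, n_pos),
        "false_positive_prop": wilson_ci(fp, n_neg),
    }
    ci["balanced_accuracy"] = (
        (ci["sensitivity"][0] + ci["specificity"][0]) / 2.0,
        (ci["sensitivity"][1] + ci["specificity"][1]) / 2.0)

    cells = (tp, fp, tn, fn)
    if continuity and 0 in cells:
        cells = tuple(c + 0.5 for c in cells)
    ctp, cfp, ctn, cfn = cells
    if min(cfp, cfn) > 0:
        dor = (ctp * ctn) / (cfp * cfn)
    else:
        dor = float("inf") if min(ctp, ctn) > 0 else float("nan")
    if all(c > 0 for c in cells) and math.isfinite(dor):
        se = math.sqrt(sum(1.0 / c for c in cells))
        ci["diagnostic_odds_ratio"] = (dor * math.exp(-1.96 * se),
                                       dor * math.exp(1.96 * se))
    else:
        ci["diagnostic_odds_ratio"] = (float("nan"), float("nan"))

    return MetricSet(
        counts=counts, accuracy=acc, sensitivity=sens, specificity=spec,
        false_negative_prop=fn / n_pos if n_pos else float("nan"),
        false_positive_prop=fp / n_neg if n_neg else float("nan"),
        balanced_accuracy=balanced_accuracy(sens, spec),
        diagnostic_odds_ratio=dor, ci=ci)


def mcnemar(pred_a: dict[str, bool], pred_b: dict[str, bool],
            labels: pd.DataFrame) -> tuple[float, float]:
    """Paired comparison of two criteria's classification correctness.

    Discordant counts b (A correct, B wrong) and c (A wrong, B correct)
    feed the continuity-corrected chi-square (|b-c|-1)^2/(b+c); when
    b + c < 25 the exact binomial test is used instead (the returned
    statistic is then min(b, c)). b + c = 0 returns (0.0, 1.0).
    """
    truth = {str(a): c != NONSEPSIS
             for a, c in zip(labels["admission_id"], labels["category"])}
    orphans = sorted((set(truth) ^ set(pred_a)) | (set(truth) ^ set(pred_b)))
    if orphans:
        raise DomainError(
            "admission ids not present on all sides: " + ", ".join(orphans[:20]))
    b = sum(1 for aid, t in truth.items()
            if pred_a[aid] == t and pred_b[aid] != t)
    c = sum(1 for aid, t in truth.items()
            if pred_a[aid] != t and pred_b[aid] == t)
    if b + c == 0:
        return 0.0, 1.0
    table = [[0, b], [c, 0]]  # only discordants matter
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(res.pvalue)


def prevalence(labels: pd.DataFrame) -> tuple[float, float, float]:
    """Sepsis proportion (ASE + COVID) with a Wilson 95% CI."""
    n = len(labels)
    if n == 0:
        raise DomainError("no labels")
    count = int((labels["category"] != NONSEPSIS).sum())
    lo, hi = wilson_ci(count, n)
    return count / n, lo, hi


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def round_rate(x: float) -> float:
    """Report rounding for rates: 2 decimals."""
    return float(f"{x:.2f}") if math.isfinite(x) else x


def round_pct(x: float) -> float:
    """Report rounding for percentages: 1 decimal."""
    return float(f"{x:.1f}") if math.isfinite(x) else x


def classification_table(
    labels: pd.DataFrame,
    streams: dict[str, dict[str, ScoreStream]],
    pss_thresholds=(5, 6, 7, 8, 9, 10),
) -> pd.DataFrame:
    """Whole-stay classification metrics per criterion (``table2.csv``).

    One row per surrogate threshold plus SIRS >= 2, qSOFA >= 2 and SOFA
    rise >= 2.
    """
    rows = []
    spec_rows = [("PSS", float(t), "absolute") for t in pss_thresholds]
    spec_rows += [("SIRS", 2.0, "absolute"), ("qSOFA", 2.0, "absolute"),
                  ("SOFA", 2.0, "delta")]
    available = (set.intersection(*(set(s) for s in streams.values()))
                 if streams else set())
    for criterion, threshold, mode in spec_rows:
        if criterion not in available:
            continue
        preds = {aid: admission_prediction(streams[aid][criterion], threshold, mode)
                 for aid in streams}
        ms = metric_set(confusion(labels, preds))
        row = {"criterion": criterion, "threshold": threshold,
               "tp": ms.counts.tp, "fp": ms.counts.fp,
               "tn": ms.counts.tn, "fn": ms.counts.fn}
        for name in ("accuracy", "sensitivity", "specificity",
                     "false_negative_prop", "false_positive_prop",
                     "balanced_accuracy", "diagnostic_odds_ratio"):
            row[name] = getattr(ms, name)
            row[f"{name}_ci_low"], row[f"{name}_ci_high"] = ms.ci[name]
        rows.append(row)
    return pd.DataFrame(rows)


def mcnemar_table(labels: pd.DataFrame,
                  streams: dict[str, dict[str, ScoreStream]],
                  pss_thresholds=(5, 6, 7, 8, 9, 10)) -> pd.DataFrame:
    """Pairwise McNemar tests: each bedside criterion vs each surrogate
    threshold (``mcnemar.csv``)."""
    preds: dict[str, dict[str, bool]] = {}
    for t in pss_thresholds:
        preds[f"PSS>={t}"] = {
            aid: admission_prediction(streams[aid]["PSS"], float(t))
            for aid in streams}
    for criterion, threshold, mode in (("SIRS", 2.0, "absolute"),
                                       ("qSOFA", 2.0, "absolute"),
                                       ("SOFA", 2.0, "delta")):
        preds[criterion] = {
            aid: admission_prediction(streams[aid][criterion], threshold, mode)
            for aid in streams}
    rows = []
    for bedside in ("SIRS", "qSOFA", "SOFA"):
        for t in pss_thresholds:
            stat, p = mcnemar(preds[bedside], preds[f"PSS>={t}"], labels)
            rows.append({"criterion_a": bedside, "criterion_b": f"PSS>={t}",
                         "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def cohort_table(
    admissions: pd.DataFrame,
    labels: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "los_days"),
    categorical: tuple[str, ...] = ("sex", "race_ethnicity", "site",
                                    "source", "disposition"),
) -> pd.DataFrame:
    """Baseline-characteristics table across the three phenotype groups.

    Continuous variables: per-group median (IQR), Kruskal-Wallis p.
    Categorical variables: per-level group counts (%), chi-square p on the
    level-by-group contingency table. A variable with no usable values is
    emitted with ``computable = False``.
    """
    df = admissions.merge(labels[["admission_id", "category"]], on="admission_id")
    df = df.copy()
    df["los_days"] = (df["discharge_min"] - df["admit_min"]) / 1440.0
    groups = ["ASE_SEPSIS", "COVID_SEPSIS", NONSEPSIS]
    rows = []
    for var in continuous:
        if var not in df.columns or df[var].dropna().empty:
            rows.append({"variable": var, "type": "continuous",
                         "level": "", "computable": False})
            continue
        samples = [df.loc[df["category"] == g, var].dropna() for g in groups]
        usable = [s for s in samples if len(s)]
        p = float("nan")
        if len(usable) >= 2 and len(np.unique(np.concatenate(usable))) > 1:
            p = float(stats.kruskal(*usable).pvalue)
        row = {"variable": var, "type": "continuous", "level": "",
               "computable": True, "test": "kruskal-wallis", "p_value": p}
        for g, s in zip(groups, samples):
            q = s.quantile([0.25, 0.5, 0.75]) if len(s) else None
            row[f"{g}_summary"] = (
                "" if q is None
                else f"{q[0.5]:.2f} ({q[0.25]:.2f}-{q[0.75]:.2f})")
        rows.append(row)
    for var in categorical:
        if var not in df.columns or df[var].dropna().empty:
            rows.append({"variable": var, "type": "categorical",
                         "level": "", "computable": False})
            continue
        ct = pd.crosstab(df[var], df["category"])
        ct = ct.reindex(columns=[g for g in groups if g in ct.columns],
                        fill_value=0)
        p = float("nan")
        if ct.shape[0] > 1 and ct.shape[1] > 1 and ct.to_numpy().sum() > 0:
            p = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        for level in ct.index:
            row = {"variable": var, "type": "categorical",
                   "level": str(level), "computable": True,
                   "test": "chi2", "p_value": p}
            for g in groups:
                n_g = int((df["category"] == g).sum())
                c = int(ct.loc[level, g]) if g in ct.columns else 0
                pct = 100.0 * c / n_g if n_g else float("nan")
                row[f"{g}_summary"] = f"{c} ({pct:.1f})"
            rows.append(row)
    return pd.DataFrame(rows)
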