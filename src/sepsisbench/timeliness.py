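"""Alert timeliness relative to time zero.

Time zero is 15 minutes before the first clinician action -- the earliest
antimicrobial or blood-culture order -- so that order-driven score inflation
cannot make a score look prospectively timely. A clinician ordering
antibiotics at 2:00 pm puts time zero at 1:45 pm. Signed offsets are
crossing_time - time_zero: negative means the criterion crossed its
threshold before time zero (a prospectively useful alert), positive after;
an offset of exactly 0 counts as before-or-at. Admissions with no
qualifying order have undefined time zero and are excluded with a logged
count.

The same machinery re-anchors on the first eSOFA organ-dysfunction event to
compare score timing with the onset of organ dysfunction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import NOT_MET, ScoreStream, first_threshold_time

logger = logging.getLogger(__name__)

UNDEFINED = None

BEFORE_OR_AT = "BEFORE_OR_AT"
AFTER = "AFTER"
NOT_MET_CAT = "NOT_MET"

#: positivity threshold and comparison mode per criterion
DEFAULT_THRESHOLDS: dict[str, tuple[float, str]] = {
    "SIRS": (2.0, "absolute"),
    "qSOFA": (2.0, "absolute"),
    "SOFA": (2.0, "delta"),
    "PSS": (8.0, "absolute"),
}


def time_zero(orders: pd.DataFrame):
    """15 min before the first antimicrobial or blood-culture order.

    Returns UNDEFINED (None) when the admission has neither order.
    """
    sel = orders.loc[orders["kind"].isin(("antimicrobial", "blood_culture")),
                     "time_min"]
    if len(sel) == 0:
        return UNDEFINED
    return int(sel.min()) - 15


@dataclass
class ThresholdCrossing:
    admission_id: str
    criterion: str
    threshold: float
    crossing_min: int | None      # None = threshold never met
    signed_offset_min: int | None  # crossing - anchor; None when not met

    @property
    def category(self) -> str:
        if self.crossing_min is None:
            return NOT_MET_CAT
        return BEFORE_OR_AT if self.signed_offset_min <= 0 else AFTER


def crossing_for(stream: ScoreStream, anchor_min: int, threshold: float,
                 mode: str = "absolute") -> ThresholdCrossing:
    """Signed threshold-crossing offset of one stream against one anchor."""
    t = first_threshold_time(stream, threshold, mode)
    if t is NOT_MET:
        return ThresholdCrossing(stream.admission_id, stream.criterion,
                                 threshold, None, None)
    return ThresholdCrossing(stream.admission_id, stream.criterion,
                             threshold, int(t), int(t) - int(anchor_min))


@dataclass
class TimelinessSummary:
    criterion: str
    threshold: float
    n: int
    n_before_or_at: int
    n_after: int
    n_not_met: int
    median_offset_min: float   # over threshold-met admissions only; NaN if none
    iqr_low_min: float
    iqr_high_min: float

    @property
    def pct_before_or_at(self) -> float:
        return 100.0 * self.n_before_or_at / self.n if self.n else float("nan")

    @property
    def pct_after(self) -> float:
        return 100.0 * self.n_after / self.n if self.n else float("nan")

    @property
    def pct_not_met(self) -> float:
        return 100.0 * self.n_not_met / self.n if self.n else float("nan")


def timeliness_summary(crossings: list[ThresholdCrossing],
                       criterion: str = "", threshold: float = float("nan")
                       ) -> TimelinessSummary:
    """Category counts over all admissions; median/IQR offset over the
    admissions where the threshold was met."""
    if crossings:
        criterion = crossings[0].criterion
        threshold = crossings[0].threshold
    offsets = np.array([c.signed_offset_min for c in crossings
                        if c.signed_offset_min is not None], dtype=float)
    cats = [c.category for c in crossings]
    if offsets.size:
        median = float(np.median(offsets))
        q1, q3 = (float(q) for q in np.percentile(offsets, [25, 75]))
    else:
        median = q1 = q3 = float("nan")
    return TimelinessSummary(
        criterion=criterion, threshold=threshold, n=len(crossings),
        n_before_or_at=cats.count(BEFORE_OR_AT),
        n_after=cats.count(AFTER),
        n_not_met=cats.count(NOT_MET_CAT),
        median_offset_min=median, iqr_low_min=q1, iqr_high_min=q3)


def summaries_to_frame(summaries: list[TimelinessSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "criterion": s.criterion, "threshold": s.threshold, "n": s.n,
            "n_before_or_at": s.n_before_or_at, "n_after": s.n_after,
            "n_not_met": s.n_not_met,
            "pct_before_or_at": s.pct_before_or_at,
            "pct_after": s.pct_after, "pct_not_met": s.pct_not_met,
            "median_offset_min": s.median_offset_min,
            "iqr_low_min": s.iqr_low_min, "iqr_high_min": s.iqr_high_min})
    return pd.DataFrame(rows)


def crossing_curve(crossings: list[ThresholdCrossing],
                   stay_minutes: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-admission rows for a cumulative-crossing plot.

    Threshold-met admissions sorted by signed offset (ties broken by
    admission_id), with the cumulative proportion of all admissions that
    crossed at or before each offset; never-met admissions follow, flagged.
    """
    met = sorted((c for c in crossings if c.signed_offset_min is not None),
                 key=lambda c: (c.signed_offset_min, c.admission_id))
    unmet = sorted((c for c in crossings if c.signed_offset_min is None),
                   key=lambda c: c.admission_id)
    n = len(crossings)
    rows = []
    for i, c in enumerate(met, start=1):
        rows.append({
            "admission_id": c.admission_id, "criterion": c.criterion,
            "signed_offset_min": float(c.signed_offset_min),
            "cumulative_proportion": i / n, "met": True,
            "stay_min": (stay_minutes or {}).get(c.admission_id, np.nan)})
    for c in unmet:
        rows.append({
            "admission_id": c.admission_id, "criterion": c.criterion,
            "signed_offset_min": np.nan,
            "cumulative_proportion": np.nan, "met": False,
            "stay_min": (stay_minutes or {}).get(c.admission_id, np.nan)})
    return pd.DataFrame(rows, columns=[
        "admission_id", "criterion", "signed_offset_min",
        "cumulative_proportion", "met", "stay_min"])


def organ_dysfunction_offset(stream: ScoreStream, first_esofa_min: int,
                             threshold: float, mode: str = "absolute"
                             ) -> ThresholdCrossing:
    """Crossing offset re-anchored on the first organ-dysfunction event."""
    return crossing_for(stream, first_esofa_min, threshold, mode)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def timeliness_cohort(
    cohort,
    labels: pd.DataFrame,
    streams: dict[str, dict[str, ScoreStream]],
    thresholds: dict[str, tuple[float, str]] | None = None,
    anchor: str = "timezero",
    sepsis_categories: tuple[str, ...] = ("ASE_SEPSIS",),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Crossings, summaries and curve table for the timeliness cohort.

    The default cohort is EHR-confirmed (ASE) sepsis admissions with a
    defined anchor; admissions without one are dropped with a logged count.
    ``anchor`` is ``'timezero'`` or ``'esofa'`` (first organ-dysfunction
    event). Returns (crossings, summary, curve) tables.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    lab = labels.set_index("admission_id")
    ord_g = dict(tuple(cohort.orders.groupby("admission_id")))
    stay = {str(r["admission_id"]): int(r["discharge_min"]) - int(r["admit_min"])
            for _, r in cohort.admissions.iterrows()}

    ids = [aid for aid in lab.index
           if lab.loc[aid, "category"] in sepsis_categories]
    anchors: dict[str, int] = {}
    n_skipped = 0
    for aid in ids:
        if anchor == "timezero":
            orders = ord_g.get(aid)
            tz = time_zero(orders) if orders is not None else UNDEFINED
        elif anchor == "esofa":
            v = lab.loc[aid, "first_esofa_min"]
            tz = None if pd.isna(v) else int(v)
        else:
            raise ValueError(f"unknown anchor: {anchor}")
        if tz is UNDEFINED:
            n_skipped += 1
            continue
        anchors[aid] = tz
    if n_skipped:
        logger.info("timeliness: %d admission(s) without a defined %s anchor",
                    n_skipped, anchor)

    all_crossings: list[ThresholdCrossing] = []
    summaries: list[TimelinessSummary] = []
    curves = []
    for criterion, (threshold, mode) in thresholds.items():
        crossings = [crossing_for(streams[aid][criterion], anchors[aid],
                                  threshold, mode)
                     for aid in anchors if criterion in streams.get(aid, {})]
        all_crossings.extend(crossings)
        summaries.append(timeliness_summary(crossings, criterion, threshold))
        curves.append(crossing_curve(crossings, stay))

    crossing_rows = pd.DataFrame([{
        "admission_id": c.admission_id, "criterion": c.criterion,
        "threshold": c.threshold, "crossing_min": c.crossing_min,
        "signed_offset_min": c.signed_offset_min, "category": c.category,
    } for c in all_crossings])
    curve = (pd.concat(curves, ignore_index=True) if curves
             else crossing_curve([]))
    return crossing_rows, summaries_to_frame(summaries), curve


def plot_crossing_curve(curve: pd.DataFrame, path: str) -> None:
    """Minimal cumulative-crossing figure (one panel per criterion)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    criteria = sorted(curve["criterion"].unique())
    fig, axes = plt.subplots(1, max(len(criteria), 1),
                             figsize=(4 * max(len(criteria), 1), 3.2),
                             squeeze=False)
    for ax, criterion in zip(axes[0], criteria):
        sub = curve[(curve["criterion"] == criterion) & curve["met"]]
        before = sub[sub["signed_offset_min"] <= 0]
        after = sub[sub["signed_offset_min"] > 0]
        ax.step(before["signed_offset_min"] / 1440.0,
                before["cumulative_proportion"], where="post", color="tab:blue")
        ax.step(after["signed_offset_min"] / 1440.0,
                after["cumulative_proportion"], where="post", color="tab:orange")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(criterion)
        ax.set_xlabel("days from time zero")
        ax.set_ylabel("cumulative proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
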