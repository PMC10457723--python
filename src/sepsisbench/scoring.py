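"""Score streams: SIRS, qSOFA, SOFA, and a transparent 15-minute surrogate
for a proprietary EHR sepsis risk score.

Each criterion is evaluated against an element *snapshot*: the most recent
observation of each element carried forward within an element-specific
validity window (vitals 8 h, labs 24 h by default, inclusive at the
boundary). An element with no in-window value is absent and contributes no
points -- a criterion that cannot be computed reads as non-septic at that
time point. Clinically impossible values are dropped before scoring.

SIRS/qSOFA/SOFA are event-driven (recomputed whenever any element updates);
the surrogate is recomputed on a fixed 15-minute grid and additionally
inflates after an antimicrobial order (an additive bump with exponential
decay), mimicking order-driven score inflation in deployed systems. All
streams are right-continuous step functions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, empty_table
from .config import PssSurrogateParams, ScoringConfig

logger = logging.getLogger(__name__)

NOT_MET = None

CRITERIA = ("SIRS", "qSOFA", "SOFA", "PSS")

#: plausibility bounds; values outside are dropped with a log entry
ELEMENT_BOUNDS: dict[str, tuple[float, float]] = {
    "temperature": (25.0, 45.0),
    "heart_rate": (10.0, 300.0),
    "resp_rate": (1.0, 80.0),
    "sbp": (20.0, 300.0),
    "map": (10.0, 250.0),
    "gcs": (3.0, 15.0),
    "wbc": (0.1, 200.0),
    "bands": (0.0, 100.0),
    "platelets": (1.0, 2000.0),
    "creatinine": (0.05, 30.0),
    "bilirubin": (0.0, 60.0),
    "lactate": (0.0, 30.0),
    "pf_ratio": (20.0, 700.0),
    "paco2": (5.0, 150.0),
}

_VITALS = ("temperature", "heart_rate", "resp_rate", "sbp", "map")
_LABS = ("wbc", "bands", "platelets", "creatinine", "bilirubin", "lactate",
         "pf_ratio", "paco2")

#: standard 0-4 organ subscore bands: (lower-inclusive threshold, points),
#: scanned from worst to best. Respiration bands are applied without the
#: ventilation co-requirement for 3-4 points; cardiovascular uses a
#: dose-free vasopressor band (any active vasopressor -> 3).
SOFA_BANDS: dict[str, list[tuple[float, int]]] = {
    # element, descending severity; predicate direction noted per organ
    "pf_ratio":   [(100.0, 4), (200.0, 3), (300.0, 2), (400.0, 1)],  # value < t
    "platelets":  [(20.0, 4), (50.0, 3), (100.0, 2), (150.0, 1)],    # value < t
    "bilirubin":  [(12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)],         # value >= t
    "creatinine": [(5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)],          # value >= t
    "gcs":        [(6.0, 4), (10.0, 3), (13.0, 2), (15.0, 1)],       # value < t
}
SOFA_VASOPRESSOR_POINTS = 3
SOFA_MAP_THRESHOLD = 70.0


def clean_observations(observations: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split observations into (plausible, dropped) by element bounds."""
    lo = observations["element"].map(lambda e: ELEMENT_BOUNDS.get(e, (-np.inf,))[0])
    hi = observations["element"].map(
        lambda e: ELEMENT_BOUNDS.get(e, (None, np.inf))[-1])
    ok = (observations["value"] >= lo) & (observations["value"] <= hi)
    dropped = observations[~ok]
    if len(dropped):
        logger.info("dropped %d implausible observation(s)", len(dropped))
    return (observations[ok].reset_index(drop=True),
            dropped.reset_index(drop=True))


def element_validity(element: str, config: ScoringConfig) -> float:
    if element == "gcs":
        return config.validity_gcs_min
    if element in _VITALS:
        return config.validity_vitals_min
    return config.validity_labs_min


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def _series_by_element(observations: pd.DataFrame
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for element, grp in observations.groupby("element"):
        grp = grp.sort_values("time_min", kind="stable")
        out[str(element)] = (grp["time_min"].to_numpy(dtype=float),
                             grp["value"].to_numpy(dtype=float))
    return out


def _values_at(series: dict[str, tuple[np.ndarray, np.ndarray]],
               times: np.ndarray, config: ScoringConfig
               ) -> dict[str, np.ndarray]:
    """Last in-window value of each element at each query time (NaN absent)."""
    out: dict[str, np.ndarray] = {}
    for element, (t, v) in series.items():
        idx = np.searchsorted(t, times, side="right") - 1
        vals = np.full(times.shape, np.nan)
        has = idx >= 0
        window = element_validity(element, config)
        age = np.where(has, times - t[np.clip(idx, 0, None)], np.inf)
        usable = has & (age <= window)
        vals[usable] = v[idx[usable]]
        out[element] = vals
    return out


def evaluate_elements(observations: pd.DataFrame, at_time: float,
                      config: ScoringConfig | None = None
                      ) -> dict[str, float]:
    """Element snapshot at one time: most recent in-window value per element.

    Elements never observed, or whose last value has aged past its validity
    window (inclusive at the boundary), are omitted from the result.
    """
    config = config or ScoringConfig()
    series = _series_by_element(observations)
    at = np.asarray([float(at_time)])
    vals = _values_at(series, at, config)
    return {e: float(v[0]) for e, v in vals.items() if not np.isnan(v[0])}


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------

@dataclass
class ScoreStream:
    """One criterion's (time, score) trajectory for one admission.

    For SOFA, ``scores`` holds the six-organ total and ``baseline`` the
    reference total; positivity is judged on ``scores - baseline``.
    """
    admission_id: str
    criterion: str
    times: np.ndarray
    scores: np.ndarray
    baseline: float = 0.0

    def delta(self) -> np.ndarray:
        return self.scores - self.baseline

    def max_score(self) -> float:
        return float(self.scores.max()) if len(self.scores) else float("-inf")


def first_threshold_time(stream: ScoreStream, threshold: float,
                         mode: str = "absolute"):
    """Earliest time at which the stream meets the threshold, else NOT_MET.

    ``mode='absolute'`` compares the score itself; ``mode='delta'`` compares
    the rise above the stream's baseline (the SOFA >= 2-point convention).
    """
    values = stream.delta() if mode == "delta" else stream.scores
    hit = np.flatnonzero(values >= threshold)
    if hit.size == 0:
        return NOT_MET
    return int(stream.times[hit[0]])


def _event_times(observations: pd.DataFrame,
                 extra: np.ndarray | None = None) -> np.ndarray:
    t = observations["time_min"].to_numpy(dtype=float)
    if extra is not None and extra.size:
        t = np.concatenate([t, extra.astype(float)])
    return np.unique(t)


def _sirs_scores(vals: dict[str, np.ndarray], n: int) -> np.ndarray:
    def g(e):  # absent -> NaN; NaN comparisons are False, i.e. no points
        return vals.get(e, np.full(n, np.nan))

    temp, hr, rr = g("temperature"), g("heart_rate"), g("resp_rate")
    paco2, wbc, bands = g("paco2"), g("wbc"), g("bands")
    with np.errstate(invalid="ignore"):
        c1 = (temp > 38.0) | (temp < 36.0)
        c2 = hr > 90.0
        c3 = (rr > 20.0) | (paco2 < 32.0)
        c4 = (wbc > 12.0) | (wbc < 4.0) | (bands > 10.0)
    return (c1.astype(int) + c2.astype(int) + c3.astype(int) + c4.astype(int)
            ).astype(float)


def _qsofa_scores(vals: dict[str, np.ndarray], n: int) -> np.ndarray:
    def g(e):
        return vals.get(e, np.full(n, np.nan))

    with np.errstate(invalid="ignore"):
        c1 = g("resp_rate") >= 22.0
        c2 = g("sbp") <= 100.0
        c3 = g("gcs") < 15.0
    return (c1.astype(int) + c2.astype(int) + c3.astype(int)).astype(float)


def _band_points_lt(values: np.ndarray, bands) -> np.ndarray:
    pts = np.zeros(values.shape)
    with np.errstate(invalid="ignore"):
        for threshold, p in sorted(bands, key=lambda b: b[0]):
            mask = (values < threshold) & (pts == 0)
            pts[mask] = p
    return pts


def _band_points_ge(values: np.ndarray, bands) -> np.ndarray:
    pts = np.zeros(values.shape)
    with np.errstate(invalid="ignore"):
        for threshold, p in sorted(bands, key=lambda b: -b[0]):
            mask = (values >= threshold) & (pts == 0)
            pts[mask] = p
    return pts


def _sofa_totals(vals: dict[str, np.ndarray], times: np.ndarray,
                 vaso_times: np.ndarray, config: ScoringConfig) -> np.ndarray:
    n = len(times)

    def g(e):
        return vals.get(e, np.full(n, np.nan))

    resp = _band_points_lt(g("pf_ratio"), SOFA_BANDS["pf_ratio"])
    coag = _band_points_lt(g("platelets"), SOFA_BANDS["platelets"])
    cns = _band_points_lt(g("gcs"), SOFA_BANDS["gcs"])
    liver = _band_points_ge(g("bilirubin"), SOFA_BANDS["bilirubin"])
    renal = _band_points_ge(g("creatinine"), SOFA_BANDS["creatinine"])

    cardio = np.zeros(n)
    with np.errstate(invalid="ignore"):
        cardio[g("map") < SOFA_MAP_THRESHOLD] = 1
    if vaso_times.size:
        idx = np.searchsorted(vaso_times, times, side="right") - 1
        age = np.where(idx >= 0, times - vaso_times[np.clip(idx, 0, None)], np.inf)
        active = age <= config.validity_labs_min
        cardio[active] = SOFA_VASOPRESSOR_POINTS
    return resp + coag + cns + liver + renal + cardio


def sirs_stream(observations: pd.DataFrame, admission_id: str = "",
                config: ScoringConfig | None = None) -> ScoreStream:
    """SIRS count (0-4): temp >38 or <36; HR >90; RR >20 or PaCO2 <32;
    WBC >12 or <4 or bands >10%. Strict inequalities throughout."""
    config = config or ScoringConfig()
    times = _event_times(observations)
    series = _series_by_element(observations)
    vals = _values_at(series, times, config)
    return ScoreStream(admission_id, "SIRS", times,
                       _sirs_scores(vals, len(times)))


def qsofa_stream(observations: pd.DataFrame, admission_id: str = "",
                 config: ScoringConfig | None = None) -> ScoreStream:
    """qSOFA count (0-3): RR >= 22; SBP <= 100; GCS < 15."""
    config = config or ScoringConfig()
    times = _event_times(observations)
    series = _series_by_element(observations)
    vals = _values_at(series, times, config)
    return ScoreStream(admission_id, "qSOFA", times,
                       _qsofa_scores(vals, len(times)))


def sofa_stream(observations: pd.DataFrame, orders: pd.DataFrame,
                admission_id: str = "",
                config: ScoringConfig | None = None) -> ScoreStream:
    """Six-organ SOFA total, recomputed at every element or vasopressor
    update. Positivity is judged on the rise over ``baseline``: 0 under the
    default convention, or the first computed total when
    ``config.sofa_baseline == 'first'``."""
    config = config or ScoringConfig()
    vaso = np.sort(orders.loc[orders["kind"] == "vasopressor",
                              "time_min"].to_numpy(dtype=float))
    times = _event_times(observations, extra=vaso)
    series = _series_by_element(observations)
    vals = _values_at(series, times, config)
    totals = _sofa_totals(vals, times, vaso, config)
    baseline = 0.0
    if config.sofa_baseline == "first" and len(totals):
        baseline = float(totals[0])
    return ScoreStream(admission_id, "SOFA", times, totals, baseline=baseline)


#: feature functions of the surrogate score: hinge-shaped abnormality
#: measures, each ~1 per "one unit of clinical concern"
def _pss_features(vals: dict[str, np.ndarray], n: int) -> dict[str, np.ndarray]:
    def g(e):
        return vals.get(e, np.full(n, np.nan))

    def hinge(x):
        return np.where(np.isnan(x), 0.0, np.maximum(x, 0.0))

    temp, hr, rr = g("temperature"), g("heart_rate"), g("resp_rate")
    sbp, gcs, wbc = g("sbp"), g("gcs"), g("wbc")
    lact, creat = g("lactate"), g("creatinine")
    return {
        "temp_dev": hinge(temp - 38.0) + hinge(36.0 - temp),
        "hr_excess": hinge((hr - 90.0) / 10.0),
        "rr_excess": hinge((rr - 20.0) / 5.0),
        "sbp_deficit": hinge((100.0 - sbp) / 10.0),
        "gcs_deficit": hinge(15.0 - gcs),
        "wbc_dev": hinge((wbc - 12.0) / 4.0) + hinge((4.0 - wbc) / 2.0),
        "lactate_excess": hinge(lact - 2.0),
        "creatinine_excess": hinge(creat - 1.2),
    }


def pss_surrogate_stream(observations: pd.DataFrame, orders: pd.DataFrame,
                         los_min: int, admission_id: str = "",
                         config: ScoringConfig | None = None,
                         params: PssSurrogateParams | None = None
                         ) -> ScoreStream:
    """Surrogate predictive score on the 15-minute grid.

    score(t) = scale * logistic(intercept + sum w_i f_i(snapshot_t))
             + bump * exp(-(t - t_last_antimicrobial_order) / decay)

    The bump term models order-driven score inflation: any antimicrobial
    order transiently raises the score regardless of physiology.
    """
    config = config or ScoringConfig()
    params = params or config.pss
    step = config.pss_grid_min
    times = np.arange(0, max(int(los_min), 0) + 1, step, dtype=float)
    series = _series_by_element(observations)
    vals = _values_at(series, times, config)
    feats = _pss_features(vals, len(times))
    raw = np.full(len(times), params.intercept)
    for name, weight in params.weights.items():
        raw = raw + weight * feats.get(name, 0.0)
    scores = params.scale * expit(raw)

    abx = np.sort(orders.loc[orders["kind"] == "antimicrobial",
                             "time_min"].to_numpy(dtype=float))
    if abx.size and params.order_bump > 0:
        idx = np.searchsorted(abx, times, side="right") - 1
        age = np.where(idx >= 0, times - abx[np.clip(idx, 0, None)], np.inf)
        scores = scores + params.order_bump * np.exp(-age / params.order_bump_decay_min)
    return ScoreStream(admission_id, "PSS", times, scores)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def score_admission(observations: pd.DataFrame, orders: pd.DataFrame,
                    los_min: int, admission_id: str,
                    criteria=CRITERIA,
                    config: ScoringConfig | None = None
                    ) -> dict[str, ScoreStream]:
    config = config or ScoringConfig()
    observations, _ = clean_observations(observations)
    out: dict[str, ScoreStream] = {}
    for criterion in criteria:
        if criterion == "SIRS":
            out[criterion] = sirs_stream(observations, admission_id, config)
        elif criterion == "qSOFA":
            out[criterion] = qsofa_stream(observations, admission_id, config)
        elif criterion == "SOFA":
            out[criterion] = sofa_stream(observations, orders, admission_id, config)
        elif criterion == "PSS":
            out[criterion] = pss_surrogate_stream(
                observations, orders, los_min, admission_id, config)
        else:
            raise ValueError(f"unknown criterion: {criterion}")
    return out


def score_cohort(cohort: Cohort, criteria=CRITERIA,
                 config: ScoringConfig | None = None
                 ) -> dict[str, dict[str, ScoreStream]]:
    """Streams for every admission: ``{admission_id: {criterion: stream}}``."""
    config = config or ScoringConfig()
    obs_g = dict(tuple(cohort.observations.groupby("admission_id")))
    ord_g = dict(tuple(cohort.orders.groupby("admission_id")))
    out: dict[str, dict[str, ScoreStream]] = {}
    for _, adm in cohort.admissions.iterrows():
        aid = str(adm["admission_id"])
        los = int(adm["discharge_min"]) - int(adm["admit_min"])
        obs = obs_g.get(aid, empty_table("observations"))
        orders = ord_g.get(aid, empty_table("orders"))
        out[aid] = score_admission(obs, orders, los, aid, criteria, config)
    return out


def streams_to_frame(streams: dict[str, dict[str, ScoreStream]]) -> pd.DataFrame:
    """Long-form ``scores.csv`` table (admission_id, criterion, time_min, score)."""
    rows = []
    for aid in streams:
        for criterion, s in streams[aid].items():
            rows.append(pd.DataFrame({
                "admission_id": aid, "criterion": criterion,
                "time_min": s.times.astype(int), "score": s.scores}))
    if not rows:
        return pd.DataFrame(columns=["admission_id", "criterion", "time_min", "score"])
    return pd.concat(rows, ignore_index=True)
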