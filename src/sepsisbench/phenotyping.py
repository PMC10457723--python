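"""Reference-standard sepsis phenotyping.

Implements the CDC Adult Sepsis Event (ASE) surveillance definition:

* presumed infection -- a blood culture with >= 4 qualifying antimicrobial
  days (QADs) beginning within +/- 2 calendar days of culture collection
  (fewer days qualify when therapy ran through the day of death and the
  death exemption is enabled); and
* concurrent organ dysfunction by EHR-optimised criteria (eSOFA):
  vasopressor initiation, mechanical-ventilation initiation, creatinine
  doubling, bilirubin >= 2.0 mg/dL and doubled, platelet fall to < 100 with
  >= 50% decline from a baseline >= 100, or lactate >= 2.0 mmol/L.

A COVID-19-specific sepsis definition (ICD-10 U07.1x plus >= 1 eSOFA event,
no culture/antimicrobial requirement) and septic shock (R65.21 / T81.12XA or
vasopressor use during a sepsis admission) sit alongside, together with the
pre-analysis exclusion cascade and the Charlson Comorbidity Index.

Lab baselines are the first recorded in-admission value. Calendar days are
``time_min // 1440`` (admissions begin at midnight of day 0).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import MINUTES_PER_DAY, PhenotypeConfig

logger = logging.getLogger(__name__)

ASE_SEPSIS = "ASE_SEPSIS"
COVID_SEPSIS = "COVID_SEPSIS"
NONSEPSIS = "NONSEPSIS"

COVID_CODE_PREFIX = "U071"
SHOCK_CODE_PREFIXES = ("R6521", "T8112")
SEPSIS_RELATED_CODE_PREFIXES = ("A40", "A41", "R652", "T8112", "U071")

EXCLUSION_RULES = (
    "burn_service",
    "los_gt_30d",
    "ama",
    "transfer",
    "sepsis_readmission_30d",
    "no_bp_temp",
)

_BP_ELEMENTS = ("sbp", "map")


def _load_list(name: str) -> frozenset[str]:
    with resources.files("sepsisbench.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh)
    return frozenset(df["drug"].astype(str))


def qualifying_antimicrobial_list() -> frozenset[str]:
    return _load_list("qualifying_antimicrobials.csv")


def vasopressor_list() -> frozenset[str]:
    return _load_list("vasopressors.csv")


def load_cci_weights() -> pd.DataFrame:
    """Quan ICD-10 prefix map with original Charlson weights."""
    with resources.files("sepsisbench.data").joinpath("cci_quan_icd10.csv").open("r") as fh:
        return pd.read_csv(fh, dtype={"code_prefix": str})


# ---------------------------------------------------------------------------
# qualifying antimicrobial days
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QadEpisode:
    start_day: int
    n_days: int
    death_exempt: bool

    def qualifies(self, min_days: int) -> bool:
        return self.n_days >= min_days or self.death_exempt


def qualifying_antimicrobial_days(
    orders: pd.DataFrame,
    *,
    qualifying: frozenset[str] | None = None,
    los_min: int | None = None,
    disposition: str = "",
    config: PhenotypeConfig | None = None,
) -> list[QadEpisode]:
    """Maximal runs of calendar days with qualifying antimicrobial therapy.

    A run may bridge up to ``config.qad_gap_days`` empty days. An episode
    whose run reaches the day of death (or the day before) is flagged
    ``death_exempt`` when the admission ended in death and the exemption is
    enabled; such episodes qualify with fewer than the minimum days.
    """
    config = config or PhenotypeConfig()
    if qualifying is None:
        qualifying = qualifying_antimicrobial_list()
    mask = (orders["kind"] == "antimicrobial") & orders["detail"].isin(qualifying)
    if not mask.any():
        return []
    days = np.unique(orders.loc[mask, "time_min"].to_numpy() // MINUTES_PER_DAY)
    episodes: list[QadEpisode] = []
    run: list[int] = [int(days[0])]
    for d in days[1:]:
        if d - run[-1] <= config.qad_gap_days + 1:
            run.append(int(d))
        else:
            episodes.append(_close_run(run, los_min, disposition, config))
            run = [int(d)]
    episodes.append(_close_run(run, los_min, disposition, config))
    return episodes


def _close_run(run: list[int], los_min: int | None, disposition: str,
               config: PhenotypeConfig) -> QadEpisode:
    exempt = False
    if (config.death_exemption and disposition == "death"
            and los_min is not None):
        death_day = int(los_min) // MINUTES_PER_DAY
        exempt = run[-1] >= death_day - 1
    return QadEpisode(start_day=run[0], n_days=len(run), death_exempt=exempt)


# ---------------------------------------------------------------------------
# eSOFA organ dysfunction
# ---------------------------------------------------------------------------

def detect_esofa_events(
    observations: pd.DataFrame,
    orders: pd.DataFrame,
    config: PhenotypeConfig | None = None,
) -> list[tuple[str, int]]:
    """First occurrence time of each eSOFA organ-dysfunction criterion.

    Criteria whose elements were never recorded are simply absent (the
    missing-data rule: an incomputable criterion reads as non-septic).
    Returned sorted by time then criterion name.
    """
    config = config or PhenotypeConfig()
    events: list[tuple[str, int]] = []

    for kind, name in (("vasopressor", "vasopressor_initiation"),
                       ("mech_vent", "mechanical_ventilation")):
        sel = orders.loc[orders["kind"] == kind, "time_min"]
        if len(sel):
            events.append((name, int(sel.min())))

    def series(element: str) -> tuple[np.ndarray, np.ndarray]:
        sub = observations[observations["element"] == element]
        sub = sub.sort_values("time_min", kind="stable")
        return sub["time_min"].to_numpy(), sub["value"].to_numpy()

    t, v = series("lactate")
    hit = np.flatnonzero(v >= config.lactate_threshold)
    if hit.size:
        events.append(("lactate", int(t[hit[0]])))

    t, v = series("creatinine")
    if v.size and v[0] > 0:
        hit = np.flatnonzero(v >= config.creatinine_ratio * v[0])
        if hit.size:
            events.append(("creatinine_doubling", int(t[hit[0]])))

    t, v = series("bilirubin")
    if v.size and v[0] > 0:
        hit = np.flatnonzero((v >= config.bilirubin_threshold)
                             & (v >= config.bilirubin_ratio * v[0]))
        if hit.size:
            events.append(("bilirubin", int(t[hit[0]])))

    t, v = series("platelets")
    if v.size and v[0] >= config.platelet_baseline_min:
        hit = np.flatnonzero((v < config.platelet_threshold)
                             & (v <= (1.0 - config.platelet_decline) * v[0]))
        if hit.size:
            events.append(("platelet_fall", int(t[hit[0]])))

    return sorted(events, key=lambda e: (e[1], e[0]))


# ---------------------------------------------------------------------------
# sepsis label
# ---------------------------------------------------------------------------

@dataclass
class SepsisLabel:
    admission_id: str
    category: str
    blood_culture_min: int | None = None
    first_qad_day: int | None = None
    esofa_events: list[tuple[str, int]] = field(default_factory=list)
    septic_shock: bool = False

    @property
    def is_sepsis(self) -> bool:
        return self.category != NONSEPSIS

    @property
    def first_esofa_min(self) -> int | None:
        return self.esofa_events[0][1] if self.esofa_events else None


def _norm_code(code: str) -> str:
    return str(code).replace(".", "").upper()


def _has_code_prefix(dx: pd.DataFrame, prefixes) -> bool:
    codes = dx["code"].map(_norm_code)
    return bool(codes.str.startswith(tuple(prefixes)).any())


def detect_ase_sepsis(
    admission: pd.Series,
    observations: pd.DataFrame,
    orders: pd.DataFrame,
    dx_codes: pd.DataFrame,
    config: PhenotypeConfig | None = None,
    *,
    qualifying: frozenset[str] | None = None,
) -> SepsisLabel:
    """Classify one admission as ASE sepsis, COVID-19 sepsis, or nonsepsis."""
    config = config or PhenotypeConfig()
    los_min = int(admission["discharge_min"]) - int(admission["admit_min"])
    episodes = qualifying_antimicrobial_days(
        orders, qualifying=qualifying, los_min=los_min,
        disposition=str(admission.get("disposition", "")), config=config)
    culture_times = sorted(
        int(t) for t in orders.loc[orders["kind"] == "blood_culture", "time_min"])

    esofa_all = detect_esofa_events(observations, orders, config)

    ase_culture: int | None = None
    ase_qad_day: int | None = None
    ase_esofa: list[tuple[str, int]] = []
    for culture in culture_times:
        cday = culture // MINUTES_PER_DAY
        episode = next(
            (ep for ep in episodes
             if ep.qualifies(config.qad_min_days)
             and abs(ep.start_day - cday) <= config.culture_window_days),
            None)
        if episode is None:
            continue
        if config.esofa_window == "culture":
            lo = (cday - config.culture_window_days) * MINUTES_PER_DAY
            hi = (cday + config.culture_window_days + 1) * MINUTES_PER_DAY
            esofa = [e for e in esofa_all if lo <= e[1] < hi]
        else:
            esofa = esofa_all
        if esofa:
            ase_culture, ase_qad_day, ase_esofa = culture, episode.start_day, esofa
            break

    covid_met = _has_code_prefix(dx_codes, (COVID_CODE_PREFIX,)) and bool(esofa_all)

    if covid_met and (config.covid_precedence or ase_culture is None):
        label = SepsisLabel(str(admission["admission_id"]), COVID_SEPSIS,
                            blood_culture_min=ase_culture,
                            first_qad_day=ase_qad_day,
                            esofa_events=esofa_all)
    elif ase_culture is not None:
        label = SepsisLabel(str(admission["admission_id"]), ASE_SEPSIS,
                            blood_culture_min=ase_culture,
                            first_qad_day=ase_qad_day,
                            esofa_events=ase_esofa)
    else:
        label = SepsisLabel(str(admission["admission_id"]), NONSEPSIS,
                            esofa_events=esofa_all)
    label.septic_shock = detect_septic_shock(orders, dx_codes, label)
    return label


def detect_septic_shock(orders: pd.DataFrame, dx_codes: pd.DataFrame,
                        label: SepsisLabel) -> bool:
    """Shock = sepsis admission with a shock code or any vasopressor order."""
    if not label.is_sepsis:
        return False
    if _has_code_prefix(dx_codes, SHOCK_CODE_PREFIXES):
        return True
    return bool((orders["kind"] == "vasopressor").any())


# ---------------------------------------------------------------------------
# Charlson Comorbidity Index
# ---------------------------------------------------------------------------

_CCI_HIERARCHY = {
    "diabetes_uncomplicated": "diabetes_complicated",
    "malignancy": "metastatic_solid_tumor",
    "mild_liver_disease": "moderate_severe_liver_disease",
}

CCI_CATEGORIES = ("0-1", "2-5", ">=6")


def charlson_index(
    dx_codes: pd.DataFrame,
    los_min: int,
    config: PhenotypeConfig | None = None,
    weights: pd.DataFrame | None = None,
) -> tuple[int, str]:
    """Charlson score over a 2-year lookback through the end of the admission.

    Components are matched by ICD-10 prefix; a milder component is dropped
    when its severe counterpart is present (complicated diabetes, metastatic
    tumor, severe liver disease). Unmapped codes are ignored.
    """
    config = config or PhenotypeConfig()
    if weights is None:
        weights = load_cci_weights()
    lo = -config.cci_lookback_days * MINUTES_PER_DAY
    window = dx_codes[(dx_codes["time_min"] >= lo)
                      & (dx_codes["time_min"] <= los_min)]
    codes = [_norm_code(c) for c in window["code"]]

    prefixes = weights["code_prefix"].tolist()
    comp_of = dict(zip(weights["code_prefix"], weights["component"]))
    weight_of = dict(zip(weights["component"], weights["weight"]))
    # longest-prefix match so e.g. I252 wins over I25-family components
    prefixes.sort(key=len, reverse=True)

    components: set[str] = set()
    for code in codes:
        for p in prefixes:
            if code.startswith(p):
                components.add(comp_of[p])
                break
    for mild, severe in _CCI_HIERARCHY.items():
        if severe in components:
            components.discard(mild)
    score = int(sum(weight_of[c] for c in components))
    if score <= 1:
        category = "0-1"
    elif score <= 5:
        category = "2-5"
    else:
        category = ">=6"
    return score, category


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    n_input: int
    counts: dict[str, int]
    retained_ids: list[str]
    excluded: pd.DataFrame  # admission_id, rule

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_excluded": self.counts[r]} for r in EXCLUSION_RULES]
        rows.append({"rule": "retained", "n_excluded": self.n_retained})
        return pd.DataFrame(rows)


def apply_exclusions(
    cohort: Cohort,
    config: PhenotypeConfig | None = None,
    labels: pd.DataFrame | None = None,
) -> tuple[Cohort, ExclusionReport]:
    """Apply the six exclusion rules with first-matching-rule attribution.

    Rules, in order: burn-service admission; length of stay > 30 days
    (strict); left against medical advice; transfer in from an outside
    facility or between internal sites; readmission within 30 days of a
    sepsis-related index admission of the same patient; neither blood
    pressure nor temperature ever recorded.

    ``labels`` (admission_id, category) feeds the readmission rule when
    ``config.readmission_rule == 'label'``; if omitted, provisional labels
    are computed on the full cohort first.
    """
    config = config or PhenotypeConfig()
    adm = cohort.admissions

    if config.readmission_rule == "label" and labels is None:
        labels = phenotype_cohort(cohort, config)

    los_days = (adm["discharge_min"] - adm["admit_min"]) / MINUTES_PER_DAY

    obs_bp_temp = cohort.observations[
        cohort.observations["element"].isin(_BP_ELEMENTS + ("temperature",))]
    has_vitals = set(obs_bp_temp["admission_id"])

    sepsis_index: set[str] = set()
    if config.readmission_rule == "label" and labels is not None:
        lab = labels.set_index("admission_id")["category"]
        sepsis_index = set(lab.index[lab != NONSEPSIS])
    else:
        for aid, grp in cohort.dx_codes.groupby("admission_id"):
            if _has_code_prefix(grp, SEPSIS_RELATED_CODE_PREFIXES):
                sepsis_index.add(str(aid))

    readmit_excluded: set[str] = set()
    window_min = config.readmission_window_days * MINUTES_PER_DAY
    for _, grp in adm.sort_values("admit_min").groupby("patient_id"):
        rows = grp[["admission_id", "admit_min", "discharge_min"]].to_numpy()
        for i in range(1, len(rows)):
            for j in range(i):
                gap = rows[i][1] - rows[j][2]
                if 0 <= gap <= window_min and rows[j][0] in sepsis_index:
                    readmit_excluded.add(str(rows[i][0]))
                    break

    counts = {rule: 0 for rule in EXCLUSION_RULES}
    excl_rows: list[dict[str, str]] = []
    retained: list[str] = []
    for idx, row in adm.iterrows():
        aid = str(row["admission_id"])
        rule = None
        if str(row.get("service", "")) == "burn":
            rule = "burn_service"
        elif los_days.loc[idx] > config.los_max_days:
            rule = "los_gt_30d"
        elif str(row.get("disposition", "")) == "ama":
            rule = "ama"
        elif str(row.get("source", "")) in ("external_transfer", "internal_transfer"):
            rule = "transfer"
        elif aid in readmit_excluded:
            rule = "sepsis_readmission_30d"
        elif aid not in has_vitals:
            rule = "no_bp_temp"
        if rule is None:
            retained.append(aid)
        else:
            counts[rule] += 1
            excl_rows.append({"admission_id": aid, "rule": rule})
            logger.info("excluded %s: %s", aid, rule)

    report = ExclusionReport(
        n_input=len(adm), counts=counts, retained_ids=retained,
        excluded=pd.DataFrame(excl_rows, columns=["admission_id", "rule"]))
    return cohort.subset(retained), report


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def phenotype_cohort(cohort: Cohort,
                     config: PhenotypeConfig | None = None) -> pd.DataFrame:
    """Label every admission; returns the ``labels.csv`` table."""
    config = config or PhenotypeConfig()
    qualifying = qualifying_antimicrobial_list()
    obs_g = dict(tuple(cohort.observations.groupby("admission_id")))
    ord_g = dict(tuple(cohort.orders.groupby("admission_id")))
    dx_g = dict(tuple(cohort.dx_codes.groupby("admission_id")))
    from .cohort import empty_table
    rows = []
    for _, admission in cohort.admissions.iterrows():
        aid = str(admission["admission_id"])
        obs = obs_g.get(aid, empty_table("observations")).sort_values(
            "time_min", kind="stable")
        orders = ord_g.get(aid, empty_table("orders")).sort_values(
            "time_min", kind="stable")
        dx = dx_g.get(aid, empty_table("dx_codes"))
        label = detect_ase_sepsis(admission, obs, orders, dx, config,
                                  qualifying=qualifying)
        rows.append({
            "admission_id": aid,
            "category": label.category,
            "shock": bool(label.septic_shock),
            "blood_culture_min": label.blood_culture_min,
            "first_qad_day": label.first_qad_day,
            "first_esofa_min": label.first_esofa_min,
        })
    return pd.DataFrame(rows, columns=[
        "admission_id", "category", "shock", "blood_culture_min",
        "first_qad_day", "first_esofa_min"])
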