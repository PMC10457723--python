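"""Seeded synthetic inpatient cohorts.

The generator emulates the statistical structure the downstream analysis
assumes -- not bedside physiology. Each admission gets element-specific
observation streams (vitals denser than labs, exponential inter-arrival
gaps), antimicrobial / blood-culture / vasopressor / ventilation orders,
ICD-10 codes, and a ground-truth label:

* nonsepsis admissions are sampled inside clamps that keep every eSOFA
  organ-dysfunction criterion silent (lactate < 2.0, no lab doubling, no
  vasopressors or ventilation), so the phenotype cannot fire on noise;
* septic admissions receive an injected episode: physiology ramps toward a
  deteriorated signature from the onset time, a blood culture and a
  consecutive run of qualifying antimicrobial days follow after an
  order-latency delay, and at least one eSOFA event (a lactate >= 2.1) is
  guaranteed. A COVID-19 variant carries ICD-10 U07.1 and organ dysfunction
  and may lack culture/antimicrobials; a small death-exempt subset dies
  with < 4 antimicrobial days, therapy running through the day of death.

Injection is airtight by construction: phenotyping recovers the truth label
for every admission. The surrogate score's generative separation is part of
the design: a configured fraction of septic admissions get the strong
(detectable) signature, and a configured fraction of nonsepsis admissions
get a transient vitals flare that crosses the surrogate threshold without
organ dysfunction.

A single RNG stream seeded once drives the whole cohort, so a fixed seed
reproduces byte-identical tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import MINUTES_PER_DAY, CohortConfig
from .errors import DomainError

ASE_SEPSIS = "ASE_SEPSIS"
COVID_SEPSIS = "COVID_SEPSIS"
NONSEPSIS = "NONSEPSIS"

#: ramp from baseline to the full post-onset signature, minutes
ONSET_RAMP_MIN = 360.0

#: rounding (decimal places) used when emitting observation values
_DECIMALS = {
    "temperature": 1, "heart_rate": 0, "resp_rate": 0, "sbp": 0, "map": 0,
    "gcs": 0, "wbc": 2, "bands": 1, "platelets": 0, "creatinine": 2,
    "bilirubin": 2, "lactate": 2, "pf_ratio": 0, "paco2": 1,
}

_ABX = ("vancomycin", "piperacillin-tazobactam", "cefepime", "ceftriaxone",
        "meropenem", "levofloxacin")
_SHORT_ABX = ("ceftriaxone", "azithromycin", "cefazolin")
_VASO = ("norepinephrine", "vasopressin")

#: historical comorbidity codes drawn for the Charlson index
_COMORBIDITY_POOL = ("E119", "E112", "J449", "I509", "N183", "C349", "C787",
                     "B20", "I219", "K704", "F03", "M05", "I70", "K259")

_RACE = (("white", 0.66), ("black", 0.22), ("hispanic", 0.06), ("other", 0.055),
         ("unknown", 0.025))


@dataclass
class GeneratedAdmission:
    """One admission's tables-in-progress plus its ground truth."""
    admission: dict
    observations: list = field(default_factory=list)  # (time, element, value)
    orders: list = field(default_factory=list)        # (time, kind, detail)
    dx_codes: list = field(default_factory=list)      # (code, time)
    truth_label: str = NONSEPSIS
    truth_onset_min: float = math.nan
    baselines: dict = field(default_factory=dict)     # not exported

    @property
    def los_min(self) -> int:
        return int(self.admission["discharge_min"] - self.admission["admit_min"])

    def extend_stay(self, new_los_min: int) -> None:
        if new_los_min > self.los_min:
            self.admission["discharge_min"] = (
                self.admission["admit_min"] + int(new_los_min))


def _choice(rng: np.random.Generator, pairs) -> str:
    names = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return str(rng.choice(names, p=probs / probs.sum()))


def _sample_times(rng: np.random.Generator, lo: float, hi: float,
                  mean_gap: float, lead: bool = True) -> list[int]:
    """Exponential inter-arrival event times in [lo, hi)."""
    times: list[int] = []
    t = lo if lead else lo + rng.exponential(mean_gap)
    while t < hi:
        times.append(int(t))
        t += max(1.0, rng.exponential(mean_gap))
    return times


def _draw_baselines(rng: np.random.Generator) -> dict[str, float]:
    return {
        "temperature": rng.normal(37.0, 0.25),
        "heart_rate": rng.normal(78, 8),
        "resp_rate": rng.normal(16, 2),
        "sbp": rng.normal(122, 12),
        "map": rng.normal(88, 8),
        "gcs": 15.0,
        "wbc": max(4.5, rng.normal(8.0, 1.5)),
        "bands": min(9.0, max(0.0, rng.normal(3.0, 2.0))),
        "platelets": max(130.0, rng.normal(230, 40)),
        "creatinine": float(np.clip(rng.normal(0.85, 0.15), 0.5, 1.3)),
        "bilirubin": float(np.clip(rng.normal(0.6, 0.2), 0.1, 0.95)),
        "lactate": float(np.clip(rng.normal(1.1, 0.25), 0.4, 1.6)),
        "pf_ratio": float(np.clip(rng.normal(410, 50), 260, 520)),
        "paco2": rng.normal(40, 4),
    }


def _nonsepsis_value(rng: np.random.Generator, element: str,
                     base: dict[str, float]) -> float:
    """Baseline noise, clamped so no eSOFA criterion can fire."""
    b = base[element]
    if element == "temperature":
        return b + rng.normal(0, 0.3)
    if element == "heart_rate":
        return max(40.0, b + rng.normal(0, 7))
    if element == "resp_rate":
        return max(8.0, b + rng.normal(0, 2))
    if element == "sbp":
        return max(85.0, b + rng.normal(0, 9))
    if element == "map":
        return max(72.0, b + rng.normal(0, 6))
    if element == "gcs":
        return 15.0
    if element == "wbc":
        return max(4.2, b + rng.normal(0, 1.2))
    if element == "bands":
        return float(np.clip(b + rng.normal(0, 1.5), 0.0, 15.0))
    if element == "platelets":
        # never < 100 nor a 50% fall from any plausible first value
        return float(max(0.62 * b, b + rng.normal(0, 12)))
    if element == "creatinine":
        return float(min(1.8 * b, b * math.exp(rng.normal(0, 0.08))))
    if element == "bilirubin":
        return float(min(1.9, b * math.exp(rng.normal(0, 0.15))))
    if element == "lactate":
        return float(np.clip(b + rng.normal(0, 0.2), 0.3, 1.9))
    if element == "pf_ratio":
        return float(np.clip(b + rng.normal(0, 30), 240, 560))
    if element == "paco2":
        return float(np.clip(b + rng.normal(0, 3), 33.5, 55))
    raise KeyError(element)


_VITAL_ELEMENTS = ("temperature", "heart_rate", "resp_rate", "sbp", "map", "gcs")
_CORE_LABS = ("wbc", "creatinine", "platelets")
_OPTIONAL_LABS = (("bilirubin", 0.5), ("lactate", 0.4), ("bands", 0.3),
                  ("pf_ratio", 0.15), ("paco2", 0.15))


def _base_admission(i: int, patient_id: str, admit_min: int, los_min: int,
                    rng: np.random.Generator, config: CohortConfig
                    ) -> GeneratedAdmission:
    adm = {
        "admission_id": f"A{i:06d}",
        "patient_id": patient_id,
        "admit_min": int(admit_min),
        "discharge_min": int(admit_min + los_min),
        "age": int(np.clip(round(rng.normal(62, 18)), 18, 97)),
        "sex": _choice(rng, (("female", 0.53), ("male", 0.47))),
        "race_ethnicity": _choice(rng, _RACE),
        "site": _choice(rng, (("tertiary", 0.54), ("community", 0.46))),
        "service": "medicine",
        "source": _choice(rng, (("ED", 0.62), ("direct", 0.38))),
        "disposition": "home",
    }
    ga = GeneratedAdmission(admission=adm, baselines=_draw_baselines(rng))

    measured = list(_VITAL_ELEMENTS) + list(_CORE_LABS)
    for lab, p in _OPTIONAL_LABS:
        if rng.random() < p:
            measured.append(lab)
    ga.baselines["_measured"] = tuple(measured)

    for element in measured:
        gap = (config.cadence_vitals_min if element in _VITAL_ELEMENTS
               else config.cadence_labs_min)
        for t in _sample_times(rng, 15.0 if element in _VITAL_ELEMENTS else 45.0,
                               los_min, gap):
            ga.observations.append(
                (t, element, _nonsepsis_value(rng, element, ga.baselines)))

    # historical comorbidity codes (negative times = before admission)
    for _ in range(int(rng.poisson(1.2))):
        code = str(rng.choice(_COMORBIDITY_POOL))
        t = -int(rng.integers(1, int(1.9 * 365))) * MINUTES_PER_DAY
        ga.dx_codes.append((code, t))
    return ga


def _add_flare(ga: GeneratedAdmission, rng: np.random.Generator) -> None:
    """Transient strong-vitals flare: crosses the surrogate threshold (and
    SIRS) with no organ dysfunction. Models e.g. a self-limited febrile
    reaction."""
    los = ga.los_min
    start = rng.uniform(0.05, 0.7) * los
    for t in _sample_times(rng, start, min(start + 360.0, los), 55.0):
        ga.observations.append(
            (t, "temperature", ga.baselines["temperature"] + 2.6 + rng.normal(0, 0.25)))
        ga.observations.append(
            (t, "heart_rate", ga.baselines["heart_rate"] + 50 + rng.normal(0, 6)))
        ga.observations.append(
            (t, "resp_rate", ga.baselines["resp_rate"] + 11 + rng.normal(0, 1.5)))


def _short_antimicrobials(ga: GeneratedAdmission, rng: np.random.Generator
                          ) -> None:
    """Blood culture plus a 1-3 day antimicrobial run (never qualifies)."""
    los = ga.los_min
    t0 = rng.uniform(30.0, max(31.0, 0.5 * los))
    ga.orders.append((int(t0), "blood_culture", ""))
    d0 = int(t0) // MINUTES_PER_DAY
    drug = str(rng.choice(_SHORT_ABX))
    for d in range(d0, min(d0 + int(rng.integers(1, 4)),
                           los // MINUTES_PER_DAY + 1)):
        t = d * MINUTES_PER_DAY + int(rng.uniform(480, 1200))
        if 0 <= t < los:
            ga.orders.append((t, "antimicrobial", drug))


def _post_onset_value(rng: np.random.Generator, element: str, base: dict,
                      shift: dict[str, float], ramp: float) -> float:
    b = base[element] + ramp * shift.get(element, 0.0)
    noise = {
        "temperature": 0.25, "heart_rate": 6, "resp_rate": 1.5, "sbp": 7,
        "map": 5, "gcs": 0.0, "wbc": 1.2, "bands": 2.0, "platelets": 10,
        "creatinine": 0.08, "bilirubin": 0.1, "lactate": 0.25,
        "pf_ratio": 25, "paco2": 3,
    }[element]
    v = b + rng.normal(0, noise) if noise else b
    if element == "gcs":
        v = float(np.clip(round(v), 3, 15))
    return float(v)


def inject_sepsis_episode(
    ga: GeneratedAdmission,
    onset_min: float,
    variant: str = "ASE",
    *,
    rng: np.random.Generator,
    config: CohortConfig,
    detectable: bool = True,
    death_exempt: bool = False,
) -> GeneratedAdmission:
    """Turn a nonseptic admission into a phenotype-positive one.

    From ``onset_min`` the admission's physiology ramps (over ~6 h) toward
    the strong or muted post-onset signature; a guaranteed lactate >= 2.1
    anchors organ dysfunction. For the ASE variant a blood culture and a
    consecutive qualifying-antimicrobial-day run follow the onset after an
    order-latency delay (the stay is extended if the run needs it). The
    COVID variant adds ICD-10 U07.1 and organ dysfunction; culture and
    antimicrobials are optional and never reach 4 days. ``death_exempt``
    produces an admission that dies with 2-3 antimicrobial days running
    through the day of death.
    """
    if variant not in ("ASE", "COVID"):
        raise DomainError(f"unknown sepsis variant: {variant}")
    if not 0 <= onset_min < ga.los_min:
        raise DomainError(
            f"onset {onset_min} outside stay [0, {ga.los_min})")
    onset = float(onset_min)
    shift = (config.trajectory.strong if detectable
             else config.trajectory.muted)

    latency = rng.lognormal(math.log(config.order_latency_median_min),
                            config.order_latency_sigma_log)
    first_action = onset + float(np.clip(latency, 20.0, 2 * MINUTES_PER_DAY))

    has_orders = True
    if variant == "COVID":
        ga.dx_codes.append(("U07.1", 0))
        has_orders = rng.random() < 0.5

    abx_days: list[int] = []
    if has_orders:
        ga.orders.append((int(first_action), "blood_culture", ""))
        first_abx = first_action + rng.uniform(10, 40)
        d0 = int(first_abx) // MINUTES_PER_DAY
        if variant == "COVID":
            n_days = int(rng.integers(1, 4))          # never qualifies alone
        elif death_exempt:
            n_days = int(rng.integers(2, 4))
        else:
            n_days = 4 + int(rng.poisson(1.5))
        drug = str(rng.choice(_ABX))
        for k in range(n_days):
            day = d0 + k
            t = (day * MINUTES_PER_DAY + int(rng.uniform(480, 1200))
                 if k else int(first_abx))
            ga.orders.append((t, "antimicrobial", drug))
            abx_days.append(day)

    if death_exempt and abx_days:
        death_day = abx_days[-1]
        ga.admission["disposition"] = "death"
        end = death_day * MINUTES_PER_DAY + int(rng.uniform(1210, 1430))
        ga.admission["discharge_min"] = ga.admission["admit_min"] + end
        ga.observations = [o for o in ga.observations if o[0] < end]
        ga.orders = [o for o in ga.orders if o[0] < end]
    elif abx_days:
        ga.extend_stay((abx_days[-1] + 1) * MINUTES_PER_DAY
                       + int(rng.uniform(600, 4000)))

    los = ga.los_min

    # guaranteed organ-dysfunction anchor
    t_lact = int(min(onset + 60 + rng.uniform(0, 120), los - 1))
    ga.observations.append(
        (t_lact, "lactate",
         max(2.1, ga.baselines["lactate"] + shift.get("lactate", 0.0))))

    # deteriorated physiology from onset to discharge; sorted iteration so
    # RNG consumption (hence the cohort) is independent of hash seeds
    measured = sorted(set(ga.baselines["_measured"])
                      | {"lactate", "creatinine", "platelets", "wbc"})
    for element in measured:
        if element not in _DECIMALS:
            continue
        gap = (60.0 if element in _VITAL_ELEMENTS
               else config.cadence_labs_min * 0.75)
        for t in _sample_times(rng, onset + rng.uniform(5, 45), los, gap,
                               lead=True):
            ramp = min(1.0, (t - onset) / ONSET_RAMP_MIN)
            ga.observations.append(
                (int(t), element,
                 _post_onset_value(rng, element, ga.baselines, shift, ramp)))

    # a subset develops shock: vasopressors (also an eSOFA criterion)
    if detectable and rng.random() < 0.35:
        t = int(min(onset + rng.uniform(180, 720), los - 1))
        ga.orders.append((t, "vasopressor", str(rng.choice(_VASO))))
        if rng.random() < 0.5:
            ga.dx_codes.append(("R65.21", int(min(t + 60, los - 1))))
    if variant == "COVID" and rng.random() < 0.4:
        t = int(min(onset + rng.uniform(240, 1440), los - 1))
        ga.orders.append((t, "mech_vent", ""))

    ga.truth_label = COVID_SEPSIS if variant == "COVID" else ASE_SEPSIS
    ga.truth_onset_min = onset
    return ga


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _finalize(gen: list[GeneratedAdmission]) -> Cohort:
    adm = pd.DataFrame([g.admission for g in gen])
    obs_rows, order_rows, dx_rows, truth_rows = [], [], [], []
    for g in gen:
        aid = g.admission["admission_id"]
        los = g.los_min
        for t, element, v in g.observations:
            if 0 <= t <= los:
                obs_rows.append((aid, int(t), element,
                                 round(float(v), _DECIMALS[element])))
        for t, kind, detail in g.orders:
            if 0 <= t <= los:
                order_rows.append((aid, int(t), kind, detail))
        for code, t in g.dx_codes:
            dx_rows.append((aid, code, int(t)))
        truth_rows.append((aid, g.truth_label, g.truth_onset_min))
    obs = pd.DataFrame(obs_rows, columns=["admission_id", "time_min",
                                          "element", "value"])
    orders = pd.DataFrame(order_rows, columns=["admission_id", "time_min",
                                               "kind", "detail"])
    dx = pd.DataFrame(dx_rows, columns=["admission_id", "code", "time_min"])
    truth = pd.DataFrame(truth_rows, columns=["admission_id", "label",
                                              "onset_min"])
    obs = obs.sort_values(["admission_id", "time_min", "element", "value"],
                          kind="stable").reset_index(drop=True)
    orders = orders.sort_values(["admission_id", "time_min", "kind", "detail"],
                                kind="stable").reset_index(drop=True)
    dx = dx.sort_values(["admission_id", "time_min", "code"],
                        kind="stable").reset_index(drop=True)
    return Cohort(admissions=adm, observations=obs, orders=orders,
                  dx_codes=dx, truth=truth)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a seeded synthetic cohort with ground-truth labels.

    Deterministic for a fixed seed. The realized number of septic
    admissions is binomial around ``sepsis_prevalence``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gen: list[GeneratedAdmission] = []
    history: list[tuple[str, int]] = []  # (patient_id, discharge_min)

    for i in range(config.n_admissions):
        is_sepsis = rng.random() < config.sepsis_prevalence
        is_covid = is_sepsis and rng.random() < config.covid_fraction_of_sepsis
        death_exempt = (is_sepsis and not is_covid
                        and rng.random() < config.death_exempt_fraction_of_sepsis)

        median = (config.los_median_days_sepsis if is_sepsis
                  else config.los_median_days_nonsepsis)
        los_days = rng.lognormal(math.log(median), config.los_sigma_log)
        if is_sepsis and not death_exempt:
            los_days = max(los_days, 6.5)
        los_min = max(720, int(los_days * MINUTES_PER_DAY))

        if history and rng.random() < 0.04:
            pid, prev_discharge = history[int(rng.integers(len(history)))]
            admit = prev_discharge + int(rng.integers(2, 50)) * MINUTES_PER_DAY
        else:
            pid = f"P{i:06d}"
            admit = int(rng.integers(0, 550)) * MINUTES_PER_DAY

        ga = _base_admission(i, pid, admit, los_min, rng, config)

        if rng.random() < config.burn_service_fraction:
            ga.admission["service"] = "burn"
        if rng.random() < config.transfer_fraction:
            ga.admission["source"] = str(rng.choice(
                ["external_transfer", "internal_transfer"]))
        if not is_sepsis and rng.random() < 0.01:
            ga.admission["disposition"] = "ama"
        if rng.random() < config.missing_bp_temp_fraction:
            ga.observations = [o for o in ga.observations
                               if o[1] not in ("sbp", "map", "temperature")]

        if is_sepsis:
            onset = rng.uniform(0.04 * los_min,
                                max(0.05 * los_min,
                                    los_min - 6 * MINUTES_PER_DAY))
            detectable = rng.random() < config.pss_detectable_fraction
            inject_sepsis_episode(
                ga, onset, "COVID" if is_covid else "ASE", rng=rng,
                config=config, detectable=detectable,
                death_exempt=death_exempt)
        else:
            if rng.random() < config.pss_false_positive_fraction:
                _add_flare(ga, rng)
            if rng.random() < config.nonsepsis_culture_fraction:
                _short_antimicrobials(ga, rng)
            if rng.random() < config.covid_code_nonsepsis_fraction:
                ga.dx_codes.append(("U07.1", 0))

        history.append((pid, int(ga.admission["discharge_min"])))
        gen.append(ga)

    return _finalize(gen)
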