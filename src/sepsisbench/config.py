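"""Configuration dataclasses and YAML round-trip.

Time convention used throughout the package: integer minutes from admission
start, with the admission assumed to begin at midnight of calendar day 0, so
that the calendar day of an event is ``time_min // 1440``. The ASE +/-2-day
antimicrobial window and qualifying-antimicrobial-day runs are calendar-day
based, which is why days, not rolling 24 h periods, are the unit.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError

MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# synthetic cohort generation
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    """Post-onset shifts applied to a septic admission's physiology.

    ``strong`` is the deteriorated signature used for admissions the
    surrogate score is meant to detect; ``muted`` is a biochemically septic
    but vitals-quiet signature (organ dysfunction on labs with near-normal
    vitals), used for the remainder.
    """

    strong: dict[str, float] = field(default_factory=lambda: {
        "temperature": 2.2,   # degC shift -> ~39.0
        "heart_rate": 45.0,   # bpm shift -> ~125
        "resp_rate": 12.0,    # /min shift -> ~28
        "sbp": -38.0,         # mmHg shift -> ~82
        "map": -25.0,         # mmHg shift -> ~62
        "gcs": -3.0,          # -> 12
        "wbc": 10.0,          # -> ~18
        "lactate": 3.2,       # -> ~4.3
        "creatinine": 1.4,    # -> ~2.2 (>=2x baseline)
        "platelets": -160.0,  # -> ~90 (eSOFA platelet fall)
    })
    muted: dict[str, float] = field(default_factory=lambda: {
        "temperature": 0.5,
        "heart_rate": 10.0,
        "resp_rate": 3.0,
        "sbp": -8.0,
        "map": -5.0,
        "gcs": 0.0,
        "wbc": 3.0,
        "lactate": 1.3,       # -> ~2.4, still an eSOFA lactate event
        "creatinine": 1.1,    # -> ~1.9-2.0, ~2x baseline
        "platelets": -100.0,  # -> ~130: SOFA coagulation point, no eSOFA fall
    })


@dataclass
class CohortConfig:
    """Parameters of the synthetic inpatient cohort generator.

    Defaults mirror a large low-prevalence inpatient population: sepsis
    prevalence 2.7% with 20.4% of sepsis carrying a COVID-19 diagnosis,
    nonsepsis length of stay centred near 3.2 days and septic stays near
    9.2 days (log-normal).
    """

    n_admissions: int = 1000
    sepsis_prevalence: float = 0.027
    covid_fraction_of_sepsis: float = 0.204

    # log-normal LOS, parameterised by median days and sigma of log
    los_median_days_nonsepsis: float = 3.2
    los_median_days_sepsis: float = 9.2
    los_sigma_log: float = 0.65

    # mean inter-observation gap per element class, minutes (exponential)
    cadence_vitals_min: float = 240.0
    cadence_labs_min: float = 720.0

    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)

    # delay from physiologic onset to first clinician action (log-normal)
    order_latency_median_min: float = 120.0
    order_latency_sigma_log: float = 0.8

    # generative separation of the surrogate score at its default threshold:
    # fraction of septic admissions given the strong (detectable) signature,
    # and fraction of nonsepsis admissions given a transient vitals flare
    # that crosses the surrogate threshold without organ dysfunction.
    pss_detectable_fraction: float = 0.85
    pss_false_positive_fraction: float = 0.27

    # cohort composition quirks exercised by the exclusion cascade
    burn_service_fraction: float = 0.004
    ama_fraction: float = 0.01
    transfer_fraction: float = 0.012
    missing_bp_temp_fraction: float = 0.005
    covid_code_nonsepsis_fraction: float = 0.02
    death_exempt_fraction_of_sepsis: float = 0.05
    nonsepsis_culture_fraction: float = 0.10

    seed: int = 0

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ConfigurationError("n_admissions must be >= 1")
        for name in ("sepsis_prevalence", "covid_fraction_of_sepsis",
                     "pss_detectable_fraction", "pss_false_positive_fraction",
                     "burn_service_fraction", "ama_fraction",
                     "transfer_fraction", "missing_bp_temp_fraction",
                     "covid_code_nonsepsis_fraction",
                     "death_exempt_fraction_of_sepsis",
                     "nonsepsis_culture_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("los_median_days_nonsepsis", "los_median_days_sepsis",
                     "cadence_vitals_min", "cadence_labs_min",
                     "order_latency_median_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# phenotyping
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeConfig:
    """Rules of the Adult Sepsis Event phenotype and the exclusion cascade."""

    qad_min_days: int = 4
    qad_gap_days: int = 0            # allowed gap inside one episode
    death_exemption: bool = True     # <4 QADs qualify if therapy ran to death
    culture_window_days: int = 2     # QAD episode start within +/- this many
                                     # calendar days of blood culture
    esofa_window: str = "admission"  # or "culture" (+/- window around culture)
    covid_precedence: bool = True    # U07.1x + eSOFA labels COVID over ASE

    lactate_threshold: float = 2.0
    bilirubin_threshold: float = 2.0
    creatinine_ratio: float = 2.0
    bilirubin_ratio: float = 2.0
    platelet_threshold: float = 100.0
    platelet_decline: float = 0.5
    platelet_baseline_min: float = 100.0

    los_max_days: float = 30.0       # strict: LOS > 30 d excluded
    readmission_window_days: float = 30.0
    readmission_rule: str = "label"  # or "icd"

    cci_lookback_days: float = 730.0

    def validate(self) -> None:
        if self.qad_min_days < 1:
            raise ConfigurationError("qad_min_days must be >= 1")
        if self.esofa_window not in ("admission", "culture"):
            raise ConfigurationError(
                f"esofa_window must be 'admission' or 'culture', got {self.esofa_window!r}")
        if self.readmission_rule not in ("label", "icd"):
            raise ConfigurationError(
                f"readmission_rule must be 'label' or 'icd', got {self.readmission_rule!r}")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class PssSurrogateParams:
    """Transparent stand-in for a proprietary 15-minute sepsis risk score.

    score(t) = scale * logistic(intercept + sum_i w_i * f_i(snapshot)) +
    bump * exp(-(t - t_order)/decay) after an antimicrobial order. The
    feature functions f_i are hinge-shaped abnormality measures (see
    ``scoring.PSS_FEATURES``). With the default scale the score lives on a
    0-15 range so alert thresholds of 5-10 are meaningful.
    """

    weights: dict[str, float] = field(default_factory=lambda: {
        "temp_dev": 1.0,
        "hr_excess": 1.0,
        "rr_excess": 1.0,
        "sbp_deficit": 1.0,
        "gcs_deficit": 1.0,
        "wbc_dev": 1.0,
        "lactate_excess": 1.0,
        "creatinine_excess": 1.0,
    })
    intercept: float = -3.0
    scale: float = 12.0
    order_bump: float = 3.0
    order_bump_decay_min: float = 240.0

    def validate(self) -> None:
        if self.order_bump < 0:
            raise ConfigurationError("order_bump must be >= 0")
        if self.order_bump_decay_min <= 0:
            raise ConfigurationError("order_bump_decay_min must be > 0")
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")


@dataclass
class ScoringConfig:
    """Element validity windows and stream conventions.

    Validity is the carry-forward horizon: a measurement contributes to a
    score for this many minutes after observation (inclusive), after which
    the element is absent and contributes no points -- absent criteria are
    read as non-septic at that time point.
    """

    validity_vitals_min: float = 480.0
    validity_labs_min: float = 1440.0
    validity_gcs_min: float = 480.0
    pss_grid_min: int = 15
    sofa_baseline: str = "zero"      # or "first": first computed total

    pss: PssSurrogateParams = field(default_factory=PssSurrogateParams)

    def validate(self) -> None:
        for name in ("validity_vitals_min", "validity_labs_min",
                     "validity_gcs_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.pss_grid_min <= 0:
            raise ConfigurationError("pss_grid_min must be > 0")
        if self.sofa_baseline not in ("zero", "first"):
            raise ConfigurationError(
                f"sofa_baseline must be 'zero' or 'first', got {self.sofa_baseline!r}")
        self.pss.validate()


# ---------------------------------------------------------------------------
# pipeline bundle + YAML
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    pss_threshold: float = 8.0

    def validate(self) -> None:
        self.cohort.validate()
        self.phenotype.validate()
        self.scoring.validate()


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    names = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in names:
            raise ConfigurationError(f"unknown configuration field: {key}")
        ftype = names[key].type
        nested = {
            "cohort": CohortConfig, "phenotype": PhenotypeConfig,
            "scoring": ScoringConfig, "pss": PssSurrogateParams,
            "trajectory": TrajectoryParams,
        }
        if key in nested and isinstance(value, dict):
            kwargs[key] = _from_dict(nested[key], value)
        else:
            kwargs[key] = value
        del ftype
    return cls(**kwargs)


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(_to_dict(config), sort_keys=True)


def config_from_yaml(text: str) -> PipelineConfig:
    data = yaml.safe_load(text) or {}
    cfg = _from_dict(PipelineConfig, data)
    cfg.validate()
    return cfg


def load_config(path: str) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_yaml(fh.read())
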