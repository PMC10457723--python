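"""Adult Sepsis Event rules: antimicrobial days, organ dysfunction, label
logic, exclusions and the comorbidity index."""
import numpy as np
import pandas as pd
import pytest

from conftest import admission_row, dx_frame, obs_frame, orders_frame
from sepsisbench.cohort import Cohort
from sepsisbench.config import PhenotypeConfig
from sepsisbench.phenotyping import (apply_exclusions, charlson_index,
                                     detect_ase_sepsis, detect_esofa_events,
                                     detect_septic_shock, phenotype_cohort,
                                     qualifying_antimicrobial_days,
                                     SepsisLabel)

DAY = 1440
ABX = "cefepime"


def abx_orders(days, drug=ABX, at_min=600):
    return orders_frame([(d * DAY + at_min, "antimicrobial", drug) for d in days])


# ---------------------------------------------------------------------------
# qualifying antimicrobial days
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("days, expected", [
    ([1, 2, 3, 4], [(1, 4)]),              # minimal qualifying run
    ([1, 2, 4, 5], [(1, 2), (4, 2)]),      # gap splits; neither qualifies
    ([0], [(0, 1)]),
    ([2, 3, 4, 5, 6, 9], [(2, 5), (9, 1)]),
])
def test_qad_episodes_are_maximal_consecutive_day_runs(days, expected):
    eps = qualifying_antimicrobial_days(abx_orders(days))
    assert [(e.start_day, e.n_days) for e in eps] == expected
    for e in eps:
        assert e.qualifies(4) == (e.n_days >= 4)


def test_qad_same_day_repeat_doses_count_once():
    orders = orders_frame([(1 * DAY + 100, "antimicrobial", ABX),
                           (1 * DAY + 900, "antimicrobial", ABX),
                           (2 * DAY + 100, "antimicrobial", ABX)])
    eps = qualifying_antimicrobial_days(orders)
    assert [(e.start_day, e.n_days) for e in eps] == [(1, 2)]


def test_nonqualifying_drug_is_ignored():
    assert qualifying_antimicrobial_days(
        abx_orders([1, 2, 3, 4], drug="acetaminophen")) == []


def test_death_exemption_qualifies_short_run():
    # therapy on days 1-2, death on day 2
    eps = qualifying_antimicrobial_days(
        abx_orders([1, 2]), los_min=2 * DAY + 1200, disposition="death")
    assert len(eps) == 1 and eps[0].death_exempt and eps[0].qualifies(4)
    # exemption disabled -> does not qualify
    eps = qualifying_antimicrobial_days(
        abx_orders([1, 2]), los_min=2 * DAY + 1200, disposition="death",
        config=PhenotypeConfig(death_exemption=False))
    assert not eps[0].death_exempt and not eps[0].qualifies(4)


def test_gap_allowance_bridges_single_missing_day():
    eps = qualifying_antimicrobial_days(
        abx_orders([1, 2, 4, 5]), config=PhenotypeConfig(qad_gap_days=1))
    assert [(e.start_day, e.n_days) for e in eps] == [(1, 4)]


# ---------------------------------------------------------------------------
# eSOFA organ dysfunction
# ---------------------------------------------------------------------------

def _esofa(obs_rows, order_rows=()):
    return detect_esofa_events(obs_frame(obs_rows), orders_frame(order_rows))


def test_lactate_threshold_is_inclusive_at_two():
    events = _esofa([(10, "lactate", 1.4), (50, "lactate", 2.0)])
    assert events == [("lactate", 50)]
    assert _esofa([(10, "lactate", 1.99)]) == []


def test_creatinine_doubling_is_inclusive_at_exactly_twice_baseline():
    events = _esofa([(10, "creatinine", 0.9), (400, "creatinine", 1.8)])
    assert events == [("creatinine_doubling", 400)]
    assert _esofa([(10, "creatinine", 0.9), (400, "creatinine", 1.79)]) == []


def test_platelet_event_needs_both_low_count_and_half_decline():
    # 47% decline, still no event
    assert _esofa([(10, "platelets", 150), (400, "platelets", 80)]) == []
    # >=50% decline to <100 from baseline >=100
    assert _esofa([(10, "platelets", 200), (400, "platelets", 90)]) == [
        ("platelet_fall", 400)]
    # baseline below 100: never a platelet event
    assert _esofa([(10, "platelets", 90), (400, "platelets", 40)]) == []


def test_bilirubin_needs_absolute_and_relative_rise():
    assert _esofa([(10, "bilirubin", 1.5), (400, "bilirubin", 2.5)]) == []
    assert _esofa([(10, "bilirubin", 0.8), (400, "bilirubin", 2.0)]) == [
        ("bilirubin", 400)]


def test_order_driven_criteria_report_first_occurrence():
    events = _esofa([], [(300, "vasopressor", "norepinephrine"),
                         (100, "vasopressor", "vasopressin"),
                         (200, "mech_vent", "")])
    assert ("vasopressor_initiation", 100) in events
    assert ("mechanical_ventilation", 200) in events


def test_missing_elements_simply_yield_no_events():
    assert _esofa([(10, "heart_rate", 120)]) == []


# ---------------------------------------------------------------------------
# ASE / COVID / shock label
# ---------------------------------------------------------------------------

def _ase(obs_rows, order_rows, dx_rows=(), config=None, **adm_kw):
    return detect_ase_sepsis(
        admission_row(**adm_kw), obs_frame(obs_rows),
        orders_frame(order_rows).sort_values("time_min", kind="stable"),
        dx_frame(dx_rows), config)


def test_culture_with_qualifying_run_and_esofa_is_ase_sepsis():
    # culture day 3, QADs days 2-5, lactate 2.4 on day 3
    orders = pd.concat([orders_frame([(3 * DAY + 100, "blood_culture", "")]),
                        abx_orders([2, 3, 4, 5])])
    label = detect_ase_sepsis(admission_row(), obs_frame([(3 * DAY, "lactate", 2.4)]),
                              orders.sort_values("time_min"), dx_frame([]))
    assert label.category == "ASE_SEPSIS"
    assert label.blood_culture_min == 3 * DAY + 100
    assert label.first_qad_day == 2
    assert label.first_esofa_min == 3 * DAY


def test_qad_start_outside_two_day_window_is_nonsepsis():
    orders = pd.concat([orders_frame([(3 * DAY, "blood_culture", "")]),
                        abx_orders([6, 7, 8, 9])])
    label = detect_ase_sepsis(admission_row(los_min=12 * DAY),
                              obs_frame([(3 * DAY, "lactate", 2.4)]),
                              orders.sort_values("time_min"), dx_frame([]))
    assert label.category == "NONSEPSIS"


def test_covid_sepsis_needs_no_culture_or_antimicrobials():
    label = _ase([(2 * DAY, "lactate", 1.0)],
                 [(2 * DAY, "mech_vent", "")], [("U07.1", 0)])
    assert label.category == "COVID_SEPSIS"


def test_covid_code_without_organ_dysfunction_is_nonsepsis():
    label = _ase([(2 * DAY, "lactate", 1.0)], [], [("U07.1", 0)])
    assert label.category == "NONSEPSIS"


def test_covid_precedence_over_ase_is_configurable():
    obs = [(3 * DAY, "lactate", 2.4)]
    orders = pd.concat([orders_frame([(3 * DAY, "blood_culture", "")]),
                        abx_orders([3, 4, 5, 6])]).sort_values("time_min")
    both = lambda cfg: detect_ase_sepsis(
        admission_row(), obs_frame(obs), orders, dx_frame([("U07.1", 0)]), cfg)
    assert both(PhenotypeConfig()).category == "COVID_SEPSIS"
    assert both(PhenotypeConfig(covid_precedence=False)).category == "ASE_SEPSIS"


def test_septic_shock_requires_sepsis_plus_code_or_vasopressor():
    sepsis = SepsisLabel("A1", "ASE_SEPSIS")
    nonsepsis = SepsisLabel("A1", "NONSEPSIS")
    vaso = orders_frame([(100, "vasopressor", "norepinephrine")])
    none = orders_frame([])
    assert detect_septic_shock(vaso, dx_frame([]), sepsis)
    assert not detect_septic_shock(vaso, dx_frame([]), nonsepsis)
    assert detect_septic_shock(none, dx_frame([("R65.21", 100)]), sepsis)
    assert detect_septic_shock(none, dx_frame([("T81.12XA", 100)]), sepsis)
    assert not detect_septic_shock(none, dx_frame([]), sepsis)


def test_adding_an_esofa_event_never_flips_positive_to_negative():
    orders = pd.concat([orders_frame([(3 * DAY, "blood_culture", "")]),
                        abx_orders([3, 4, 5, 6])]).sort_values("time_min")
    base_obs = [(3 * DAY, "lactate", 2.4)]
    before = detect_ase_sepsis(admission_row(), obs_frame(base_obs), orders,
                               dx_frame([]))
    after = detect_ase_sepsis(
        admission_row(), obs_frame(base_obs + [(4 * DAY, "lactate", 5.0)]),
        orders, dx_frame([]))
    assert before.category == "ASE_SEPSIS" and after.category == "ASE_SEPSIS"
    more_orders = pd.concat([orders, orders_frame(
        [(2 * DAY, "vasopressor", "norepinephrine")])]).sort_values("time_min")
    assert detect_ase_sepsis(admission_row(), obs_frame(base_obs), more_orders,
                             dx_frame([])).category == "ASE_SEPSIS"


# ---------------------------------------------------------------------------
# brute-force oracle over random small admissions
# ---------------------------------------------------------------------------

def _brute_force_ase(culture_days, qad_days, has_esofa, min_days=4):
    """Direct scan over all (culture, episode) pairs on a day-set basis."""
    days = sorted(set(qad_days))
    episodes = []
    for d in days:
        if episodes and d - episodes[-1][-1] == 1:
            episodes[-1].append(d)
        else:
            episodes.append([d])
    return has_esofa and any(
        len(ep) >= min_days and abs(ep[0] - c) <= 2
        for c in culture_days for ep in episodes)


def test_ase_detection_matches_brute_force_on_random_order_sets(rng):
    for _ in range(300):
        culture_days = sorted(rng.choice(10, size=rng.integers(0, 3),
                                         replace=False))
        qad_days = sorted(rng.choice(12, size=rng.integers(0, 8),
                                     replace=False))
        has_esofa = bool(rng.random() < 0.7)
        obs = obs_frame([(5 * DAY, "lactate", 3.0)] if has_esofa else [])
        orders = pd.concat(
            [orders_frame([(int(c) * DAY + 60, "blood_culture", "")
                           for c in culture_days]),
             abx_orders([int(d) for d in qad_days])]).sort_values("time_min")
        got = detect_ase_sepsis(admission_row(los_min=20 * DAY), obs, orders,
                                dx_frame([]))
        want = _brute_force_ase(culture_days, qad_days, has_esofa)
        assert (got.category == "ASE_SEPSIS") == want, (
            culture_days, qad_days, has_esofa)


# ---------------------------------------------------------------------------
# Charlson index
# ---------------------------------------------------------------------------

def test_charlson_no_codes_scores_zero():
    assert charlson_index(dx_frame([]), 10 * DAY) == (0, "0-1")


def test_charlson_sums_distinct_component_weights():
    dx = dx_frame([("E11.9", -100 * DAY), ("J44.9", -30 * DAY),
                   ("J44.1", -10 * DAY)])  # diabetes 1 + COPD 1 (COPD once)
    assert charlson_index(dx, 10 * DAY) == (2, "2-5")


def test_charlson_metastatic_cancer_reaches_top_category():
    score, cat = charlson_index(dx_frame([("C78.7", -DAY)]), 10 * DAY)
    assert score == 6 and cat == ">=6"


def test_charlson_hierarchy_counts_severe_form_only():
    dx = dx_frame([("C50.9", -DAY), ("C78.7", -DAY)])  # tumor + metastasis
    assert charlson_index(dx, 10 * DAY)[0] == 6
    dx = dx_frame([("E11.9", -DAY), ("E11.2", -DAY)])  # diabetes +/- compl.
    assert charlson_index(dx, 10 * DAY)[0] == 2


def test_charlson_lookback_window_is_two_years_through_discharge():
    old = dx_frame([("C78.7", -800 * DAY)])
    assert charlson_index(old, 10 * DAY)[0] == 0
    during = dx_frame([("C78.7", 5 * DAY)])
    assert charlson_index(during, 10 * DAY)[0] == 6
    assert charlson_index(during, 3 * DAY)[0] == 0  # after discharge


def test_charlson_unmapped_codes_are_ignored():
    assert charlson_index(dx_frame([("Z99.9", -DAY)]), 10 * DAY)[0] == 0


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------

def _one_admission_cohort(**adm_kw):
    adm = pd.DataFrame([admission_row(**adm_kw).to_dict()])
    obs = obs_frame([(100, "temperature", 37.0), (100, "sbp", 120.0)])
    return Cohort(admissions=adm, observations=obs,
                  orders=orders_frame([]), dx_codes=dx_frame([]))


@pytest.mark.parametrize("los_days, rule", [(31, "los_gt_30d"), (30.0, None)])
def test_los_exclusion_is_strictly_greater_than_30_days(los_days, rule):
    cohort = _one_admission_cohort(los_min=int(los_days * DAY))
    retained, report = apply_exclusions(cohort)
    if rule:
        assert report.counts[rule] == 1 and report.n_retained == 0
    else:
        assert report.n_retained == 1


def test_no_bp_and_no_temperature_excluded():
    cohort = _one_admission_cohort()
    cohort.observations = obs_frame([(100, "heart_rate", 80.0)])
    _, report = apply_exclusions(cohort)
    assert report.counts["no_bp_temp"] == 1
    # temperature alone keeps the admission
    cohort.observations = obs_frame([(100, "temperature", 37.0)])
    _, report = apply_exclusions(cohort)
    assert report.n_retained == 1


@pytest.mark.parametrize("field, value, rule", [
    ("service", "burn", "burn_service"),
    ("disposition", "ama", "ama"),
    ("source", "external_transfer", "transfer"),
    ("source", "internal_transfer", "transfer"),
])
def test_single_rule_exclusions(field, value, rule):
    cohort = _one_admission_cohort(**{field: value})
    _, report = apply_exclusions(cohort)
    assert report.counts[rule] == 1


def test_first_matching_rule_attribution_and_conservation(small_cohort):
    retained, report = apply_exclusions(small_cohort)
    assert report.n_input == report.n_retained + sum(report.counts.values())
    # burn + LOS>30 admission counts under burn (listed first)
    cohort = _one_admission_cohort(service="burn", los_min=40 * DAY)
    _, rep = apply_exclusions(cohort)
    assert rep.counts["burn_service"] == 1 and rep.counts["los_gt_30d"] == 0


def test_sepsis_readmission_within_30_days_is_excluded():
    septic = admission_row(admission_id="A1", los_min=10 * DAY).to_dict()
    readmit = admission_row(admission_id="A2", los_min=5 * DAY).to_dict()
    readmit.update(admit_min=10 * DAY + 20 * DAY,
                   discharge_min=10 * DAY + 25 * DAY)
    adm = pd.DataFrame([septic, readmit])
    obs = pd.concat([
        obs_frame([(100, "temperature", 37.0), (3 * DAY, "lactate", 3.0)], "A1"),
        obs_frame([(100, "temperature", 37.0)], "A2")])
    orders = pd.concat([
        orders_frame([(3 * DAY, "blood_culture", "")], "A1"),
        orders_frame([(d * DAY + 600, "antimicrobial", ABX)
                      for d in (3, 4, 5, 6)], "A1")])
    cohort = Cohort(admissions=adm, observations=obs, orders=orders,
                    dx_codes=dx_frame([]))
    _, report = apply_exclusions(cohort)
    assert report.counts["sepsis_readmission_30d"] == 1
    assert report.excluded["admission_id"].tolist() == ["A2"]


def test_every_retained_admission_gets_exactly_one_category(small_cohort):
    retained, report = apply_exclusions(small_cohort)
    labels = phenotype_cohort(retained)
    assert len(labels) == report.n_retained
    counts = labels["category"].value_counts()
    assert counts.sum() == report.n_retained
    assert set(counts.index) <= {"ASE_SEPSIS", "COVID_SEPSIS", "NONSEPSIS"}
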