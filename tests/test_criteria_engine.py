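"""Criteria engine: rule semantics, PPI protection, cross-module labels."""

from collections import defaultdict
from datetime import date, timedelta

import pytest

from pipcox.criteria_engine import (
    CriteriaConfig,
    classify_atc,
    default_criteria,
    episodes_for_criterion,
    evaluate_cohort_part1,
    evaluate_cohort_part2,
    merge_other_pips,
    part1_pip_records,
    part2_med_records,
    raw_criterion_intervals,
    PIPRecord,
)
from pipcox.ehr_model import (
    DateInterval,
    DiagnosisEvent,
    PatientRecord,
    Prescription,
)
from pipcox.episode_merge import merge_intervals, subtract_intervals

from conftest import interval_dayset

CONFIG = CriteriaConfig()
CRITERIA = CONFIG.criteria


def _patient(birth=date(1936, 6, 15), entry=date(2007, 1, 1), exit_=date(2014, 12, 31), sex="F"):
    return PatientRecord("P1", birth, sex, entry, exit_, "study_end")


def _rx(atc, start, end, dose=None):
    return Prescription("P1", atc, start, end, dose)


def _dx(icpc, d):
    return DiagnosisEvent("P1", icpc, d)


def _eval(code, patient, prescriptions, diagnoses=()):
    spec = CRITERIA[code]
    eps = episodes_for_criterion(prescriptions, spec, CONFIG)
    return part1_pip_records(spec, patient, eps, list(diagnoses), CONFIG)


def test_atc_classification_longest_prefix():
    assert classify_atc("A02BC01") == "PPI"
    assert classify_atc("M01AE01") == "NSAID"
    assert classify_atc("B01AC06") == "ASA_ECC"  # plain ASA carved out of B01AC
    assert classify_atc("B01AC08") == "ASA_ECC"
    assert classify_atc("B01AC04") == "platelet_inhibitor"
    assert classify_atc("B01AA04") == "oral_anticoagulant"
    assert classify_atc("N06AB06") == "SSRI"
    assert classify_atc("C10AA05") is None


def test_d2b_age_70_patient_full_episode():
    """An NSAID episode in a 70+ patient is nonadherent throughout."""
    patient = _patient(birth=date(1936, 6, 15))  # 70 throughout 2007
    recs = _eval("START_D2B", patient, [_rx("M01AE01", date(2007, 1, 11), date(2007, 1, 28))])
    # NSAID gap extension adds 3 days to the script tail
    assert [r.interval for r in recs] == [DateInterval(date(2007, 1, 11), date(2007, 1, 31))]


def test_d2b_age_64_no_record():
    patient = _patient(birth=date(1943, 1, 1))  # 64 in 2007
    recs = _eval("START_D2B", patient, [_rx("M01AE01", date(2007, 2, 1), date(2007, 2, 20))])
    assert recs == []


def test_d2b_interval_starts_at_70th_birthday_mid_episode():
    """The age condition switches on at the birthday, splitting the episode."""
    patient = _patient(birth=date(1937, 6, 1))  # turns 70 on 2007-06-01
    recs = _eval("START_D2B", patient, [_rx("M01AE01", date(2007, 5, 1), date(2007, 7, 1))])
    assert [r.interval for r in recs] == [DateInterval(date(2007, 6, 1), date(2007, 7, 4))]


def test_a9_dose_threshold():
    """ASA qualifies only above 160 mg/day (ECC above 200)."""
    patient = _patient()
    low = _eval("STOPP_A9", patient, [_rx("B01AC06", date(2007, 3, 1), date(2007, 3, 20), 100.0)])
    assert low == []
    high = _eval("STOPP_A9", patient, [_rx("B01AC06", date(2007, 3, 1), date(2007, 3, 20), 200.0)])
    assert [r.interval for r in high] == [DateInterval(date(2007, 3, 1), date(2007, 3, 25))]
    # carbasalate calcium threshold is 200 mg/day
    ecc = _eval("STOPP_A9", patient, [_rx("B01AC08", date(2007, 3, 1), date(2007, 3, 20), 180.0)])
    assert ecc == []


def test_a15_ignores_ppi_protection():
    """Anticoagulant + bleeding disorder is a PIM regardless of PPI."""
    patient = _patient()
    rx = [
        _rx("B01AA04", date(2008, 1, 1), date(2008, 1, 31)),
        _rx("A02BC01", date(2008, 1, 1), date(2008, 2, 28)),
    ]
    recs = _eval("STOPP_A15", patient, rx, [_dx("B83", date(2000, 5, 5))])
    assert [r.interval for r in recs] == [DateInterval(date(2008, 1, 1), date(2008, 2, 2))]
    # without the bleeding-disorder history: nothing
    assert _eval("STOPP_A15", patient, rx) == []


def test_e5_qualifies_after_90_days_of_continuous_nsaid():
    patient = _patient()
    rx = [_rx("M01AE01", date(2008, 1, 1), date(2008, 6, 30))]
    recs = _eval("STOPP_E5", patient, rx, [_dx("T92", date(2001, 1, 1))])
    assert [r.interval for r in recs] == [
        DateInterval(date(2008, 1, 1) + timedelta(days=90), date(2008, 7, 3))
    ]
    # a short course never qualifies
    short = _eval("STOPP_E5", patient, [_rx("M01AE01", date(2008, 1, 1), date(2008, 2, 15))],
                  [_dx("T92", date(2001, 1, 1))])
    assert short == []


def test_d3b_requires_concurrent_companion():
    """ASA + SSRI in a 75-year-old: exposure only while both run."""
    patient = _patient(birth=date(1932, 1, 1))
    rx = [
        _rx("B01AC06", date(2007, 3, 1), date(2007, 3, 26)),  # +5 gap -> Mar 31
        _rx("N06AB06", date(2007, 3, 15), date(2007, 4, 15)),
    ]
    recs = _eval("START_D3B", patient, rx)
    assert [r.interval for r in recs] == [DateInterval(date(2007, 3, 15), date(2007, 3, 31))]


def test_ppi_protection_subtracts_days():
    patient = _patient(birth=date(1930, 1, 1))
    nsaid = _rx("M01AE01", date(2007, 1, 11), date(2007, 1, 28))  # episode Jan 11-31
    full = _eval("START_D2B", patient, [nsaid, _rx("A02BC01", date(2007, 1, 8), date(2007, 1, 31))])
    assert full == []  # PPI (with its own 3 gap days) covers the episode
    partial = _eval("START_D2B", patient, [nsaid, _rx("A02BC01", date(2007, 1, 20), date(2007, 1, 22))])
    assert [r.interval for r in partial] == [
        DateInterval(date(2007, 1, 11), date(2007, 1, 19)),
        DateInterval(date(2007, 1, 26), date(2007, 1, 31)),
    ]


def test_records_clipped_to_observation_window():
    patient = _patient(entry=date(2007, 1, 15), exit_=date(2007, 1, 25), birth=date(1930, 1, 1))
    recs = _eval("START_D2B", patient, [_rx("M01AE01", date(2007, 1, 1), date(2007, 2, 20))])
    assert [r.interval for r in recs] == [DateInterval(date(2007, 1, 15), date(2007, 1, 25))]


def test_unknown_criterion_rejected():
    spec = CRITERIA["START_D2B"]
    bogus = type(spec)(code="STOPP_X1", primary_drug_classes=frozenset({"NSAID"}))
    with pytest.raises(ValueError):
        raw_criterion_intervals(bogus, _patient(), {}, [])


def test_part2_keeps_medication_as_is():
    """Part-2 med intervals ignore PPI; PPI episodes returned separately."""
    patient = _patient(birth=date(1930, 1, 1))
    spec = CRITERIA["START_D2B"]
    rx = [
        _rx("M01AE01", date(2007, 1, 11), date(2007, 1, 28)),
        _rx("A02BC01", date(2007, 1, 20), date(2007, 1, 22)),
    ]
    eps = episodes_for_criterion(rx, spec, CONFIG)
    out = part2_med_records(spec, patient, eps, [], CONFIG)
    assert out["med_intervals"] == [DateInterval(date(2007, 1, 11), date(2007, 1, 31))]
    assert out["ppi_intervals"] == [DateInterval(date(2007, 1, 20), date(2007, 1, 25))]
    with pytest.raises(ValueError):
        part2_med_records(CRITERIA["STOPP_A9"], patient, eps, [], CONFIG)


def test_part2_without_ppi_scripts():
    patient = _patient(birth=date(1930, 1, 1))
    spec = CRITERIA["START_D2B"]
    eps = episodes_for_criterion([_rx("M01AE01", date(2007, 1, 11), date(2007, 1, 28))], spec, CONFIG)
    out = part2_med_records(spec, patient, eps, [], CONFIG)
    assert out["ppi_intervals"] == []


def test_merge_other_pips_worked_example():
    """Analysing one criterion merges the remaining records per patient."""
    a15 = PIPRecord("P1", "STOPP_A15", DateInterval(date(2007, 1, 1), date(2007, 1, 14)))
    d2b = PIPRecord("P1", "START_D2B", DateInterval(date(2007, 1, 11), date(2007, 1, 31)))
    d2c = PIPRecord("P1", "START_D2C", DateInterval(date(2007, 1, 8), date(2007, 1, 14)))
    other = merge_other_pips([a15, d2b, d2c], "STOPP_A15")
    assert [(r.criterion_code, r.interval) for r in other] == [
        ("OTHER", DateInterval(date(2007, 1, 8), date(2007, 1, 31)))
    ]
    assert merge_other_pips([a15], "STOPP_A15") == []


def test_merge_other_pips_matches_dayset_oracle():
    import numpy as np

    from conftest import random_intervals

    rng = np.random.default_rng(3)
    codes = list(CRITERIA)
    records = []
    for pid in ("A", "B", "C"):
        for iv in random_intervals(rng, 25):
            records.append(PIPRecord(pid, codes[int(rng.integers(len(codes)))], iv))
    excluded = "START_D2B"
    other = merge_other_pips(records, excluded)
    for pid in ("A", "B", "C"):
        got = interval_dayset([r.interval for r in other if r.patient_id == pid])
        want = interval_dayset(
            [r.interval for r in records if r.patient_id == pid and r.criterion_code != excluded]
        )
        assert got == want


# --- cross-module properties on synthetic cohorts ---


def _records_by_key(records):
    out = defaultdict(list)
    for r in records:
        out[(r.criterion_code, r.patient_id)].append(r.interval)
    return out


@pytest.mark.parametrize("seed", [7, 19, 301])
def test_engine_reproduces_generator_labels_exactly(seed):
    """Interval engine output equals the day-grid ground-truth labels."""
    from pipcox.synthetic_data import SimulationConfig, generate_cohort

    cohort, truth = generate_cohort(SimulationConfig(n_patients=150, seed=seed))
    engine = _records_by_key(evaluate_cohort_part1(cohort))
    gt = {
        (code, pid): ivs
        for code, by_pid in truth.part1_intervals.items()
        for pid, ivs in by_pid.items()
    }
    assert set(engine) == set(gt)
    for key in gt:
        assert sorted(engine[key]) == sorted(gt[key]), key


def test_part1_equals_part2_minus_ppi(small_cohort):
    """Definitional identity: part-1 = part-2 medication minus PPI days."""
    cohort, _ = small_cohort
    part1 = _records_by_key(evaluate_cohort_part1(cohort))
    for code in ("START_D2B", "START_D3C", "START_D2A"):
        part2 = evaluate_cohort_part2(cohort, code)
        for pid, rec in part2.items():
            expect = subtract_intervals(rec["med_intervals"], rec["ppi_intervals"])
            got = part1.get((code, pid), [])
            assert merge_intervals(got) == expect, (code, pid)


def test_yaml_config_overrides(tmp_path):
    """Criteria YAML overrides merge into the defaults."""
    cfg_file = tmp_path / "criteria.yaml"
    cfg_file.write_text(
        """
strict_age_bounds: true
gap_days:
  overrides:
    START_D2C/platelet_inhibitor: 2
    START_D2B/NSAID: 7
criteria:
  START_D2B:
    age_min: 75
"""
    )
    cfg = CriteriaConfig.from_yaml(cfg_file)
    assert cfg.strict_age_bounds
    assert cfg.gap_table.gap("START_D2B", "NSAID") == 7
    assert cfg.gap_table.gap("START_D3B", "NSAID") == 3  # untouched default
    assert cfg.criteria["START_D2B"].age_min == 75
    assert cfg.criteria["START_D2B"].ppi_protective  # inherited
    assert cfg.criteria["START_D3C"].age_min == 80  # untouched


def test_no_record_outside_observation_window(small_cohort):
    cohort, _ = small_cohort
    windows = {
        r.patient_id: (r.entry_date, r.exit_date) for r in cohort.patients.itertuples(index=False)
    }
    for rec in evaluate_cohort_part1(cohort):
        lo, hi = windows[rec.patient_id]
        assert lo <= rec.interval.start <= rec.interval.end <= hi
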