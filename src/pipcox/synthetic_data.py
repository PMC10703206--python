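"""Synthetic primary-care cohorts with known ground truth.

The source GP database is not public, so every downstream stage is
exercised on simulated cohorts that reproduce the statistical structure
the analysis relies on:

* dynamic entry/exit over an 8-year window, with patients entering at
  the study start or at their 65th birthday and leaving at death,
  de-registration or the study end;
* chronic medication issued as consecutive scripts of 14-90 days with
  refill gaps of 0-10 days, so the gap-day merging rule is exercised in
  both directions (gaps small enough to merge and large enough to
  split);
* co-prescription patterns (NSAID/ASA with or without PPI,
  anticoagulants, SSRIs, corticosteroids) and pre-study history
  diagnoses (peptic ulcer, gout, bleeding disorder);
* gastrointestinal bleedings drawn from a proportional-hazards model
  ``lambda(t) = lambda0 * exp(b_exp*PIP(t) + b_ppi*PPI(t) + b_age*age(t)
  + b_male*male)`` at day resolution, written as specific ICPC codes or
  (for a configured fraction) as free-text-only journal notes, plus
  distractor notes that must *not* be detected.

The generator also emits day-level ground-truth exposure labels per
criterion, computed by an independent day-grid (boolean array)
implementation of the same rules the interval-based criteria engine
applies; exact agreement between the two is a cross-module test.  An
in-study bleeding coded as an ulcer (D85/D86) creates "history of
peptic ulcer" from that day onward and the labels are updated
accordingly, mirroring what the rule engine sees when run on the final
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ehr_model import (
    Cohort,
    DateInterval,
    STUDY_END,
    STUDY_START,
    anniversary_in_year,
    compute_age,
)
from .criteria_engine import CriteriaConfig, CriterionSpec, START_CODES, classify_atc
from .episode_merge import merge_intervals

__all__ = [
    "DrugClassConfig",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "simulate_bleedings",
    "write_simulation_outputs",
]

_EVENT_ICPC = ("D14", "D15", "D85", "D86")
#: channel mix of coded bleedings (hematemesis/melena/duodenal/other ulcer)
_EVENT_ICPC_WEIGHTS = (19, 36, 33, 39)

_BLEEDING_NOTE_TEMPLATES = (
    "melena, bloedverlies uit de maag",
    "maagbloeding bij chronisch NSAID gebruik",
    "bloeding tractus digestivus, verwijzing MDL",
    "gastro-intestinale bloeding vastgesteld",
    "haematemesis, fors bloedverlies maag",
)
#: keyword-bearing notes attached to a specific non-GI code: the
#: detector's exclusion rule must reject these
_DISTRACTOR_TEMPLATES = (
    ("recidiverende neusbloeding; ook maagklachten besproken", "R06"),
    ("bloed in urine, tevens maagpijn gemeld", "U06"),
    ("vaginaal bloedverlies; maag rustig", "W03"),
)
#: anchor-only notes that must not fire either
_BENIGN_NOTE_TEMPLATES = (
    "controle bloeddruk, stabiel",
    "bloedonderzoek aangevraagd",
)


@dataclass(frozen=True)
class DrugClassConfig:
    """Prescribing behaviour for one drug class.

    ``user_prob`` is the probability a patient ever uses the class;
    users receive ``1 + Poisson(mean_episodes - 1)`` treatment episodes,
    each issued as ``1 + Poisson(mean_scripts - 1)`` consecutive scripts
    of uniform 14-90 day length separated by uniform 0-10 day refill
    gaps.  Doses are drawn per episode from ``dose_options_mg``.
    """

    user_prob: float
    atc_codes: tuple
    dose_options_mg: tuple  # ((dose, weight), ...)
    mean_episodes: float = 1.4
    mean_scripts: float = 3.0
    script_len_min: int = 14
    script_len_max: int = 90
    refill_gap_max: int = 10


def _default_drug_classes() -> dict:
    return {
        "NSAID": DrugClassConfig(
            0.12, ("M01AE01", "M01AB05"), ((1200.0, 0.7), (500.0, 0.3)),
            mean_scripts=1.6, script_len_max=50,
        ),
        "ASA_ECC": DrugClassConfig(
            0.10, ("B01AC06", "B01AC08"), ((80.0, 0.55), (100.0, 0.25), (240.0, 0.20)),
            mean_scripts=2.5,
        ),
        "PPI": DrugClassConfig(0.10, ("A02BC01", "A02BC02"), ((20.0, 0.6), (40.0, 0.4))),
        "oral_anticoagulant": DrugClassConfig(
            0.08, ("B01AA04", "B01AF01"), ((3.0, 0.5), (110.0, 0.5))
        ),
        "platelet_inhibitor": DrugClassConfig(0.05, ("B01AC04",), ((75.0, 1.0),)),
        "corticosteroid": DrugClassConfig(0.07, ("H02AB06",), ((30.0, 1.0),)),
        "SSRI": DrugClassConfig(0.08, ("N06AB06",), ((20.0, 1.0),)),
    }


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator (defaults emulate the study).

    Hazard coefficients are on the log scale; the default planted
    exposure effect matches the headline composite hazard ratio of 5.45
    so that recovery is checked at the scale the analysis operates on.
    The default baseline hazard is far above the source database's
    empirical bleeding rate: at desk scale (a few thousand patients
    rather than ~27,000) it yields enough events for stable model fits,
    and it is a single number to lower for realism.
    """

    n_patients: int = 2000
    study_start: date = STUDY_START
    study_end: date = STUDY_END
    seed: int = 0

    # hazard structure
    baseline_hazard_per_day: float = 2e-5
    log_hr_exposure: float = float(np.log(5.45))
    log_hr_ppi: float = 0.0
    log_hr_age_per_year: float = 0.05
    #: the age effect is applied to (age - age_ref_years), so the
    #: baseline hazard is that of an unexposed female of this age
    age_ref_years: float = 75.0
    log_hr_male: float = 0.4
    min_interevent_gap_days: int = 30

    # demographics; age at study start uniform on [57, 90] so that
    # everyone is >=65 at some point of the window
    age_at_start_min: float = 57.0
    age_at_start_max: float = 90.0
    female_prob: float = 0.59
    exit_rate_per_year: float = 0.08  # death + leaving combined
    death_fraction_of_exits: float = 0.55

    # prescribing
    drug_classes: dict = field(default_factory=_default_drug_classes)
    ppi_coprescription_prob: float = 0.40

    # pre-study history diagnoses
    peptic_ulcer_history_prob: float = 0.05
    gout_history_prob: float = 0.04
    bleeding_disorder_history_prob: float = 0.03

    # journal notes
    freetext_only_bleeding_prob: float = 0.13  # fraction of bleedings text-only
    distractor_note_prob: float = 0.04
    benign_note_prob: float = 0.10

    #: design target for the fraction of patients with >=1 PIP record;
    #: documents what the default prescribing parameters aim at
    expected_pip_patient_fraction: float = 0.12

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if k in ("study_start", "study_end"):
                v = date.fromisoformat(v)
            elif k == "drug_classes":
                v = {
                    name: DrugClassConfig(
                        user_prob=b["user_prob"],
                        atc_codes=tuple(b["atc_codes"]),
                        dose_options_mg=tuple(tuple(x) for x in b["dose_options_mg"]),
                        mean_episodes=b.get("mean_episodes", 1.4),
                        mean_scripts=b.get("mean_scripts", 3.0),
                        script_len_min=b.get("script_len_min", 14),
                        script_len_max=b.get("script_len_max", 90),
                        refill_gap_max=b.get("refill_gap_max", 10),
                    )
                    for name, b in v.items()
                }
            if not hasattr(cfg, k):
                raise ValueError(f"unknown simulation config key {k!r}")
            setattr(cfg, k, v)
        return cfg


@dataclass
class GroundTruth:
    """What the generator knows: labels, events and true parameters."""

    #: criterion code -> patient_id -> part-1 exposure intervals
    part1_intervals: dict
    #: patient_id -> merged union of all part-1 intervals
    combined_intervals: dict
    #: patient_id -> PPI coverage intervals (3-day gap extension)
    ppi_intervals: dict
    #: (patient_id, date, channel, code) per planted bleeding
    events: list
    true_params: dict


# ---------------------------------------------------------------------------
# day-grid label computation (independent of the interval engine)


class _PatientSim:
    """Working state for one simulated patient on the study day grid."""

    __slots__ = (
        "pid", "birth", "sex", "entry", "exit", "exit_reason",
        "rx", "dx", "labels", "combined", "ppi", "age_days", "_cov_cache",
    )

    def __init__(self, pid, birth, sex, entry, exit_, exit_reason):
        self.pid = pid
        self.birth = birth
        self.sex = sex
        self.entry = entry  # day index
        self.exit = exit_  # day index, inclusive
        self.exit_reason = exit_reason
        self.rx = []  # (atc, cls, start_idx, end_idx, dose)
        self.dx = []  # (icpc, date)
        self.labels = {}
        self.combined = None
        self.ppi = None
        self.age_days = None
        self._cov_cache = {}


def _coverage(sim: _PatientSim, D: int, cls: str, gap: int, dose_spec=None) -> np.ndarray:
    """Boolean day array: class coverage with each script extended by gap."""
    key = (cls, gap, id(dose_spec))
    cached = sim._cov_cache.get(key)
    if cached is not None:
        return cached
    arr = np.zeros(D, dtype=bool)
    for atc, c, s, e, dose in sim.rx:
        if c != cls:
            continue
        if dose_spec is not None:
            thr, thr_len = None, -1
            for prefix, t in dose_spec.items():
                if atc.startswith(prefix) and len(prefix) > thr_len:
                    thr, thr_len = t, len(prefix)
            if thr is None or dose is None or not dose > thr:
                continue
        arr[s : min(e + gap, D - 1) + 1] = True
    sim._cov_cache[key] = arr
    return arr


def _age_ok_array(sim: _PatientSim, D: int, study_start: date, age_min, age_max) -> np.ndarray:
    idx = np.arange(D)
    ok = np.ones(D, dtype=bool)
    if age_min is not None:
        d0 = (anniversary_in_year(sim.birth, sim.birth.year + age_min) - study_start).days
        ok &= idx >= d0
    if age_max is not None:
        d1 = (anniversary_in_year(sim.birth, sim.birth.year + age_max + 1) - study_start).days
        ok &= idx < d1
    return ok


def _history_array(sim: _PatientSim, D: int, study_start: date, codes: frozenset) -> np.ndarray:
    dates = [d for c, d in sim.dx if c in codes]
    arr = np.zeros(D, dtype=bool)
    if dates:
        first = (min(dates) - study_start).days
        arr[max(first, 0):] = True
    return arr


def _label_criterion(
    sim: _PatientSim, spec: CriterionSpec, cc: CriteriaConfig, D: int, study_start: date
) -> np.ndarray:
    """Day-grid part-1 label for one criterion (clipped to the window)."""
    primary = np.zeros(D, dtype=bool)
    for cls in spec.primary_drug_classes:
        gap = cc.gap_table.gap(spec.code, cls)
        cov = _coverage(sim, D, cls, gap, spec.dose_thresholds_mg)
        if spec.min_duration_days:
            # qualify from day (min_duration+1) of each continuous run
            padded = np.concatenate(([False], cov, [False])).astype(np.int8)
            d = np.diff(padded)
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0] - 1
            run_cov = np.zeros(D, dtype=bool)
            for s, e in zip(starts, ends):
                qs = s + spec.min_duration_days
                if qs <= e:
                    run_cov[qs : e + 1] = True
            cov = run_cov
        primary |= cov
    lab = primary
    if spec.companion_drug_classes:
        comp = np.zeros(D, dtype=bool)
        for cls in spec.companion_drug_classes:
            comp |= _coverage(sim, D, cls, cc.gap_table.gap(spec.code, cls))
        lab = lab & comp
    if spec.required_history_icpc:
        lab = lab & _history_array(sim, D, study_start, spec.required_history_icpc)
    if spec.age_min is not None or spec.age_max is not None:
        amin = spec.age_min + 1 if (cc.strict_age_bounds and spec.age_min is not None) else spec.age_min
        lab = lab & _age_ok_array(sim, D, study_start, amin, spec.age_max)
    if spec.is_start and spec.ppi_protective:
        lab = lab & ~_coverage(sim, D, "PPI", cc.gap_table.gap(spec.code, "PPI"))
    out = np.zeros(D, dtype=bool)
    out[sim.entry : sim.exit + 1] = lab[sim.entry : sim.exit + 1]
    return out


def _relabel(sim: _PatientSim, cc: CriteriaConfig, D: int, study_start: date) -> None:
    sim._cov_cache.clear()
    if not sim.rx:  # no medication, no exposure
        sim.labels = {}
        sim.combined = np.zeros(D, dtype=bool)
        sim.ppi = np.zeros(D, dtype=bool)
        return
    sim.labels = {
        code: _label_criterion(sim, spec, cc, D, study_start)
        for code, spec in cc.criteria.items()
    }
    combined = np.zeros(D, dtype=bool)
    for arr in sim.labels.values():
        combined |= arr
    sim.combined = combined
    ppi = _coverage(sim, D, "PPI", cc.gap_table.gap("START_D2B", "PPI"))
    clipped = np.zeros(D, dtype=bool)
    clipped[sim.entry : sim.exit + 1] = ppi[sim.entry : sim.exit + 1]
    sim.ppi = clipped


def _update_ulcer_labels(sim: _PatientSim, cc: CriteriaConfig, D: int, study_start: date) -> None:
    """Refresh only the peptic-ulcer-history criteria after a new ulcer code.

    Drug coverage is unchanged, so the cached coverage arrays remain
    valid; only the history condition (and hence the combined label)
    can differ.
    """
    if not sim.rx:
        return
    for code in ("START_D2A", "START_D3A"):
        spec = cc.criteria.get(code)
        if spec is not None:
            sim.labels[code] = _label_criterion(sim, spec, cc, D, study_start)
    combined = np.zeros(D, dtype=bool)
    for arr in sim.labels.values():
        combined |= arr
    sim.combined = combined


def _array_to_intervals(arr: np.ndarray, study_start: date) -> list[DateInterval]:
    padded = np.concatenate(([False], arr, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return [
        DateInterval(study_start + timedelta(days=int(s)), study_start + timedelta(days=int(e)))
        for s, e in zip(starts, ends)
    ]


def _age_day_array(sim: _PatientSim, D: int, study_start: date) -> np.ndarray:
    """Completed age per study day (int array)."""
    if sim.age_days is not None:
        return sim.age_days
    idx = np.arange(D)
    base = compute_age(sim.birth, study_start)
    bumps = np.zeros(D, dtype=np.int32)
    for year in range(study_start.year, study_start.year + 10):
        ann = (anniversary_in_year(sim.birth, year) - study_start).days
        if 0 < ann < D:
            bumps[ann] = 1
        elif ann <= 0:
            pass
    ages = base + np.cumsum(bumps)
    sim.age_days = ages
    return ages


# ---------------------------------------------------------------------------
# cohort generation


def _sample_weighted(rng, options):
    if len(options) == 1:
        return options[0][0]
    w = np.array([o[1] for o in options], dtype=float)
    cum = np.cumsum(w)
    i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return options[min(i, len(options) - 1)][0]


def _generate_prescriptions(sim: _PatientSim, cfg: SimulationConfig, rng, D: int) -> None:
    for cls, dc in cfg.drug_classes.items():
        if rng.random() >= dc.user_prob:
            continue
        n_episodes = 1 + rng.poisson(max(dc.mean_episodes - 1.0, 0.0))
        for _ in range(n_episodes):
            if sim.exit <= sim.entry:
                break
            start = int(rng.integers(sim.entry, sim.exit + 1))
            atc = dc.atc_codes[int(rng.integers(len(dc.atc_codes)))]
            dose = float(_sample_weighted(rng, dc.dose_options_mg))
            n_scripts = 1 + rng.poisson(max(dc.mean_scripts - 1.0, 0.0))
            day = start
            emit_ppi = cls in ("NSAID", "ASA_ECC") and rng.random() < cfg.ppi_coprescription_prob
            for _ in range(n_scripts):
                if day > sim.exit:
                    break
                length = int(rng.integers(dc.script_len_min, dc.script_len_max + 1))
                end = min(day + length - 1, sim.exit)
                sim.rx.append((atc, cls, day, end, dose))
                if emit_ppi:
                    ppi_dc = cfg.drug_classes["PPI"]
                    ppi_atc = ppi_dc.atc_codes[int(rng.integers(len(ppi_dc.atc_codes)))]
                    ppi_dose = float(_sample_weighted(rng, ppi_dc.dose_options_mg))
                    sim.rx.append(("%s" % ppi_atc, "PPI", day, end, ppi_dose))
                day = end + 1 + int(rng.integers(0, dc.refill_gap_max + 1))


def _generate_history(sim: _PatientSim, cfg: SimulationConfig, rng, study_start: date) -> None:
    for prob, codes in (
        (cfg.peptic_ulcer_history_prob, ("D85", "D86")),
        (cfg.gout_history_prob, ("T92",)),
        (cfg.bleeding_disorder_history_prob, ("B83",)),
    ):
        if rng.random() < prob:
            code = codes[int(rng.integers(len(codes)))]
            back = int(rng.integers(365, 15 * 365))
            sim.dx.append((code, study_start - timedelta(days=back)))


def _simulate_patient_events(
    sim: _PatientSim, cfg: SimulationConfig, cc: CriteriaConfig, rng, D: int
) -> list[tuple]:
    """Thin a day-resolution Bernoulli process under the planted hazard.

    Returns (day_idx, channel, code, text) tuples; updates labels when
    an ulcer-coded event creates new peptic-ulcer history.
    """
    study_start = cfg.study_start
    lam0 = cfg.baseline_hazard_per_day
    if lam0 <= 0:
        return []
    n = sim.exit - sim.entry + 1
    if n <= 0:
        return []

    def day_probs():
        sl = slice(sim.entry, sim.exit + 1)
        ages = _age_day_array(sim, D, study_start)[sl]
        lp = (
            cfg.log_hr_exposure * sim.combined[sl]
            + cfg.log_hr_ppi * sim.ppi[sl]
            + cfg.log_hr_age_per_year * (ages - cfg.age_ref_years)
            + cfg.log_hr_male * (1.0 if sim.sex == "M" else 0.0)
        )
        return -np.expm1(-lam0 * np.exp(lp))

    p = day_probs()
    u = rng.random(n)
    events = []
    i = 0
    ulcer_codes = frozenset({"D85", "D86"})
    while i < n:
        cand = np.nonzero(u[i:] < p[i:])[0]
        if cand.size == 0:
            break
        j = i + int(cand[0])
        day_idx = sim.entry + j
        ev_date = study_start + timedelta(days=day_idx)
        if rng.random() < cfg.freetext_only_bleeding_prob:
            channel = "free_text"
            code = ("A99", "D99", "")[int(rng.integers(3))]
            text = _BLEEDING_NOTE_TEMPLATES[int(rng.integers(len(_BLEEDING_NOTE_TEMPLATES)))]
        else:
            channel = "icpc"
            w = np.array(_EVENT_ICPC_WEIGHTS, dtype=float)
            code = _EVENT_ICPC[int(rng.choice(4, p=w / w.sum()))]
            text = ""
        events.append((day_idx, channel, code, text))
        if channel == "icpc":
            had_history = any(c in ulcer_codes for c, d in sim.dx if d <= ev_date)
            sim.dx.append((code, ev_date))
            if code in ulcer_codes and not had_history:
                # new ulcer history switches on the ulcer-history
                # criteria from the event day onward
                _update_ulcer_labels(sim, cc, D, study_start)
                p = day_probs()
        i = j + cfg.min_interevent_gap_days
        if i >= n:
            break
        u[i:] = rng.random(n - i)
    return events


def generate_cohort(
    config: Optional[SimulationConfig] = None,
    criteria_config: Optional[CriteriaConfig] = None,
) -> tuple[Cohort, GroundTruth]:
    """Simulate a complete cohort plus its ground truth.

    All randomness derives from ``config.seed``; re-running with the
    same configuration reproduces the tables byte-for-byte.
    """
    cfg = config or SimulationConfig()
    cc = criteria_config or CriteriaConfig()
    rng = np.random.default_rng(cfg.seed)
    study_start, study_end = cfg.study_start, cfg.study_end
    if study_start >= study_end:
        raise ValueError("study_start must precede study_end")
    D = (study_end - study_start).days + 1
    exit_rate_day = cfg.exit_rate_per_year / 365.25

    pat_rows, rx_rows, dx_rows, note_rows = [], [], [], []
    part1: dict[str, dict] = {code: {} for code in cc.criteria}
    combined: dict[str, list] = {}
    ppi_truth: dict[str, list] = {}
    all_events = []

    width = max(5, len(str(max(cfg.n_patients, 1))))
    for k in range(cfg.n_patients):
        pid = f"P{k:0{width}d}"
        while True:
            age0 = rng.uniform(cfg.age_at_start_min, cfg.age_at_start_max)
            birth = study_start - timedelta(days=int(round(age0 * 365.25)))
            b65 = anniversary_in_year(birth, birth.year + 65)
            if b65 <= study_end:  # must turn 65 within the window
                break
        sex = "F" if rng.random() < cfg.female_prob else "M"
        entry_date = max(study_start, b65)
        entry = (entry_date - study_start).days
        if exit_rate_day > 0:
            t_out = int(rng.exponential(1.0 / exit_rate_day))
        else:
            t_out = D
        exit_idx = min(entry + t_out, D - 1)
        if exit_idx >= D - 1 or entry + t_out >= D - 1:
            exit_reason = "study_end"
        else:
            exit_reason = (
                "death" if rng.random() < cfg.death_fraction_of_exits else "left_practice"
            )
        sim = _PatientSim(pid, birth, sex, entry, exit_idx, exit_reason)
        _generate_history(sim, cfg, rng, study_start)
        _generate_prescriptions(sim, cfg, rng, D)
        _relabel(sim, cc, D, study_start)

        events = _simulate_patient_events(sim, cfg, cc, rng, D)

        exit_date = study_start + timedelta(days=sim.exit)
        pat_rows.append((pid, birth, sex, entry_date, exit_date, sim.exit_reason))
        for atc, cls, s, e, dose in sim.rx:
            rx_rows.append(
                (pid, atc, study_start + timedelta(days=s), study_start + timedelta(days=e), dose)
            )
        for code, d in sim.dx:
            dx_rows.append((pid, code, d))
        for day_idx, channel, code, text in events:
            ev_date = study_start + timedelta(days=day_idx)
            if channel == "free_text":
                note_rows.append((pid, ev_date, code, text))
            all_events.append((pid, ev_date, channel, code))
        # distractor / benign notes
        if rng.random() < cfg.distractor_note_prob and sim.exit > sim.entry:
            text, code = _DISTRACTOR_TEMPLATES[int(rng.integers(len(_DISTRACTOR_TEMPLATES)))]
            d = study_start + timedelta(days=int(rng.integers(sim.entry, sim.exit + 1)))
            note_rows.append((pid, d, code, text))
        if rng.random() < cfg.benign_note_prob and sim.exit > sim.entry:
            text = _BENIGN_NOTE_TEMPLATES[int(rng.integers(len(_BENIGN_NOTE_TEMPLATES)))]
            d = study_start + timedelta(days=int(rng.integers(sim.entry, sim.exit + 1)))
            note_rows.append((pid, d, "", text))

        for code, arr in sim.labels.items():
            if arr.any():
                part1[code][pid] = _array_to_intervals(arr, study_start)
        if sim.combined.any():
            combined[pid] = _array_to_intervals(sim.combined, study_start)
        if sim.ppi.any():
            ppi_truth[pid] = _array_to_intervals(sim.ppi, study_start)

    cohort = Cohort(
        patients=pd.DataFrame(
            pat_rows,
            columns=["patient_id", "birth_date", "sex", "entry_date", "exit_date", "exit_reason"],
        ),
        prescriptions=pd.DataFrame(
            rx_rows, columns=["patient_id", "atc_code", "start_date", "end_date", "daily_dose_mg"]
        ),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "icpc_code", "date"]),
        notes=pd.DataFrame(note_rows, columns=["patient_id", "date", "icpc_code", "text"]),
    )
    truth = GroundTruth(
        part1_intervals=part1,
        combined_intervals=combined,
        ppi_intervals=ppi_truth,
        events=all_events,
        true_params={
            "baseline_hazard_per_day": cfg.baseline_hazard_per_day,
            "log_hr_exposure": cfg.log_hr_exposure,
            "log_hr_ppi": cfg.log_hr_ppi,
            "log_hr_age_per_year": cfg.log_hr_age_per_year,
            "log_hr_male": cfg.log_hr_male,
            "seed": cfg.seed,
        },
    )
    return cohort, truth


def simulate_bleedings(
    cohort: Cohort,
    exposure_labels: Mapping[str, Sequence[DateInterval]],
    config: Optional[SimulationConfig] = None,
    rng=None,
) -> list[tuple]:
    """Standalone event simulation on externally supplied exposure labels.

    Draws bleeding times from the day-resolution proportional-hazards
    model given per-patient exposure intervals, without the ulcer-code
    label feedback that :func:`generate_cohort` applies (labels are
    taken as fixed).  Returns (patient_id, date, channel, code) tuples.
    Useful for calibration checks of the event process itself.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    study_start = cfg.study_start
    D = (cfg.study_end - study_start).days + 1
    out = []
    if cfg.baseline_hazard_per_day <= 0:
        return out
    for r in cohort.patients.itertuples(index=False):
        entry = (r.entry_date - study_start).days
        exit_idx = (r.exit_date - study_start).days
        sim = _PatientSim(r.patient_id, r.birth_date, r.sex, entry, exit_idx, r.exit_reason)
        lab = np.zeros(D, dtype=bool)
        for iv in exposure_labels.get(r.patient_id, []):
            a = (iv.start - study_start).days
            b = (iv.end - study_start).days
            lab[max(a, 0) : min(b, D - 1) + 1] = True
        sim.combined = lab
        sim.ppi = np.zeros(D, dtype=bool)
        # fixed labels: disable the ulcer feedback by pre-seeding history
        sim.dx = [("D85", date(1900, 1, 1))]
        events = _simulate_patient_events(sim, cfg, CriteriaConfig(), rng, D)
        for day_idx, channel, code, _ in events:
            out.append((r.patient_id, study_start + timedelta(days=day_idx), channel, code))
    return out


def write_simulation_outputs(
    cohort: Cohort, truth: GroundTruth, cfg: SimulationConfig, outdir
) -> dict:
    """Write the four cohort CSVs, ground-truth CSVs and a run manifest."""
    from pathlib import Path

    from .ehr_model import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {t: outdir / f"{t}.csv" for t in ("patients", "prescriptions", "diagnoses", "notes")}
    write_cohort(cohort, paths["patients"], paths["prescriptions"], paths["diagnoses"], paths["notes"])

    gt_rows = [
        (code, pid, iv.start.isoformat(), iv.end.isoformat())
        for code, by_pid in truth.part1_intervals.items()
        for pid, ivs in sorted(by_pid.items())
        for iv in ivs
    ]
    pd.DataFrame(gt_rows, columns=["criterion_code", "patient_id", "start", "end"]).to_csv(
        outdir / "ground_truth_exposure.csv", index=False
    )
    pd.DataFrame(
        [(pid, d.isoformat(), ch, code) for pid, d, ch, code in truth.events],
        columns=["patient_id", "date", "channel", "code"],
    ).to_csv(outdir / "ground_truth_events.csv", index=False)
    manifest = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "study_start": cfg.study_start.isoformat(),
        "study_end": cfg.study_end.isoformat(),
        "true_params": {k: float(v) for k, v in truth.true_params.items()},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {str(k): str(v) for k, v in paths.items()}
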