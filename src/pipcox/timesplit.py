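"""Counting-process construction: splitting follow-up into sequences.

Exposure to a PIM or PPO switches on and off as prescriptions start and
stop, so exposure enters the Cox model as a time-dependent covariate.
Each participant's follow-up is divided into sequences — one row per
maximal segment on which every covariate is constant — in the standard
``(t_start, t_stop]`` counting-process layout with delayed entry (a
participant contributes to risk sets only from their entry day onward).

The time axis is days since the study start.  A calendar day ``d``
corresponds to the unit interval ending at ``t = (d - study_start).days
+ 1``; a bleeding on day ``d`` terminates the row whose ``t_stop`` is
that value.  A participant with no exposure and no event yields exactly
one row; one bleeding splits their time into two rows; a patient whose
exposure changed every day of the full study window would reach the
theoretical maximum of ``(window days) - 1`` sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import pandas as pd

from .bleeding_detector import BleedingEvent
from .criteria_engine import (
    CRITERION_CODES,
    START_CODES,
    STOPP_CODES,
    CriteriaConfig,
    PIPRecord,
    evaluate_cohort_part2,
)
from .ehr_model import Cohort, DateInterval, PatientRecord, STUDY_START, STUDY_END, compute_age
from .episode_merge import intersect_intervals, merge_intervals

__all__ = [
    "CountingProcessRow",
    "ModelDataset",
    "ModelSpec",
    "build_rows",
    "assemble_model_dataset",
    "max_sequences",
    "GROUPS",
]

#: Composite exposure groups usable in place of a single criterion code.
GROUPS = ("ALL_COMBINED", "STARTS_COMBINED", "STOPPS_COMBINED", "ALL_STARTS")


@dataclass(frozen=True)
class CountingProcessRow:
    cluster_id: str
    t_start: int
    t_stop: int
    event: int
    covariates: Mapping[str, float]


@dataclass
class ModelDataset:
    """Rows plus ordered covariate names for one model fit."""

    rows: list
    covariate_names: list
    model_tag: str

    def to_frame(self) -> pd.DataFrame:
        data = [
            {
                "cluster_id": r.cluster_id,
                "t_start": r.t_start,
                "t_stop": r.t_stop,
                "event": r.event,
                **{k: r.covariates[k] for k in self.covariate_names},
            }
            for r in self.rows
        ]
        cols = ["cluster_id", "t_start", "t_stop", "event"] + list(self.covariate_names)
        return pd.DataFrame(data, columns=cols)

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.rows)


@dataclass(frozen=True)
class ModelSpec:
    """Which exposure, which model form, which population.

    ``criterion`` is a criterion code or a composite group; ``form`` is
    one of ``multivariable`` (exposure + age + sex), ``adjusted`` (adds
    the merged remaining PIMs/PPOs as a confounder),
    ``part2_multivariable`` (harmful medication as-is + age + sex) or
    ``part2_interaction`` (medication, PPI and medication-by-PPI).
    """

    criterion: str
    form: str = "multivariable"
    population: str = "full"  # full | bleeding_subpopulation

    def __post_init__(self):
        if self.form not in {"multivariable", "adjusted", "part2_multivariable", "part2_interaction"}:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.criterion not in CRITERION_CODES + GROUPS:
            raise ValueError(f"unknown criterion/group {self.criterion!r}")
        if self.form == "adjusted" and self.criterion in GROUPS:
            raise ValueError("the adjusted form applies to individual criteria only")
        if self.form.startswith("part2") and self.criterion not in START_CODES + ("ALL_STARTS",):
            raise ValueError(
                f"part-2 forms need a START criterion or ALL_STARTS, got {self.criterion}"
            )

    @property
    def tag(self) -> str:
        return f"{self.criterion}:{self.form}" + (
            "" if self.population == "full" else f":{self.population}"
        )


def max_sequences(study_start: date = STUDY_START, study_end: date = STUDY_END) -> int:
    """Theoretical maximum sequences for a full-window participant.

    With exposure flipping every day, each of the window's interior day
    boundaries can start a new sequence: window day-count minus one.
    """
    return (study_end - study_start).days + 1 - 1


def build_rows(
    patient: PatientRecord,
    exposure_interval_sets: Mapping[str, Sequence[DateInterval]],
    events: Sequence[date],
    sex_male: Optional[int] = None,
    study_start: date = STUDY_START,
    split_at_birthdays: bool = False,
) -> list[CountingProcessRow]:
    """Counting-process rows for one participant.

    Cut points are the entry/exit boundaries, every exposure interval
    start and (end + 1 day), and every event day; one row is emitted
    per resulting segment.  A participant with no exposure and no
    event therefore yields exactly one sequence, and one bleeding
    splits their time at the event day.  Each named exposure flag is 1
    on segments lying inside that interval set; ``event`` is 1 on the
    row ending at an event day.  Follow-up continues after an event
    (participants remain at risk for recurrent bleedings).

    Age in completed years is evaluated at each row's first day.  With
    ``split_at_birthdays`` (the model-assembly default) rows are
    additionally cut at birthday anniversaries, keeping the age
    covariate exactly constant within rows instead of frozen at the
    value a possibly years-long unexposed row started with; this
    refinement leaves risk sets and the partial likelihood otherwise
    unchanged.  An exposure set named ``age`` or ``sex`` is rejected to
    avoid collision with the built-in covariates.
    """
    for name in exposure_interval_sets:
        if name in ("age", "sex"):
            raise ValueError(f"exposure set name {name!r} collides with a built-in covariate")

    def t_of_day_end(d: date) -> int:
        return (d - study_start).days + 1

    t_entry = (patient.entry_date - study_start).days
    t_exit = t_of_day_end(patient.exit_date)

    cuts = {t_entry, t_exit}
    if split_at_birthdays:
        from .ehr_model import anniversary_in_year

        for year in range(patient.entry_date.year, patient.exit_date.year + 1):
            ann = (anniversary_in_year(patient.birth_date, year) - study_start).days
            if t_entry < ann < t_exit:
                cuts.add(ann)
    for intervals in exposure_interval_sets.values():
        for iv in intervals:
            cuts.add(max(t_entry, (iv.start - study_start).days))
            cuts.add(min(t_exit, t_of_day_end(iv.end)))
    event_ts = set()
    for d in events:
        if not (patient.entry_date <= d <= patient.exit_date):
            raise ValueError(
                f"event {d} outside observation window "
                f"[{patient.entry_date}, {patient.exit_date}] of {patient.patient_id}"
            )
        event_ts.add(t_of_day_end(d))
    cuts |= event_ts
    grid = sorted(t for t in cuts if t_entry <= t <= t_exit)

    sex = sex_male if sex_male is not None else (1 if patient.sex == "M" else 0)
    rows = []
    for a, b in zip(grid[:-1], grid[1:]):
        first_day = study_start + timedelta(days=a)
        covs = {"age": float(compute_age(patient.birth_date, first_day)), "sex": float(sex)}
        for name, intervals in exposure_interval_sets.items():
            covs[name] = float(any(iv.contains(first_day) for iv in intervals))
        rows.append(
            CountingProcessRow(
                cluster_id=patient.patient_id,
                t_start=a,
                t_stop=b,
                event=int(b in event_ts),
                covariates=covs,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Dataset assembly per model form


def _records_by_patient(
    pip_records: Sequence[PIPRecord], codes: Optional[set] = None
) -> dict[str, list[DateInterval]]:
    out: dict[str, list[DateInterval]] = {}
    for rec in pip_records:
        if codes is not None and rec.criterion_code not in codes:
            continue
        out.setdefault(rec.patient_id, []).append(rec.interval)
    return {pid: merge_intervals(ivs) for pid, ivs in out.items()}


def _clip_all(intervals: Sequence[DateInterval], window: DateInterval) -> list[DateInterval]:
    return [iv2 for iv in intervals if (iv2 := iv.clip(window)) is not None]


def assemble_model_dataset(
    cohort: Cohort,
    pip_records: Sequence[PIPRecord],
    bleedings: Sequence[BleedingEvent],
    model_spec: ModelSpec,
    config: Optional[CriteriaConfig] = None,
    part2_intervals: Optional[Mapping[str, Mapping[str, list]]] = None,
    study_start: date = STUDY_START,
    split_at_birthdays: bool = True,
) -> ModelDataset:
    """Build the counting-process dataset for one model specification.

    Part-1 forms consume the PIP records (combined groups use the
    merged union of the relevant criteria; the adjusted form adds the
    merged remaining criteria as ``pip_other``).  Part-2 forms derive
    medication/PPI intervals from the cohort via the criteria engine
    (or from ``part2_intervals`` when supplied), with the product
    covariate set on segments covered by both.  The
    ``bleeding_subpopulation`` filter keeps only participants with at
    least one detected bleeding.
    """
    spec = model_spec
    events_by_pid: dict[str, list[date]] = {}
    for ev in bleedings:
        events_by_pid.setdefault(ev.patient_id, []).append(ev.date)

    patients = cohort.patient_records()
    if spec.population == "bleeding_subpopulation":
        patients = [p for p in patients if p.patient_id in events_by_pid]

    if spec.form in ("multivariable", "adjusted"):
        if spec.criterion == "ALL_COMBINED":
            target = _records_by_patient(pip_records)
        elif spec.criterion in ("STARTS_COMBINED", "ALL_STARTS"):
            target = _records_by_patient(pip_records, set(START_CODES))
        elif spec.criterion == "STOPPS_COMBINED":
            target = _records_by_patient(pip_records, set(STOPP_CODES))
        else:
            target = _records_by_patient(pip_records, {spec.criterion})
        covariate_names = ["pip", "age", "sex"]
        other = None
        if spec.form == "adjusted":
            other = _records_by_patient(
                pip_records, set(CRITERION_CODES) - {spec.criterion}
            )
            covariate_names = ["pip", "pip_other", "age", "sex"]
        rows = []
        for p in patients:
            sets = {"pip": target.get(p.patient_id, [])}
            if other is not None:
                sets["pip_other"] = other.get(p.patient_id, [])
            rows.extend(
                build_rows(p, sets, events_by_pid.get(p.patient_id, []), study_start=study_start,
                           split_at_birthdays=split_at_birthdays)
            )
        return ModelDataset(rows, covariate_names, spec.tag)

    # --- part 2 forms ---
    codes = list(START_CODES) if spec.criterion == "ALL_STARTS" else [spec.criterion]
    med_by_pid: dict[str, list[DateInterval]] = {}
    ppi_by_pid: dict[str, list[DateInterval]] = {}
    for code in codes:
        data = (
            part2_intervals.get(code)
            if part2_intervals is not None
            else evaluate_cohort_part2(cohort, code, config)
        )
        for pid, rec in (data or {}).items():
            med_by_pid.setdefault(pid, []).extend(rec["med_intervals"])
            ppi_by_pid.setdefault(pid, []).extend(rec["ppi_intervals"])
    med_by_pid = {pid: merge_intervals(ivs) for pid, ivs in med_by_pid.items()}
    ppi_by_pid = {pid: merge_intervals(ivs) for pid, ivs in ppi_by_pid.items()}

    rows = []
    if spec.form == "part2_multivariable":
        covariate_names = ["meds", "age", "sex"]
        for p in patients:
            sets = {"meds": med_by_pid.get(p.patient_id, [])}
            rows.extend(
                build_rows(p, sets, events_by_pid.get(p.patient_id, []), study_start=study_start,
                           split_at_birthdays=split_at_birthdays)
            )
    else:  # part2_interaction
        covariate_names = ["meds", "ppi", "meds_x_ppi", "age", "sex"]
        for p in patients:
            med = med_by_pid.get(p.patient_id, [])
            ppi = ppi_by_pid.get(p.patient_id, [])
            sets = {
                "meds": med,
                "ppi": ppi,
                "meds_x_ppi": intersect_intervals(med, ppi),
            }
            rows.extend(
                build_rows(p, sets, events_by_pid.get(p.patient_id, []), study_start=study_start,
                           split_at_birthdays=split_at_birthdays)
            )
    return ModelDataset(rows, covariate_names, spec.tag)
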