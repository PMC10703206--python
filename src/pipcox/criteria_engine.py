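"""Rule engine for the gastrointestinal-bleeding STOPP/START criteria.

Three STOPP criteria (potentially inappropriate medications, PIM) and six
START criteria (potential prescribing omissions, PPO) are evaluated over
merged drug episodes and coded diagnoses, producing day-resolved
intervals of nonadherence (PIP records).  Two exposure semantics exist:

* **part 1** (nonadherence): for the START criteria, days on which a
  proton pump inhibitor (PPI) is co-prescribed comply with the criterion
  and are removed from the exposure interval; STOPP intervals are used
  as-is.
* **part 2** (harmful medication): the START medication-plus-patient
  -characteristics combination is kept *as is*, and the PPI episodes are
  returned separately so the model can estimate main and interaction
  effects of gastroprotection.

Criterion definitions (drug classes, age bounds, dose thresholds,
history codes) ship as an overridable default configuration; ATC codes
map to drug classes by longest-prefix match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .ehr_model import (
    Cohort,
    DateInterval,
    PatientRecord,
    Prescription,
    anniversary_in_year,
)
from .episode_merge import (
    DrugEpisode,
    GapDayTable,
    extend_and_merge,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "CRITERION_CODES",
    "STOPP_CODES",
    "START_CODES",
    "CriterionSpec",
    "PIPRecord",
    "CriteriaConfig",
    "default_criteria",
    "DEFAULT_ATC_CLASS_MAP",
    "classify_atc",
    "episodes_for_criterion",
    "raw_criterion_intervals",
    "part1_pip_records",
    "part2_med_records",
    "merge_other_pips",
    "evaluate_cohort_part1",
    "evaluate_cohort_part2",
    "pip_records_to_frame",
]

STOPP_CODES = ("STOPP_A9", "STOPP_A15", "STOPP_E5")
START_CODES = (
    "START_D2A",
    "START_D2B",
    "START_D2C",
    "START_D3A",
    "START_D3B",
    "START_D3C",
)
CRITERION_CODES = STOPP_CODES + START_CODES

#: ATC prefix -> drug class, longest prefix wins.  Plain acetylsalicylic
#: acid (B01AC06 antithrombotic, N02BA01 analgesic) and carbasalate
#: calcium (B01AC08) form the ASA/ECC class and are carved out of the
#: broader platelet-aggregation-inhibitor group B01AC.
DEFAULT_ATC_CLASS_MAP: Mapping[str, str] = {
    "A02BC": "PPI",
    "M01A": "NSAID",
    "B01AC06": "ASA_ECC",
    "B01AC08": "ASA_ECC",
    "N02BA01": "ASA_ECC",
    "B01AC": "platelet_inhibitor",
    "B01AA": "oral_anticoagulant",
    "B01AE": "oral_anticoagulant",
    "B01AF": "oral_anticoagulant",
    "H02AB": "corticosteroid",
    "N06AB": "SSRI",
}


def classify_atc(atc_code: str, atc_map: Mapping[str, str] = DEFAULT_ATC_CLASS_MAP) -> Optional[str]:
    """Drug class for an ATC code by longest matching prefix, else None."""
    best = None
    best_len = -1
    for prefix, cls in atc_map.items():
        if atc_code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = cls, len(prefix)
    return best


@dataclass(frozen=True)
class CriterionSpec:
    """One STOPP or START criterion as machine-checkable conditions.

    A day is in the criterion's raw exposure set when *all* configured
    conditions hold: a primary-class episode is active (with dose above
    threshold and episode duration beyond ``min_duration_days`` where
    required), a companion-class episode is concurrently active, a
    qualifying diagnosis exists on or before the day, and the patient's
    completed age is within bounds.
    """

    code: str
    primary_drug_classes: frozenset
    companion_drug_classes: frozenset = frozenset()
    required_history_icpc: frozenset = frozenset()
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    #: ATC prefix -> mg/day threshold (strictly greater qualifies).
    dose_thresholds_mg: Optional[Mapping[str, float]] = None
    min_duration_days: Optional[int] = None
    ppi_protective: bool = False

    @property
    def is_start(self) -> bool:
        return self.code.startswith("START")


def default_criteria() -> dict[str, CriterionSpec]:
    """The nine gastrointestinal-bleeding criteria.

    Age bounds are inclusive at the printed threshold (">70" admits a
    70-year-old): the published worked example applies both the ">70"
    and the "60-70" NSAID criteria to a 70-year-old patient, which
    forces this reading.  History ICPC sets (peptic ulcer D85/D86,
    bleeding disorder B83, gout T92) are configurable because the source
    guideline's full code lists are not printed.
    """
    return {
        "STOPP_A9": CriterionSpec(
            code="STOPP_A9",
            primary_drug_classes=frozenset({"ASA_ECC"}),
            # ASA > 160 mg/day; effervescent calcium carbasalate > 200 mg/day
            dose_thresholds_mg={"B01AC06": 160.0, "N02BA01": 160.0, "B01AC08": 200.0},
        ),
        "STOPP_A15": CriterionSpec(
            code="STOPP_A15",
            primary_drug_classes=frozenset({"platelet_inhibitor", "oral_anticoagulant"}),
            required_history_icpc=frozenset({"B83"}),
        ),
        "STOPP_E5": CriterionSpec(
            code="STOPP_E5",
            primary_drug_classes=frozenset({"NSAID"}),
            required_history_icpc=frozenset({"T92"}),
            min_duration_days=90,  # ">3 months" of continuous NSAID coverage
        ),
        "START_D2A": CriterionSpec(
            code="START_D2A",
            primary_drug_classes=frozenset({"NSAID"}),
            required_history_icpc=frozenset({"D85", "D86"}),
            ppi_protective=True,
        ),
        "START_D2B": CriterionSpec(
            code="START_D2B",
            primary_drug_classes=frozenset({"NSAID"}),
            age_min=70,
            ppi_protective=True,
        ),
        "START_D2C": CriterionSpec(
            code="START_D2C",
            primary_drug_classes=frozenset({"NSAID"}),
            companion_drug_classes=frozenset(
                {"oral_anticoagulant", "corticosteroid", "SSRI", "ASA_ECC", "platelet_inhibitor"}
            ),
            age_min=60,
            age_max=70,
            ppi_protective=True,
        ),
        "START_D3A": CriterionSpec(
            code="START_D3A",
            primary_drug_classes=frozenset({"ASA_ECC"}),
            required_history_icpc=frozenset({"D85", "D86"}),
            age_min=60,
            ppi_protective=True,
        ),
        "START_D3B": CriterionSpec(
            code="START_D3B",
            primary_drug_classes=frozenset({"ASA_ECC"}),
            companion_drug_classes=frozenset({"oral_anticoagulant", "corticosteroid", "SSRI"}),
            age_min=70,
            ppi_protective=True,
        ),
        "START_D3C": CriterionSpec(
            code="START_D3C",
            primary_drug_classes=frozenset({"ASA_ECC"}),
            age_min=80,
            ppi_protective=True,
        ),
    }


@dataclass(frozen=True)
class PIPRecord:
    """One interval of nonadherence to one criterion for one patient."""

    patient_id: str
    criterion_code: str
    interval: DateInterval


@dataclass
class CriteriaConfig:
    """Engine configuration: criteria, ATC mapping, gap days, age mode."""

    criteria: dict = field(default_factory=default_criteria)
    atc_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ATC_CLASS_MAP))
    gap_table: GapDayTable = field(default_factory=GapDayTable)
    #: when True, ">70" is read strictly (age >= 71) instead of the
    #: default inclusive reading (age >= 70).
    strict_age_bounds: bool = False

    @classmethod
    def from_yaml(cls, path) -> "CriteriaConfig":
        """Load overrides from a YAML file (missing keys keep defaults)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "atc_map" in raw:
            cfg.atc_map = dict(raw["atc_map"])
        if "strict_age_bounds" in raw:
            cfg.strict_age_bounds = bool(raw["strict_age_bounds"])
        if "gap_days" in raw:
            gd = raw["gap_days"]
            cfg.gap_table = GapDayTable(
                class_defaults=dict(gd.get("class_defaults", GapDayTable().class_defaults)),
                overrides={
                    (k.split("/")[0], k.split("/")[1]): v
                    for k, v in gd.get("overrides", {}).items()
                },
            )
        for code, block in raw.get("criteria", {}).items():
            base = cfg.criteria.get(code)
            fields = dict(
                primary_drug_classes=frozenset(block.get("primary_drug_classes", base.primary_drug_classes if base else ())),
                companion_drug_classes=frozenset(block.get("companion_drug_classes", base.companion_drug_classes if base else ())),
                required_history_icpc=frozenset(block.get("required_history_icpc", base.required_history_icpc if base else ())),
                age_min=block.get("age_min", base.age_min if base else None),
                age_max=block.get("age_max", base.age_max if base else None),
                dose_thresholds_mg=block.get("dose_thresholds_mg", base.dose_thresholds_mg if base else None),
                min_duration_days=block.get("min_duration_days", base.min_duration_days if base else None),
                ppi_protective=block.get("ppi_protective", base.ppi_protective if base else code.startswith("START")),
            )
            cfg.criteria[code] = CriterionSpec(code=code, **fields)
        return cfg


# ---------------------------------------------------------------------------
# Episode construction per criterion


def _dose_qualifies(p: Prescription, thresholds: Mapping[str, float]) -> bool:
    best, best_len = None, -1
    for prefix, thr in thresholds.items():
        if p.atc_code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = thr, len(prefix)
    if best is None:
        return False
    dose = p.daily_dose_mg
    if dose is None or dose != dose:
        return False
    return dose > best


def episodes_for_criterion(
    prescriptions: Sequence[Prescription],
    spec: CriterionSpec,
    config: CriteriaConfig,
    include_ppi: bool = True,
) -> dict[str, list[DrugEpisode]]:
    """Build merged drug episodes for every class a criterion needs.

    Gap days are looked up per (criterion, class).  For dose-threshold
    criteria only scripts exceeding the threshold enter the primary
    episodes, so merged episodes represent continuous supra-threshold
    use.  PPI episodes are built for START criteria (for protection
    subtraction or part-2 covariates).
    """
    classes = set(spec.primary_drug_classes) | set(spec.companion_drug_classes)
    if include_ppi and spec.is_start:
        classes.add("PPI")
    by_class: dict[str, list[Prescription]] = {c: [] for c in classes}
    for p in prescriptions:
        cls = classify_atc(p.atc_code, config.atc_map)
        if cls not in by_class:
            continue
        if (
            cls in spec.primary_drug_classes
            and spec.dose_thresholds_mg is not None
            and not _dose_qualifies(p, spec.dose_thresholds_mg)
        ):
            continue
        by_class[cls].append(p)
    out = {}
    for cls, plist in by_class.items():
        gap = config.gap_table.gap(spec.code, cls)
        out[cls] = extend_and_merge(plist, gap, drug_class=cls) if plist else []
    return out


# ---------------------------------------------------------------------------
# Raw criterion evaluation


def _age_interval(
    patient: PatientRecord, spec: CriterionSpec, strict: bool
) -> Optional[list[DateInterval]]:
    """Calendar days on which the age condition holds.

    None means the criterion has no age bounds; an empty list means the
    condition can never hold for this patient.
    """
    if spec.age_min is None and spec.age_max is None:
        return None
    lo_age = spec.age_min
    hi_age = spec.age_max
    if strict and lo_age is not None:
        lo_age += 1
    start = date.min
    end = date.max - timedelta(days=1)
    if lo_age is not None:
        start = anniversary_in_year(patient.birth_date, patient.birth_date.year + lo_age)
    if hi_age is not None:
        # condition fails from the (hi_age+1)-th anniversary onward
        end = anniversary_in_year(
            patient.birth_date, patient.birth_date.year + hi_age + 1
        ) - timedelta(days=1)
    if start > end:
        return []
    return [DateInterval(start, end)]


def raw_criterion_intervals(
    spec: CriterionSpec,
    patient: PatientRecord,
    episodes: Mapping[str, Sequence[DrugEpisode]],
    diagnoses: Sequence,
    config: Optional[CriteriaConfig] = None,
) -> list[DateInterval]:
    """Day set on which every condition of the criterion holds.

    ``episodes`` maps drug class to merged episodes built for this
    criterion (see :func:`episodes_for_criterion`); ``diagnoses`` is the
    patient's diagnosis events.  Age-boundary days split intervals at
    birthday anniversaries (the criterion can switch on or off
    mid-episode).  The result is *not* clipped to the observation
    window; clipping happens in record construction.
    """
    config = config or CriteriaConfig()
    if spec.code not in CRITERION_CODES:
        raise ValueError(f"unknown criterion code {spec.code!r}")

    primary: list[DateInterval] = []
    for cls in spec.primary_drug_classes:
        for ep in episodes.get(cls, []):
            iv = ep.interval
            if spec.min_duration_days:
                qual_start = iv.start + timedelta(days=spec.min_duration_days)
                if qual_start > iv.end:
                    continue
                iv = DateInterval(qual_start, iv.end)
            primary.append(iv)
    result = merge_intervals(primary)
    if not result:
        return []

    if spec.companion_drug_classes:
        companions = [
            ep.interval
            for cls in spec.companion_drug_classes
            for ep in episodes.get(cls, [])
        ]
        result = intersect_intervals(result, merge_intervals(companions))
        if not result:
            return []

    if spec.required_history_icpc:
        dates = [d.date for d in diagnoses if d.icpc_code in spec.required_history_icpc]
        if not dates:
            return []
        first = min(dates)
        result = intersect_intervals(result, [DateInterval(first, date.max - timedelta(days=1))])
        if not result:
            return []

    age_iv = _age_interval(patient, spec, config.strict_age_bounds)
    if age_iv is not None:
        result = intersect_intervals(result, age_iv)
    return result


def part1_pip_records(
    spec: CriterionSpec,
    patient: PatientRecord,
    episodes: Mapping[str, Sequence[DrugEpisode]],
    diagnoses: Sequence,
    config: Optional[CriteriaConfig] = None,
) -> list[PIPRecord]:
    """Nonadherence intervals (part-1 semantics) for one criterion.

    START intervals lose the days on which a PPI episode is active (a
    concomitant PPI complies with the criterion); STOPP intervals are
    kept as-is.  Records are clipped to the observation window and
    same-criterion overlaps merged.
    """
    raw = raw_criterion_intervals(spec, patient, episodes, diagnoses, config)
    if spec.is_start and spec.ppi_protective:
        ppi = [ep.interval for ep in episodes.get("PPI", [])]
        raw = subtract_intervals(raw, ppi)
    clipped = [iv2 for iv in raw if (iv2 := iv.clip(patient.window)) is not None]
    return [
        PIPRecord(patient.patient_id, spec.code, iv) for iv in merge_intervals(clipped)
    ]


def part2_med_records(
    spec: CriterionSpec,
    patient: PatientRecord,
    episodes: Mapping[str, Sequence[DrugEpisode]],
    diagnoses: Sequence,
    config: Optional[CriteriaConfig] = None,
) -> dict[str, list[DateInterval]]:
    """Part-2 exposure: harmful-medication intervals as-is, plus PPI.

    Only defined for START criteria.  Returns ``med_intervals`` (the raw
    criterion day set, no PPI subtraction) and ``ppi_intervals``, both
    clipped to the observation window, for building the medication, PPI
    and medication-by-PPI covariates.
    """
    if not spec.is_start:
        raise ValueError(f"part-2 semantics only apply to START criteria, got {spec.code}")
    raw = raw_criterion_intervals(spec, patient, episodes, diagnoses, config)
    med = [iv2 for iv in raw if (iv2 := iv.clip(patient.window)) is not None]
    ppi = [
        iv2
        for ep in episodes.get("PPI", [])
        if (iv2 := ep.interval.clip(patient.window)) is not None
    ]
    return {"med_intervals": merge_intervals(med), "ppi_intervals": merge_intervals(ppi)}


def merge_other_pips(
    all_pip_records: Sequence[PIPRecord], excluded_criterion: str
) -> list[PIPRecord]:
    """Confounder intervals: union of all records of the *other* criteria.

    When one criterion is analysed, every remaining PIM/PPO record of
    the same patient is merged into ``OTHER``-coded intervals.
    """
    by_patient: dict[str, list[DateInterval]] = {}
    for rec in all_pip_records:
        if rec.criterion_code == excluded_criterion:
            continue
        by_patient.setdefault(rec.patient_id, []).append(rec.interval)
    out = []
    for pid in sorted(by_patient):
        for iv in merge_intervals(by_patient[pid]):
            out.append(PIPRecord(pid, "OTHER", iv))
    return out


# ---------------------------------------------------------------------------
# Cohort-level drivers


def _patient_prescriptions(df: pd.DataFrame) -> list[Prescription]:
    return [
        Prescription(r.patient_id, r.atc_code, r.start_date, r.end_date, r.daily_dose_mg)
        for r in df.itertuples(index=False)
    ]


def _patient_diagnoses(df: pd.DataFrame) -> list:
    from .ehr_model import DiagnosisEvent

    return [DiagnosisEvent(r.patient_id, r.icpc_code, r.date) for r in df.itertuples(index=False)]


def evaluate_cohort_part1(
    cohort: Cohort, config: Optional[CriteriaConfig] = None
) -> list[PIPRecord]:
    """All part-1 PIP records for every patient and criterion."""
    config = config or CriteriaConfig()
    rx_by_pid = cohort.grouped("prescriptions")
    dx_by_pid = cohort.grouped("diagnoses")
    records: list[PIPRecord] = []
    for patient in cohort.patient_records():
        pid = patient.patient_id
        rx = _patient_prescriptions(rx_by_pid[pid]) if pid in rx_by_pid else []
        if not rx:
            continue
        dx = _patient_diagnoses(dx_by_pid[pid]) if pid in dx_by_pid else []
        for spec in config.criteria.values():
            eps = episodes_for_criterion(rx, spec, config)
            records.extend(part1_pip_records(spec, patient, eps, dx, config))
    return records


def evaluate_cohort_part2(
    cohort: Cohort, criterion_code: str, config: Optional[CriteriaConfig] = None
) -> dict[str, dict[str, list[DateInterval]]]:
    """Part-2 med/PPI intervals per patient for one START criterion."""
    config = config or CriteriaConfig()
    spec = config.criteria[criterion_code]
    rx_by_pid = cohort.grouped("prescriptions")
    dx_by_pid = cohort.grouped("diagnoses")
    out: dict[str, dict[str, list[DateInterval]]] = {}
    for patient in cohort.patient_records():
        pid = patient.patient_id
        rx = _patient_prescriptions(rx_by_pid[pid]) if pid in rx_by_pid else []
        if not rx:
            continue
        dx = _patient_diagnoses(dx_by_pid[pid]) if pid in dx_by_pid else []
        eps = episodes_for_criterion(rx, spec, config)
        rec = part2_med_records(spec, patient, eps, dx, config)
        if rec["med_intervals"] or rec["ppi_intervals"]:
            out[pid] = rec
    return out


def pip_records_to_frame(records: Sequence[PIPRecord]) -> pd.DataFrame:
    """PIP records as a tidy frame (patient_id, criterion_code, start, end)."""
    return pd.DataFrame(
        [(r.patient_id, r.criterion_code, r.interval.start, r.interval.end) for r in records],
        columns=["patient_id", "criterion_code", "start", "end"],
    )
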