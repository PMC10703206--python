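"""Interval algebra on prescription episodes.

Repeat prescriptions for a chronic medication arrive as consecutive
scripts separated by small refill gaps.  Following the merging rule used
throughout the analysis, every prescription's end date is extended by a
medication-specific number of *gap days* (chosen from drug clearance
properties), and any two extended scripts of the same patient and drug
class that then overlap or touch are merged into a single
:class:`DrugEpisode`.  The same closed-interval day-set algebra (union,
subtraction, intersection) is reused to combine and protect
criterion-level exposure intervals.

All operations are defined on day sets: an interval ``[start, end]`` is
the set of calendar days it covers (inclusive), and two intervals touch
when the second starts the day after the first ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .ehr_model import DateInterval, Prescription

__all__ = [
    "DRUG_CLASSES",
    "GapDayTable",
    "DrugEpisode",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "extend_and_merge",
]

#: Drug classes referenced by the gastrointestinal-bleeding criteria.
DRUG_CLASSES = (
    "NSAID",
    "ASA_ECC",
    "PPI",
    "oral_anticoagulant",
    "platelet_inhibitor",
    "corticosteroid",
    "SSRI",
)

_ONE_DAY = timedelta(days=1)


@dataclass(frozen=True)
class GapDayTable:
    """Days added to each prescription's end date before merging.

    The defaults follow the published per-medication table: ASA/ECC 5,
    platelet aggregation inhibitors 4, NSAIDs 3, PPIs 3, and oral
    anticoagulants / corticosteroids / SSRIs 2 days.  A handful of
    criterion-specific overrides exist (companion antiplatelets under
    the NSAID-combination criterion use 2 days); look-ups therefore go
    through ``(criterion_code, drug_class)``.
    """

    class_defaults: Mapping[str, int] = field(
        default_factory=lambda: {
            "ASA_ECC": 5,
            "platelet_inhibitor": 4,
            "NSAID": 3,
            "PPI": 3,
            "oral_anticoagulant": 2,
            "corticosteroid": 2,
            "SSRI": 2,
        }
    )
    overrides: Mapping[tuple, int] = field(
        default_factory=lambda: {
            ("START_D2C", "platelet_inhibitor"): 2,
            ("START_D2C", "ASA_ECC"): 2,
        }
    )

    def gap(self, criterion_code: str, drug_class: str) -> int:
        key = (criterion_code, drug_class)
        if key in self.overrides:
            return self.overrides[key]
        try:
            return self.class_defaults[drug_class]
        except KeyError:
            raise KeyError(f"no gap-day entry for drug class {drug_class!r}") from None


@dataclass(frozen=True)
class DrugEpisode:
    """A merged, gap-extended interval of continuous exposure to one class."""

    patient_id: str
    drug_class: str
    interval: DateInterval
    max_daily_dose_mg: Optional[float] = None
    source_prescription_ids: tuple = ()


def _to_pairs(intervals: Iterable[DateInterval]) -> list[tuple[int, int]]:
    return [(iv.start.toordinal(), iv.end.toordinal()) for iv in intervals]


def _from_pairs(pairs: Iterable[tuple[int, int]]) -> list[DateInterval]:
    return [DateInterval(date.fromordinal(a), date.fromordinal(b)) for a, b in pairs]


def _merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge ordinal pairs into a maximal disjoint sorted list.

    Overlapping *or touching* (gap of zero days) pairs coalesce.
    """
    if not pairs:
        return []
    pairs = sorted(pairs)
    out = [pairs[0]]
    for a, b in pairs[1:]:
        pa, pb = out[-1]
        if a <= pb + 1:  # overlap or touch
            out[-1] = (pa, max(pb, b))
        else:
            out.append((a, b))
    return out


def merge_intervals(intervals: Sequence[DateInterval]) -> list[DateInterval]:
    """Union of day sets as a maximal, disjoint, sorted interval list."""
    return _from_pairs(_merge_pairs(_to_pairs(intervals)))


def subtract_intervals(
    a: Sequence[DateInterval], b: Sequence[DateInterval]
) -> list[DateInterval]:
    """Day-set difference ``a \\ b`` as a maximal disjoint sorted list."""
    left = _merge_pairs(_to_pairs(a))
    right = _merge_pairs(_to_pairs(b))
    out: list[tuple[int, int]] = []
    j = 0
    for a0, a1 in left:
        cur = a0
        while j < len(right) and right[j][1] < cur:
            j += 1
        k = j
        while k < len(right) and right[k][0] <= a1:
            b0, b1 = right[k]
            if b0 > cur:
                out.append((cur, b0 - 1))
            cur = max(cur, b1 + 1)
            if cur > a1:
                break
            k += 1
        if cur <= a1:
            out.append((cur, a1))
    return _from_pairs(out)


def intersect_intervals(
    a: Sequence[DateInterval], b: Sequence[DateInterval]
) -> list[DateInterval]:
    """Day-set intersection as a maximal disjoint sorted list."""
    left = _merge_pairs(_to_pairs(a))
    right = _merge_pairs(_to_pairs(b))
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(left) and j < len(right):
        lo = max(left[i][0], right[j][0])
        hi = min(left[i][1], right[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if left[i][1] < right[j][1]:
            i += 1
        else:
            j += 1
    # adjacent output pieces cannot touch because inputs are maximal
    return _from_pairs(out)


def extend_and_merge(
    prescriptions: Sequence[Prescription],
    gap_days: int,
    drug_class: Optional[str] = None,
) -> list[DrugEpisode]:
    """Merge same-patient, same-class scripts into drug episodes.

    Each prescription's end date is first extended by ``gap_days`` (the
    medication's clearance allowance); extended scripts that overlap or
    touch are merged into one episode running from the earliest start to
    the latest extended end.  Merging two scripts whose original end and
    next start are at most ``gap_days`` apart is equivalent, by the
    closed-interval touch rule, to this extend-then-union formulation.

    The episode dose is the maximum daily dose over its source scripts.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be non-negative")
    if not prescriptions:
        return []
    pids = {p.patient_id for p in prescriptions}
    if len(pids) != 1:
        raise ValueError(f"prescriptions span multiple patients: {sorted(pids)}")
    patient_id = prescriptions[0].patient_id

    items = sorted(
        enumerate(prescriptions), key=lambda t: (t[1].start_date, t[1].end_date)
    )
    episodes: list[DrugEpisode] = []
    cur_start = cur_end = None
    cur_sources: list[int] = []
    cur_dose: Optional[float] = None

    def _flush():
        if cur_start is None:
            return
        episodes.append(
            DrugEpisode(
                patient_id=patient_id,
                drug_class=drug_class or "",
                interval=DateInterval(
                    date.fromordinal(cur_start), date.fromordinal(cur_end)
                ),
                max_daily_dose_mg=cur_dose,
                source_prescription_ids=tuple(cur_sources),
            )
        )

    def _norm(d):
        # NaN (missing dose from CSV) behaves like None
        return None if d is None or d != d else float(d)

    for idx, p in items:
        a = p.start_date.toordinal()
        b = p.end_date.toordinal() + gap_days
        dose = _norm(p.daily_dose_mg)
        if cur_start is not None and a <= cur_end + 1:
            cur_end = max(cur_end, b)
            cur_sources.append(idx)
            if dose is not None:
                cur_dose = dose if cur_dose is None else max(cur_dose, dose)
        else:
            _flush()
            cur_start, cur_end, cur_sources = a, b, [idx]
            cur_dose = dose
    _flush()
    return episodes


def total_days(intervals: Sequence[DateInterval]) -> int:
    """Total number of distinct days covered by an interval list."""
    return sum((b - a) + 1 for a, b in _merge_pairs(_to_pairs(intervals)))
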