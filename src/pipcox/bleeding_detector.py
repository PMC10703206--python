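"""Detection of gastrointestinal bleeding events in coded and free-text data.

Bleedings are identified through two channels:

1. specific ICPC codes: hematemesis (D14), melena (D15), duodenal ulcer
   (D85) and other stomach ulcers (D86);
2. a keyword search over free-text journal notes, combining a Dutch
   "bleed" stem with a stomach/digestive/gastro context term, accepted
   only when the note's attached ICPC code is general/non-specific (or
   absent) and *not* a specific code for a different diagnosis.

Events from the two channels are unioned; the ICPC channel wins when
both fire on the same day, and events of the same patient closer than a
configurable window (default 30 days) are collapsed into one bleeding.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "BLEEDING_ICPC_CODES",
    "BleedingEvent",
    "KeywordConfig",
    "detect_by_icpc",
    "detect_by_freetext",
    "combine_events",
    "detect_bleedings",
    "events_to_frame",
]

#: Specific ICPC-1 codes counted as gastrointestinal bleeding.
BLEEDING_ICPC_CODES = ("D14", "D15", "D85", "D86")


@dataclass(frozen=True)
class BleedingEvent:
    patient_id: str
    date: date
    source: str  # "icpc" | "free_text"
    matched: str  # ICPC code or matched keywords


@dataclass(frozen=True)
class KeywordConfig:
    """Keyword and ICPC-code sets driving the free-text channel.

    ``anchor_terms`` are bleeding stems ("bloed" covers bloeding,
    bloedverlies, maagbloeding, ...); ``context_terms`` localize the
    bleeding to the digestive tract.  Matching is case-insensitive
    substring search on diacritic-stripped text.
    """

    anchor_terms: tuple = ("bloed",)
    context_terms: tuple = ("maag", "verter", "gastro", "tract", "dig", "darm")
    #: general codes under which an uncoded/vague bleeding may be filed
    nonspecific_icpc: frozenset = frozenset({"A99", "D99"})
    #: specific codes for *other* diagnoses that disqualify a keyword hit
    exclusion_icpc: frozenset = frozenset({"R06", "U06", "W03"})

    def __post_init__(self):
        if not self.anchor_terms or not self.context_terms:
            raise ValueError("anchor and context term lists must be non-empty")


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFKD", str(text))
    return "".join(c for c in text if not unicodedata.combining(c)).lower()


def detect_by_icpc(diagnoses: pd.DataFrame) -> list[BleedingEvent]:
    """One event per (patient, day) with a specific bleeding ICPC code."""
    hits = diagnoses[diagnoses["icpc_code"].isin(BLEEDING_ICPC_CODES)]
    seen: dict[tuple, BleedingEvent] = {}
    for r in hits.itertuples(index=False):
        key = (r.patient_id, r.date)
        if key not in seen:
            seen[key] = BleedingEvent(r.patient_id, r.date, "icpc", r.icpc_code)
    return sorted(seen.values(), key=lambda e: (e.patient_id, e.date))


def detect_by_freetext(
    notes: pd.DataFrame, config: Optional[KeywordConfig] = None
) -> list[BleedingEvent]:
    """Keyword-detected bleedings from journal notes.

    A note fires when its normalized text contains at least one anchor
    term *and* one context term, and its attached ICPC code is in the
    non-specific set (or absent) and not in the exclusion set.
    """
    config = config or KeywordConfig()
    seen: dict[tuple, BleedingEvent] = {}
    for r in notes.itertuples(index=False):
        text = _normalize(r.text)
        anchors = [t for t in config.anchor_terms if t in text]
        contexts = [t for t in config.context_terms if t in text]
        if not anchors or not contexts:
            continue
        code = (r.icpc_code or "").strip()
        if code and code in config.exclusion_icpc:
            continue
        if code and code not in config.nonspecific_icpc:
            continue
        key = (r.patient_id, r.date)
        if key not in seen:
            seen[key] = BleedingEvent(
                r.patient_id, r.date, "free_text", "+".join(anchors + contexts)
            )
    return sorted(seen.values(), key=lambda e: (e.patient_id, e.date))


def combine_events(
    icpc_events: Sequence[BleedingEvent],
    text_events: Sequence[BleedingEvent],
    collapse_window_days: int = 30,
) -> list[BleedingEvent]:
    """Union both channels into distinct bleedings.

    Same-day duplicates resolve in favour of the ICPC channel; any event
    less than ``collapse_window_days`` days after the patient's previous
    retained event is folded into it (treated as the same bleeding).
    """
    by_key: dict[tuple, BleedingEvent] = {}
    for ev in text_events:
        by_key[(ev.patient_id, ev.date)] = ev
    for ev in icpc_events:
        by_key[(ev.patient_id, ev.date)] = ev  # icpc wins on collision
    merged = sorted(by_key.values(), key=lambda e: (e.patient_id, e.date))
    out: list[BleedingEvent] = []
    last: dict[str, date] = {}
    for ev in merged:
        prev = last.get(ev.patient_id)
        if prev is not None and (ev.date - prev).days < collapse_window_days:
            continue
        out.append(ev)
        last[ev.patient_id] = ev.date
    return out


def detect_bleedings(
    cohort,
    config: Optional[KeywordConfig] = None,
    collapse_window_days: int = 30,
) -> list[BleedingEvent]:
    """Full detection pipeline restricted to each patient's window.

    Out-of-window records (e.g. pre-entry ulcer history) are dropped
    *before* the collapse step so they cannot absorb an in-window event.
    """
    windows = {
        r.patient_id: (r.entry_date, r.exit_date)
        for r in cohort.patients.itertuples(index=False)
    }

    def _in_window(events):
        out = []
        for ev in events:
            w = windows.get(ev.patient_id)
            if w is not None and w[0] <= ev.date <= w[1]:
                out.append(ev)
        return out

    return combine_events(
        _in_window(detect_by_icpc(cohort.diagnoses)),
        _in_window(detect_by_freetext(cohort.notes, config)),
        collapse_window_days,
    )


def events_to_frame(events: Sequence[BleedingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.patient_id, e.date, e.source, e.matched) for e in events],
        columns=["patient_id", "date", "source", "matched"],
    )
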