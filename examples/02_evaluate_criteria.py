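"""Evaluate the STOPP/START criteria on a hand-built patient record.

A 72-year-old takes an NSAID for six weeks; a PPI covers only the
middle two weeks.  Under the prescribing criteria, NSAID use above age
70 without gastroprotection is a potential prescribing omission
(START D2B), so the nonadherence interval is the NSAID episode minus
the PPI-covered days.
"""

from datetime import date

from pipcox import PatientRecord, Prescription
from pipcox.criteria_engine import (
    CriteriaConfig,
    episodes_for_criterion,
    part1_pip_records,
)

config = CriteriaConfig()
patient = PatientRecord("demo", date(1935, 1, 1), "F",
                        date(2007, 1, 1), date(2014, 12, 31), "study_end")
scripts = [
    Prescription("demo", "M01AE01", date(2007, 3, 1), date(2007, 3, 21), 1200.0),
    Prescription("demo", "M01AE01", date(2007, 3, 24), date(2007, 4, 12), 1200.0),
    Prescription("demo", "A02BC01", date(2007, 3, 15), date(2007, 3, 28), 20.0),
]

spec = config.criteria["START_D2B"]
episodes = episodes_for_criterion(scripts, spec, config)
print("merged NSAID episodes (3 gap days):")
for ep in episodes["NSAID"]:
    print(f"  {ep.interval.start} .. {ep.interval.end}")
print("PPI episodes:")
for ep in episodes["PPI"]:
    print(f"  {ep.interval.start} .. {ep.interval.end}")

records = part1_pip_records(spec, patient, episodes, [], config)
print("START D2B nonadherence records (NSAID days not covered by PPI):")
for r in records:
    print(f"  {r.interval.start} .. {r.interval.end}  ({r.interval.n_days} days)")
# The two NSAID scripts merge into one episode (gap <= 3 days); the
# PPI-covered middle is carved out, leaving two nonadherence intervals.
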