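"""Detect gastrointestinal bleedings from codes and free text.

Bleedings hide in two places: specific ICPC codes (D14 hematemesis,
D15 melena, D85/D86 ulcers) and free-text journal notes filed under a
vague code.  The keyword channel requires a Dutch "bleed" stem plus a
digestive-context term and rejects notes whose code names a different
diagnosis.
"""

from datetime import date

import pandas as pd

from pipcox import SimulationConfig, generate_cohort, detect_bleedings
from pipcox.bleeding_detector import detect_by_freetext, KeywordConfig

cohort, truth = generate_cohort(SimulationConfig(n_patients=800, seed=5))
events = detect_bleedings(cohort)

n_icpc = sum(1 for e in events if e.source == "icpc")
n_text = sum(1 for e in events if e.source == "free_text")
print(f"detected bleedings:   {len(events)} ({n_icpc} coded + {n_text} free-text-only)")
print(f"planted bleedings:    {len(truth.events)}")

# the exclusion rule at work on three hand-written notes
notes = pd.DataFrame(
    [
        ("p1", date(2010, 1, 1), "A99", "melena, bloedverlies uit de maag"),
        ("p2", date(2010, 1, 1), "R06", "neusbloeding; ook maagklachten"),
        ("p3", date(2010, 1, 1), "", "controle bloeddruk, stabiel"),
    ],
    columns=["patient_id", "date", "icpc_code", "text"],
)
hits = detect_by_freetext(notes, KeywordConfig())
print("free-text demo: fired for", [e.patient_id for e in hits])
# Only p1 fires: p2 has the keywords but a specific non-GI code
# (epistaxis), p3 has a "bloed" stem with no digestive context.
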