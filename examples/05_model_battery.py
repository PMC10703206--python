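"""Run the full model battery and inspect the PPI interaction.

Fits every model form of the analysis plan: combined and per-criterion
nonadherence models (part 1), harmful-medication and medication-by-PPI
interaction models (part 2), and the bleeding-subpopulation sensitivity
fits.  Criteria during which no bleeding occurred come back flagged as
non-estimable instead of crashing the run.
"""

import pandas as pd

from pipcox import default_plan, detect_bleedings, evaluate_cohort_part1, generate_cohort, run_plan
from pipcox.calibration import calibration_config

pd.set_option("display.width", 140)

cohort, _ = generate_cohort(calibration_config(n_patients=1500, seed=8))
records = evaluate_cohort_part1(cohort)
bleedings = detect_bleedings(cohort)

table, fits = run_plan(cohort, records, bleedings, default_plan())
cols = ["criterion", "form", "population", "n_records", "n_events", "hr", "p_value", "estimable"]
print(table[cols].round(3).to_string(index=False))

inter = table[(table["form"] == "part2_interaction") & table.get("interaction_coef").notna()]
if len(inter):
    print("\nmedication-by-PPI interaction (stratum-specific HRs):")
    print(inter[["criterion", "no_ppi_hr", "ppi_hr", "interaction_coef", "interaction_p"]]
          .round(3).to_string(index=False))
# A negative interaction coefficient means concomitant PPI lowers the
# medication hazard ratio — gastroprotection working as intended.
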