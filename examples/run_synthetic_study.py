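"""End-to-end synthetic two-arm study.

Simulates 10 treated vs 9 control animals: per animal, baseline and
follow-up LGE phantoms under the arm's scar remodeling rule, one optical
movie, and a histology table; every stream runs through its analysis module
and arms are compared endpoint-by-endpoint with the exact Mann-Whitney
test.
"""

import pandas as pd

from cardioscar.study import StudyConfig, run_study

pd.set_option("display.width", 160)

report = run_study(StudyConfig(), seed=1)
cols = ["endpoint", "treated_median", "control_median", "p_value"]
print(report.endpoints[cols].round(3).to_string(index=False))

print(
    "\nThe treated arm grows epicardial heterogeneous tissue (dEpHT) with"
    "\nstable dense scar, the control arm converts HT into dense scar"
    "\n(dEpDS), and electrical HT-HM dispersion (delta CV / delta APD) is"
    "\nsmaller in the treated arm; endocardial and endocardial-histology"
    "\nendpoints do not separate. p-values are exact Mann-Whitney."
)
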