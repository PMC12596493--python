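"""Multimorbidity profile of a cohort: single / >=2 / >=4 disease split.

Percentages are shares of the stratum's inpatients; "diagnoses" counts
distinct 3-character ICD-10 categories summed over records.
"""

import pandas as pd

from multimorbnet import generate_records, prepare_strata, profile, study_config

records, _ = generate_records(study_config(seed=17, scale=0.05))
strata = prepare_strata(records, scheme="sex_age")

rows = [profile(s).as_row() for s in strata.values()]
df = pd.DataFrame(rows)[
    ["stratum", "n_records", "n_diseases", "diagnoses_per_capita",
     "pct_single", "pct_multi", "pct_complex"]
]
print(df.to_string(index=False))
# pct_multi is the multimorbidity prevalence (2+ diseases), pct_complex the
# complex-multimorbidity prevalence (4+); the two sexes and four age bands
# are profiled independently.
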