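"""Per-patient-year outcome comparison on the matched cohort.

Follow-up runs from the index date to death, BTA initiation, a later SRE
(non-SRE group) or end of data.  Rates pool group totals over group
person-years; ratios compare SRE vs non-SRE with bootstrap p-values.
"""
from dataclasses import replace

from sreburden import (SimulationConfig, generate_claims, build_cohorts,
                       run_matching, compute_followups, person_level_outcomes,
                       outcomes_table)

ds, _ = generate_claims(replace(SimulationConfig(), n_persons=3000, seed=42))
cohort = build_cohorts(ds, seed=7).cohort
m = run_matching(ds, cohort, seed=11)

ids = m.matched.matched_ids()
matched_cohort = cohort[cohort["person_id"].isin(ids)]
fu = compute_followups(matched_cohort, ds)
pt = person_level_outcomes(ds, fu)
t3 = outcomes_table(pt, n_boot=500, seed=13)
print(t3[["outcome", "rate_sre_2dp", "rate_non_sre_2dp", "ratio_2dp",
          "p_value"]].to_string(index=False))
# Each row is one resource or cost outcome per patient-year; a ratio above 1
# means the SRE group uses more of it. The total-cost ratio estimates the
# incremental cost of skeletal-related events.
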