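"""Apply the eligibility chain and inspect the attrition table.

Incident bone-metastasis cases are kept if a solid tumor is confirmed around
the BM date, the person is an adult with continuous enrollment, and no
bone-targeting agent (BTA) was dispensed before the index date.  SRE patients
are indexed at their first SRE; non-SRE patients get a random index drawn from
the SRE group's BM-to-index offsets.
"""
from dataclasses import replace

from sreburden import SimulationConfig, generate_claims, build_cohorts

ds, _ = generate_claims(replace(SimulationConfig(), n_persons=3000, seed=42))
res = build_cohorts(ds, seed=7)

print(res.attrition.to_string(index=False))
share = (res.cohort["group"] == "SRE").mean()
print(f"\nSRE share of the eligible cohort: {share:.1%}")
# Each attrition row is the number of persons remaining after one eligibility
# criterion; the final row is the analyzable SRE + non-SRE cohort.
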