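"""Generate a synthetic German-style claims extract with known ground truth.

The generator emits seven tables (persons, enrollment, diagnoses, procedures,
dispensings, itemized costs, sick leave) for a population of cancer patients
with bone metastases, plus the latent per-person frailty that confounds SRE
risk with healthcare costs.
"""
from dataclasses import replace

from sreburden import SimulationConfig, generate_claims

cfg = replace(SimulationConfig(), n_persons=3000, seed=42)
ds, truth = generate_claims(cfg)

print("record counts per table:", ds.counts())
bm = truth.table["has_bm"].mean()
sre = truth.table["true_sre_date"].notna().mean()
print(f"share with a bone-metastasis diagnosis: {bm:.1%}")
print(f"share with an observed skeletal-related event: {sre:.1%}")
print(f"configured total-cost effect of the SRE state: "
      f"{cfg.implied_total_cost_multiplier():.3f}")
# The last number is the ground truth the downstream matched analysis should
# recover; the two shares describe how common BM and SREs are in this world.
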