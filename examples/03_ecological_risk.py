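"""Ecological risk quotients for a simulated campaign.

Derives PNECs from the packaged toxicity registry (endpoint / assessment
factor: 100 acute, 10 chronic), computes RQ_E = MEC / PNEC per analyte x
trophic level x state x setting x season, and summarizes how often the
ecological benchmark of 1.0 is exceeded.
"""

from phenorisk import (
    CampaignDesign,
    GenerativeParams,
    derive_pnec,
    eco_risk_table,
    generate_campaign,
    mec_table,
    summarize_exceedance,
)
from phenorisk.registries import load_toxicity_records

df = generate_campaign(CampaignDesign(), GenerativeParams(seed=1))
pnec = derive_pnec(load_toxicity_records())
eco = eco_risk_table(mec_table(df), pnec)

print("highest quotients (most at-risk taxa):")
cols = ["analyte", "trophic_level", "class", "state", "setting", "season", "rq_e", "tier"]
print(eco.sort_values("rq_e", ascending=False)[cols].head(8).to_string(index=False))

print("\nexceedance of RQ_E > 1:")
print(summarize_exceedance(eco).round(2).to_string(index=False))
print("\nRQ_E > 1 means the measured concentration exceeds the concentration "
      "predicted to have no effect on that trophic level; invertebrates "
      "(daphnia-type endpoints) are typically the most sensitive here.")
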