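"""Plate quality control: z'-factor per readout.

Simulates one default 384-well plate per readout (~100 classified cells
per well, positive controls at activity 0.9) and computes

    z' = 1 - 3 (sigma_pos + sigma_neg) / |mu_pos - mu_neg|

between the positive-control and DMSO hit-rate populations.  An assay
scoring 0.5-1.0 is conventionally rated excellent.
"""

import nucleoscreen as ns
from nucleoscreen.platemap import POSITIVE_CONTROL_PREFIX

plates = ns.build_screen_layout([f"compound_{i:04d}" for i in range(320)], plates=1)
effect = ns.EffectModel(control_activity=0.9)
counts = ns.simulate_screen_tables(plates, effect, cells_per_well=120, replicates=1, seed=1)
rates = ns.hit_rate_table(counts)

for readout, grp in rates.groupby("readout"):
    pos = grp.loc[grp["role"].str.startswith(POSITIVE_CONTROL_PREFIX), "hit_rate"].dropna()
    neg = grp.loc[grp["role"] == "dmso", "hit_rate"].dropna()
    z = ns.zprime(pos, neg)
    print(f"{readout:16s}  mu_pos={pos.mean():.3f}  mu_neg={neg.mean():.3f}  z'={z:.3f}")
# All four readouts should score z' >= 0.5 under default conditions.
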