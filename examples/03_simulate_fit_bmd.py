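"""Simulate a component study, fit candidate models, estimate BMD/BMDL.

Generates a synthetic PFOS-style study (6 groups x 3 dishes x 20 embryos)
with a known linear swim-bladder-area truth, screens the top dose group
for a trend reversal, fits the candidate dose-response models to the
per-fish data pooled across replicates, and reports the benchmark dose at
one control standard deviation with its one-sided 95% lower bound.
"""

import numpy as np

from toxmix import (compute_bmd, default_pfos_fts_designs, default_truth,
                    exclude_nonmonotonic_top, fit_candidates, generate_study)

design, _, _ = default_pfos_fts_designs()
truth = default_truth(design)
table = generate_study(design, truth, seed=20220725)

dose_of = dict(zip(design.labels, design.doses("PFOS")))
alive = table[table["alive"]].dropna(subset=["SBA_mm2"])
doses = alive["treatment"].map(dose_of).to_numpy()
sba = alive["SBA_mm2"].to_numpy()

# screen the top group: drop it if it reverses the trend by > 1 control SD
group_means = [sba[doses == d].mean() for d in sorted(set(doses))]
ctrl = sba[doses == 0]
retained, dropped = exclude_nonmonotonic_top(group_means, ctrl.std(ddof=1))
if dropped:
    top = sorted(set(doses))[-1]
    keep = doses < top
    doses, sba = doses[keep], sba[keep]
print(f"top dose group dropped: {dropped}")

fits = fit_candidates(doses, sba, ["linear", "power", "polynomial2"])
print(f"{'model':<14}{'AIC':>10}  {'BMD':>8}  {'BMDL':>8}  qc")
for f in fits:
    res = compute_bmd(f, ctrl.mean(), ctrl.std(ddof=1))
    print(f"{f.name:<14}{f.aic:>10.1f}  {res.bmd:>8.0f}  {res.bmdl:>8.0f}  "
          f"{res.qc_flag}")
print("\nBMD: dose shifting mean SBA by one control SD; BMDL: its one-sided")
print("95% profile-likelihood lower bound (both in µg/L).")
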