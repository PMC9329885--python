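"""NOAEL/LOAEL points of departure from a simulated study.

Replicate (dish) means are compared by one-way ANOVA with Tukey-corrected
control-vs-treatment contrasts; the significance pattern yields the NOAEL
and LOAEL with bounded/unbounded qualifiers, and qualified POD ratios
propagate the inequality direction.
"""

from toxmix import (anova_pairwise, default_pfos_fts_designs, default_truth,
                    derive_noael_loael, generate_study, pod_ratio,
                    replicate_means)
from toxmix.pod import POD, UNBOUNDED_HIGH, UNBOUNDED_LOW

design, _, _ = default_pfos_fts_designs()
table = generate_study(design, default_truth(design), seed=7)
dose_of = dict(zip(design.labels, design.doses("PFOS")))

for endpoint in ("SBA", "BL", "mortality"):
    res = anova_pairwise(replicate_means(table, endpoint), endpoint=endpoint)
    pods = derive_noael_loael(res, dose_of)
    noael = f"{pods.noael.prefix}{pods.noael.value:g}" if pods.noael else "none"
    loael = f"{pods.loael.prefix}{pods.loael.value:g}" if pods.loael else "none"
    print(f"{endpoint:<10} NOAEL {noael:>8} µg/L   LOAEL {loael:>8} µg/L")

# ratio of unbounded PODs propagates the inequalities
r = pod_ratio(POD(15530.0, UNBOUNDED_HIGH), POD(0.76, UNBOUNDED_LOW))
print(f"\nPOD ratio >15530 / <0.76 = {r.ratio:.3g} ({r.qualifier}):")
print("an unbounded-high numerator over an unbounded-low denominator is a")
print("lower bound on the true potency difference.")
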