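"""Reference linear dose-response parameters for the PFOS / 6:2 FTS
zebrafish swim-bladder-area studies.

These are the reported component-study and binary-mixture-study fits
(intercept ``a`` in mm^2, slope ``b`` in mm^2 per ug/L, observed control
mean ``R0`` in mm^2).  They let the relative-potency and dose-balance
machinery be exercised exactly from published parameters, without the
underlying per-fish data.
"""

from .drmodels import LinearDRFit

__all__ = [
    "PFOS_COMPONENT_FIT",
    "FTS_COMPONENT_FIT",
    "PFOS_MIXTURE_FIT",
    "FTS_MIXTURE_FIT",
    "PFOS_MW",
    "FTS_MW",
]

#: PFOS dosed alone, swim bladder area
PFOS_COMPONENT_FIT = LinearDRFit.from_params(a=0.04563, b=-6.45e-6, R0=0.0637)
#: 6:2 FTS dosed alone, swim bladder area
FTS_COMPONENT_FIT = LinearDRFit.from_params(a=0.05499, b=-5.60e-7, R0=0.0594)
#: PFOS concentration axis of the binary-mixture experiment
PFOS_MIXTURE_FIT = LinearDRFit.from_params(a=0.05218, b=-1.57e-5, R0=0.0529)
#: 6:2 FTS concentration axis of the binary-mixture experiment
FTS_MIXTURE_FIT = LinearDRFit.from_params(a=0.05250, b=-1.39e-6, R0=0.0529)

#: molecular weights, ug per uMol (for ug/L -> uM display conversion)
PFOS_MW = 500.13
FTS_MW = 428.17
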