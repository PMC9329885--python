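"""Synthetic zebrafish-embryo study generator.

Emulates the design of a binary-mixture developmental toxicity study:
a control group (T0) plus five treatment groups (T1..T5), three replicate
Petri dishes of twenty embryos each, with continuous morphometric
endpoints (body length BL in mm, swim bladder area SBA in mm^2, yolk sac
area YSA in mm^2) and binary mortality/hatch outcomes recorded per fish.

Continuous endpoint means follow a linear dose-response in the
potency-weighted total dose ``sum_k w_k * C_k`` (index chemical weight 1),
with Gaussian noise truncated at zero since lengths and areas cannot be
negative.  Mortality and hatching are group-level Bernoulli draws; dead
fish carry missing morphometrics, mirroring the practice of discarding
dead embryos before imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyDesign",
    "EndpointTruth",
    "TruthModel",
    "generate_study",
    "default_pfos_fts_designs",
    "default_truth",
    "ENDPOINT_COLUMNS",
    "MEASUREMENT_COLUMNS",
]

#: canonical CSV column per continuous endpoint (unit in the suffix)
ENDPOINT_COLUMNS: dict[str, str] = {"BL": "BL_mm", "SBA": "SBA_mm2", "YSA": "YSA_mm2"}

#: full measurement-table column order
MEASUREMENT_COLUMNS: list[str] = [
    "experiment",
    "replicate",
    "treatment",
    "alive",
    "hatched",
    "BL_mm",
    "SBA_mm2",
    "YSA_mm2",
]


class DesignError(ValueError):
    """Invalid study design or truth model."""


@dataclass
class StudyDesign:
    """Layout of one exposure experiment.

    Parameters
    ----------
    name:
        Experiment identifier written to the ``experiment`` column.
    analytes:
        Chemical names, index chemical first by convention.
    groups:
        Ordered ``(label, {analyte: measured concentration ug/L})`` pairs;
        the first group is the control.
    n_replicates, n_embryos_per_replicate:
        Dishes per group and embryos per dish.
    endpoints:
        Continuous endpoints measured (subset of BL/SBA/YSA).
    nominal:
        Optional ``{label: {analyte: nominal concentration}}`` bookkeeping;
        analysis always uses the measured values in ``groups``.
    """

    name: str
    analytes: tuple[str, ...]
    groups: tuple[tuple[str, dict[str, float]], ...]
    n_replicates: int = 3
    n_embryos_per_replicate: int = 20
    endpoints: tuple[str, ...] = ("BL", "SBA", "YSA")
    nominal: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_embryos_per_replicate < 1:
            raise DesignError("replicate and embryo counts must be >= 1")
        if len(self.groups) < 2:
            raise DesignError("need a control plus at least one treatment group")
        for ep in self.endpoints:
            if ep not in ENDPOINT_COLUMNS:
                raise DesignError(f"unknown endpoint {ep!r}; expected one of {sorted(ENDPOINT_COLUMNS)}")
        for label, concs in self.groups:
            for analyte, c in concs.items():
                if analyte not in self.analytes:
                    raise DesignError(f"group {label!r} references unknown analyte {analyte!r}")
                if c < 0:
                    raise DesignError(f"negative concentration for {analyte!r} in group {label!r}")
        # treatment concentrations must not decrease with group order; the
        # control may carry a small trace (instrument carryover) below T1
        for analyte in self.analytes:
            doses = [concs.get(analyte, 0.0) for _, concs in self.groups]
            treat = doses[1:]
            if any(b < a for a, b in zip(treat, treat[1:])):
                raise DesignError(f"concentrations of {analyte!r} must be non-decreasing across treatment groups")
            # trace contamination in the control is tolerated as long as it is
            # negligible against the dosed range (<=1% of the top dose)
            top = max(treat, default=0.0)
            if doses[0] > 0 and doses[0] > 0.01 * top:
                raise DesignError(f"control concentration of {analyte!r} is not a negligible trace")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_records(self) -> int:
        return self.n_groups * self.n_replicates * self.n_embryos_per_replicate

    def doses(self, analyte: str) -> np.ndarray:
        """Measured concentration of one analyte per group, in group order."""
        return np.array([concs.get(analyte, 0.0) for _, concs in self.groups], dtype=float)

    def weighted_doses(self, weights: Mapping[str, float]) -> np.ndarray:
        """Potency-weighted total dose per group: sum_k w_k * C_k."""
        total = np.zeros(self.n_groups)
        for analyte in self.analytes:
            total += weights.get(analyte, 1.0) * self.doses(analyte)
        return total


@dataclass
class EndpointTruth:
    """Ground-truth linear dose-response for one continuous endpoint.

    ``mean(dose) = intercept + slope * weighted_dose``; ``control_mean``
    records the baseline used when expressing percent responses (it
    defaults to the intercept, but a study may observe a control mean that
    sits off the fitted line).
    """

    intercept: float
    slope: float
    noise_sd: float
    control_mean: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise DesignError("noise SD must be > 0")
        if self.control_mean is None:
            self.control_mean = self.intercept


@dataclass
class TruthModel:
    """Complete generating model for one experiment."""

    endpoints: dict[str, EndpointTruth]
    potency_weights: dict[str, float]
    mortality: tuple[float, ...]
    hatch: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in self.endpoints:
            if name not in ENDPOINT_COLUMNS:
                raise DesignError(f"unknown endpoint {name!r} in truth model")
        for analyte, w in self.potency_weights.items():
            if w <= 0:
                raise DesignError(f"potency weight for {analyte!r} must be > 0")
        for p in (*self.mortality, *self.hatch):
            if not 0.0 <= p <= 1.0:
                raise DesignError("mortality/hatch probabilities must lie in [0, 1]")


def generate_study(design: StudyDesign, truth: TruthModel, seed: int) -> pd.DataFrame:
    """Simulate one experiment as a per-fish measurement table.

    One row per embryo.  Continuous endpoints are drawn from a normal
    distribution truncated at zero with mean ``a + b * weighted_dose``;
    alive/hatched flags are Bernoulli with the group probabilities of
    ``truth``.  Dead fish have missing endpoint values.  The same
    ``(design, truth, seed)`` triple always yields an identical table
    (single named generator: numpy PCG64).
    """
    if len(truth.mortality) != design.n_groups or len(truth.hatch) != design.n_groups:
        raise DesignError(
            f"mortality/hatch must list one probability per group ({design.n_groups})"
        )
    for ep in design.endpoints:
        if ep not in truth.endpoints:
            raise DesignError(f"truth model missing endpoint {ep!r}")

    rng = np.random.default_rng(seed)
    wd = design.weighted_doses(truth.potency_weights)
    n_fish = design.n_embryos_per_replicate

    rows: dict[str, list] = {c: [] for c in MEASUREMENT_COLUMNS}
    for g, (label, _) in enumerate(design.groups):
        for rep in range(1, design.n_replicates + 1):
            alive = rng.random(n_fish) >= truth.mortality[g]
            hatched = rng.random(n_fish) < truth.hatch[g]
            hatched &= alive  # dead embryos never hatch
            values: dict[str, np.ndarray] = {}
            for ep in design.endpoints:
                t = truth.endpoints[ep]
                mu = t.intercept + t.slope * wd[g]
                lo = (0.0 - mu) / t.noise_sd
                draw = stats.truncnorm.rvs(lo, np.inf, loc=mu, scale=t.noise_sd,
                                           size=n_fish, random_state=rng)
                draw = np.where(alive, draw, np.nan)
                values[ENDPOINT_COLUMNS[ep]] = draw
            rows["experiment"].extend([design.name] * n_fish)
            rows["replicate"].extend([rep] * n_fish)
            rows["treatment"].extend([label] * n_fish)
            rows["alive"].extend(alive.astype(bool).tolist())
            rows["hatched"].extend(hatched.astype(bool).tolist())
            for col in ENDPOINT_COLUMNS.values():
                if col in values:
                    rows[col].extend(values[col].tolist())
                else:
                    rows[col].extend([np.nan] * n_fish)

    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    table.attrs["seed"] = int(seed)
    table.attrs["generator"] = "numpy.random.PCG64"
    table.attrs["design"] = design.name
    return table


# ---------------------------------------------------------------------------
# Reference dose regimens (measured and nominal concentrations, ug/L) for the
# PFOS / 6:2 FTS component experiments and their 1:10 binary mixture.
# ---------------------------------------------------------------------------

PFOS = "PFOS"
FTS = "6:2 FTS"

_LABELS = ("T0", "T1", "T2", "T3", "T4", "T5")

_PFOS_COMPONENT_MEASURED = (0.0, 0.76, 3.2, 50.0, 2066.0, 7475.0)
_PFOS_COMPONENT_NOMINAL = (0.0, 0.1, 2.0, 60.0, 600.0, 1980.0)

_FTS_COMPONENT_MEASURED = (0.0, 1.2, 23.0, 731.0, 6331.0, 15530.0)
_FTS_COMPONENT_NOMINAL = (0.0, 1.0, 20.0, 600.0, 6000.0, 19800.0)
#: 6:2 FTS detected in the component-study control (instrument carryover)
FTS_CONTROL_TRACE = 1.9

_MIX_PFOS_MEASURED = (0.0, 0.075, 0.63, 29.0, 241.0, 1570.0)
_MIX_FTS_MEASURED = (0.0, 1.3, 21.0, 683.0, 5825.0, 15229.0)
_MIX_PFOS_NOMINAL = _PFOS_COMPONENT_NOMINAL
_MIX_FTS_NOMINAL = _FTS_COMPONENT_NOMINAL


def _mk_design(name, analytes, measured, nominal):
    groups = tuple(
        (label, {a: measured[a][i] for a in analytes}) for i, label in enumerate(_LABELS)
    )
    nom = {label: {a: nominal[a][i] for a in analytes} for i, label in enumerate(_LABELS)}
    return StudyDesign(name=name, analytes=tuple(analytes), groups=groups, nominal=nom)


def default_pfos_fts_designs(
    include_control_trace: bool = False,
) -> tuple[StudyDesign, StudyDesign, StudyDesign]:
    """The PFOS component, 6:2 FTS component and binary-mixture regimens.

    Measured concentrations are hard-coded; nominal targets are kept as
    bookkeeping.  ``include_control_trace`` puts the 1.9 ug/L 6:2 FTS
    carryover back into the component-study control (default off: simulated
    controls are clean).
    """
    fts_control = FTS_CONTROL_TRACE if include_control_trace else 0.0
    fts_measured = (fts_control,) + _FTS_COMPONENT_MEASURED[1:]
    pfos = _mk_design("pfos_component", [PFOS], {PFOS: _PFOS_COMPONENT_MEASURED},
                      {PFOS: _PFOS_COMPONENT_NOMINAL})
    fts = _mk_design("fts_component", [FTS], {FTS: fts_measured},
                     {FTS: _FTS_COMPONENT_NOMINAL})
    mixture = _mk_design(
        "binary_mixture",
        [PFOS, FTS],
        {PFOS: _MIX_PFOS_MEASURED, FTS: _MIX_FTS_MEASURED},
        {PFOS: _MIX_PFOS_NOMINAL, FTS: _MIX_FTS_NOMINAL},
    )
    return pfos, fts, mixture


def default_truth(design: StudyDesign) -> TruthModel:
    """A realistic generating model for the given regimen.

    Swim bladder area follows the component-study linear fit (intercept
    0.04563 mm^2, slope -6.45e-6 mm^2 per ug/L of PFOS-equivalent dose,
    fish-level SD 0.013 mm^2).  Body length declines weakly and yolk sac
    area grows weakly with dose.  6:2 FTS is down-weighted 14-fold relative
    to PFOS (the limiting potency ratio of the component fits).  Mortality
    and hatch rates are flat across groups, reflecting endpoints that were
    unresponsive over these dose ranges.
    """
    n = design.n_groups
    weights = {PFOS: 1.0, FTS: 1.0 / 13.88}
    # any other analyte name defaults to index-like weight 1
    for a in design.analytes:
        weights.setdefault(a, 1.0)
    return TruthModel(
        endpoints={
            "SBA": EndpointTruth(intercept=0.04563, slope=-6.45e-6, noise_sd=0.013,
                                 control_mean=0.0637),
            "BL": EndpointTruth(intercept=3.90, slope=-2.0e-5, noise_sd=0.15),
            "YSA": EndpointTruth(intercept=0.20, slope=1.5e-6, noise_sd=0.030),
        },
        potency_weights=weights,
        mortality=tuple([0.05] * n),
        hatch=tuple([0.90] * n),
    )
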