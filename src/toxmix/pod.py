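"""Points of departure from group comparisons.

Replicate (dish) means are the statistical unit: a one-way ANOVA across
groups followed by Tukey-corrected pairwise comparisons of each treatment
against the control gives the significance pattern from which the NOAEL
(highest dose with no significant effect below the LOAEL) and LOAEL
(lowest significant dose) are read off.  Designs often fail to bracket
these, so each POD carries a bounded/unbounded qualifier: significance
already at the lowest dose leaves the LOAEL unbounded from below, and no
significance anywhere leaves the NOAEL unbounded from above.  Ratios of
qualified PODs propagate the inequality direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthetic import ENDPOINT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "PairwiseResult",
    "POD",
    "PODSet",
    "RelPotencyEstimate",
    "replicate_means",
    "anova_pairwise",
    "derive_noael_loael",
    "pod_ratio",
    "BOUNDED",
    "UNBOUNDED_HIGH",
    "UNBOUNDED_LOW",
]

BOUNDED = "bounded"
UNBOUNDED_HIGH = "unbounded_high"  # true value above the reported dose (">")
UNBOUNDED_LOW = "unbounded_low"    # true value below the reported dose ("<")

#: rate endpoints computed over all embryos rather than survivors
RATE_ENDPOINTS = {"mortality": "alive", "hatch": "hatched"}


@dataclass(frozen=True)
class GroupComparison:
    group: str
    diff: float          # treatment mean - control mean (replicate means)
    p_adj: float
    significant: bool


@dataclass
class PairwiseResult:
    """ANOVA + Tukey control-vs-treatment contrasts for one endpoint."""

    endpoint: str
    control: str
    comparisons: list[GroupComparison]
    anova_f: float
    anova_p: float
    alpha: float
    zero_variance: bool = False


@dataclass(frozen=True)
class POD:
    """A point of departure with its bounding qualifier."""

    value: float
    qualifier: str  # bounded | unbounded_high | unbounded_low

    def __post_init__(self):
        if self.qualifier not in (BOUNDED, UNBOUNDED_HIGH, UNBOUNDED_LOW):
            raise ValueError(f"unknown qualifier {self.qualifier!r}")

    @property
    def prefix(self) -> str:
        """Inequality prefix for reporting: '<', '>' or ''."""
        return {BOUNDED: "", UNBOUNDED_HIGH: ">", UNBOUNDED_LOW: "<"}[self.qualifier]


@dataclass
class PODSet:
    endpoint: str
    noael: POD | None
    loael: POD | None
    noael_group: str | None = None
    loael_group: str | None = None
    nonmonotonic: bool = False


@dataclass(frozen=True)
class RelPotencyEstimate:
    """Ratio of two qualified PODs with the propagated inequality."""

    numerator: POD
    denominator: POD
    ratio: float
    qualifier: str  # exact | upper_bound | lower_bound | indeterminate


def replicate_means(table: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Per-replicate summary of one endpoint, long form.

    Continuous endpoints (BL/SBA/YSA) are averaged over surviving fish in
    each dish; ``mortality`` and ``hatch`` are per-dish proportions over
    all embryos.  Empty dishes (no survivors) yield a missing mean and a
    logged warning.
    """
    if endpoint in ENDPOINT_COLUMNS:
        col = ENDPOINT_COLUMNS[endpoint]
        alive = table[table["alive"].astype(bool)]
        out = (alive.groupby(["treatment", "replicate"], sort=False)[col]
               .mean().rename("value").reset_index())
        # reinstate replicates that lost every fish, as missing means
        full = (table.groupby(["treatment", "replicate"], sort=False)
                .size().rename("n").reset_index()[["treatment", "replicate"]])
        out = full.merge(out, on=["treatment", "replicate"], how="left")
        n_empty = int(out["value"].isna().sum())
        if n_empty:
            logger.warning("%d replicate(s) had no surviving fish for %s", n_empty, endpoint)
        return out
    if endpoint in RATE_ENDPOINTS:
        col = RATE_ENDPOINTS[endpoint]
        flags = table[col].astype(bool)
        if endpoint == "mortality":
            flags = ~flags
        tmp = table.assign(value=flags.astype(float))
        return (tmp.groupby(["treatment", "replicate"], sort=False)["value"]
                .mean().reset_index())
    raise ValueError(
        f"unknown endpoint {endpoint!r}; expected one of "
        f"{sorted(ENDPOINT_COLUMNS) + sorted(RATE_ENDPOINTS)}"
    )


def anova_pairwise(rep_means: pd.DataFrame, alpha: float = 0.05,
                   control: str | None = None,
                   endpoint: str = "") -> PairwiseResult:
    """One-way ANOVA on replicate means plus Tukey HSD control contrasts.

    ``rep_means`` is the long-form output of :func:`replicate_means`; the
    control defaults to the first treatment label in table order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    data = rep_means.dropna(subset=["value"])
    labels = list(dict.fromkeys(rep_means["treatment"]))
    if control is None:
        control = labels[0]
    counts = data.groupby("treatment").size()
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 replicate means each")

    groups = [data.loc[data["treatment"] == g, "value"].to_numpy() for g in labels]
    if all(np.ptp(g) == 0 for g in groups):
        logger.warning("zero within-group variance everywhere; p-values undefined")
        comps = [GroupComparison(g, float(np.mean(v) - np.mean(groups[0])),
                                 float("nan"), False)
                 for g, v in zip(labels[1:], groups[1:])]
        return PairwiseResult(endpoint, control, comps, float("nan"), float("nan"),
                              alpha, zero_variance=True)

    f_stat, f_p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(data["value"].to_numpy(),
                              data["treatment"].to_numpy(), alpha=alpha)
    pair_p = {
        frozenset((tukey.groupsunique[i], tukey.groupsunique[j])): p
        for (i, j), p in zip(
            ((i, j) for i in range(len(tukey.groupsunique))
             for j in range(i + 1, len(tukey.groupsunique))),
            tukey.pvalues)
    }
    ctrl_mean = float(np.mean(groups[0]))
    comps = []
    for g, vals in zip(labels[1:], groups[1:]):
        p = float(pair_p[frozenset((control, g))])
        comps.append(GroupComparison(g, float(np.mean(vals) - ctrl_mean), p, p < alpha))
    return PairwiseResult(endpoint, control, comps, float(f_stat), float(f_p), alpha)


def derive_noael_loael(pairwise: PairwiseResult,
                       group_doses: Mapping[str, float]) -> PODSet:
    """Read the NOAEL/LOAEL off a significance pattern.

    Groups must be supplied in increasing dose order via ``group_doses``.
    The LOAEL is the lowest significant dose; the NOAEL the highest dose
    below it.  Significance at the lowest dose leaves the LOAEL unbounded
    from below (no NOAEL); no significance anywhere makes the top dose an
    unbounded NOAEL (no LOAEL).  A significant group above a
    non-significant higher dose is logged as non-monotonic.
    """
    doses = [group_doses[c.group] for c in pairwise.comparisons]
    if any(b < a for a, b in zip(doses, doses[1:])):
        raise ValueError("group_doses must be non-decreasing in comparison order")
    sig = [c.significant for c in pairwise.comparisons]
    nonmono = any(s and not t for s, t in zip(sig, sig[1:]))
    if nonmono:
        logger.warning("non-monotonic significance pattern for %s: %s",
                       pairwise.endpoint or "endpoint", sig)

    if not any(sig):
        top = pairwise.comparisons[-1]
        return PODSet(pairwise.endpoint, POD(group_doses[top.group], UNBOUNDED_HIGH),
                      None, noael_group=top.group, nonmonotonic=nonmono)
    first = next(i for i, s in enumerate(sig) if s)
    loael_cmp = pairwise.comparisons[first]
    if first == 0:
        return PODSet(pairwise.endpoint, None,
                      POD(group_doses[loael_cmp.group], UNBOUNDED_LOW),
                      loael_group=loael_cmp.group, nonmonotonic=nonmono)
    noael_cmp = pairwise.comparisons[first - 1]
    return PODSet(pairwise.endpoint,
                  POD(group_doses[noael_cmp.group], BOUNDED),
                  POD(group_doses[loael_cmp.group], BOUNDED),
                  noael_group=noael_cmp.group, loael_group=loael_cmp.group,
                  nonmonotonic=nonmono)


#: ratio-qualifier algebra: (numerator, denominator) -> result.  A "<"
#: numerator or ">" denominator pushes the ratio down (upper bound) and
#: vice versa; agreeing directions cancel into indeterminacy.
_RATIO_QUALIFIER = {
    (BOUNDED, BOUNDED): "exact",
    (UNBOUNDED_LOW, BOUNDED): "upper_bound",
    (BOUNDED, UNBOUNDED_HIGH): "upper_bound",
    (UNBOUNDED_LOW, UNBOUNDED_HIGH): "upper_bound",
    (UNBOUNDED_HIGH, BOUNDED): "lower_bound",
    (BOUNDED, UNBOUNDED_LOW): "lower_bound",
    (UNBOUNDED_HIGH, UNBOUNDED_LOW): "lower_bound",
    (UNBOUNDED_LOW, UNBOUNDED_LOW): "indeterminate",
    (UNBOUNDED_HIGH, UNBOUNDED_HIGH): "indeterminate",
}


def pod_ratio(pod_num: POD, pod_den: POD) -> RelPotencyEstimate:
    """Ratio of two PODs with inequality-qualifier propagation."""
    if pod_num.value <= 0 or pod_den.value <= 0:
        raise ValueError("PODs must be strictly positive")
    return RelPotencyEstimate(
        pod_num, pod_den, pod_num.value / pod_den.value,
        _RATIO_QUALIFIER[(pod_num.qualifier, pod_den.qualifier)],
    )
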