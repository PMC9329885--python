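"""Mixture interaction analysis: index-chemical dose balance, isoboles
and response additivity.

Two additivity conventions are implemented and named explicitly:

* **Dose addition** (Loewe): an isobole is the straight line joining the
  single-chemical doses that each alone produce a given response level;
  mixtures plotting below the line respond more than additively
  (synergism), above it less (antagonism).
* **Response addition**: the predicted mixture response is the sum of
  each component's predicted response at its concentration in the
  mixture, floored at zero per component and capped at 100% in total.

The five-step balance procedure expresses the mixture result on the index
chemical's dose scale: at each response level, (1) the index-alone dose,
(2) the index dose implied by the mixture-experiment fit, (3) their
difference — the index-equivalent dose attributable to the co-chemical,
(4) the co-chemical dose implied by the mixture fit, and (5) the relative
potency as balance / co-dose.  A non-positive balance means the mixture
needed *more* index chemical than the component study at the same
response — an antagonistic signal — and is flagged rather than ratioed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .drmodels import LinearDRFit
from .potency import (BELOW_INTERCEPT, OK, DEFAULT_RESPONSE_GRID, DoseSolution,
                      dose_at_response, percent_response)

__all__ = [
    "BalanceRow",
    "IsoboleLine",
    "InteractionCall",
    "equivalent_dose_balance",
    "isobole",
    "classify_point",
    "response_additivity_table",
    "balance_table",
    "observed_percent_response",
    "ANTAGONISTIC",
]

ANTAGONISTIC = "antagonistic"


@dataclass(frozen=True)
class BalanceRow:
    """One response level of the five-step balance table."""

    level: float
    dose_index_alone: DoseSolution
    dose_index_mix: DoseSolution
    balance: float  # NaN unless flag == "ok"
    dose_co_mix: DoseSolution
    rp_index_co: float  # balance / co dose
    rp_co_index: float
    flag: str  # "ok" | "below_intercept" | "antagonistic"


@dataclass(frozen=True)
class IsoboleLine:
    """Additivity line for one response level.

    The segment joining ``(x_intercept, 0)`` — index chemical alone — and
    ``(0, y_intercept)`` — co-chemical alone — holds every dose-additive
    combination producing the level.
    """

    level: float
    x_intercept: float
    y_intercept: float


@dataclass(frozen=True)
class InteractionCall:
    """Response-additivity verdict for one observed mixture point."""

    dose_index: float
    dose_co: float
    observed: float
    predicted: float
    deviation: float  # observed - predicted
    call: str  # "additive" | "synergistic" | "antagonistic"


def equivalent_dose_balance(fit_index_alone: LinearDRFit,
                            fit_index_mix: LinearDRFit,
                            fit_co_mix: LinearDRFit,
                            grid: Iterable[float] = DEFAULT_RESPONSE_GRID
                            ) -> list[BalanceRow]:
    """Run the five-step index-equivalent dose balance over a response grid."""
    rows: list[BalanceRow] = []
    for level in grid:
        d_alone = dose_at_response(fit_index_alone, level)
        d_mix = dose_at_response(fit_index_mix, level)
        d_co = dose_at_response(fit_co_mix, level)
        if not (d_alone.ok and d_mix.ok and d_co.ok):
            rows.append(BalanceRow(level, d_alone, d_mix, float("nan"), d_co,
                                   float("nan"), float("nan"), BELOW_INTERCEPT))
            continue
        balance = d_alone.dose - d_mix.dose
        if balance <= 0:
            rows.append(BalanceRow(level, d_alone, d_mix, float("nan"), d_co,
                                   float("nan"), float("nan"), ANTAGONISTIC))
            continue
        rows.append(BalanceRow(level, d_alone, d_mix, balance, d_co,
                               balance / d_co.dose, d_co.dose / balance, OK))
    return rows


def isobole(fit_index_alone: LinearDRFit, fit_co_alone: LinearDRFit,
            level: float) -> IsoboleLine | None:
    """Dose-addition isobole endpoints at one response level.

    Returns ``None`` when either component's line cannot reach the level
    from a positive dose (below-intercept), i.e. no isobole exists.
    """
    dx = dose_at_response(fit_index_alone, level)
    dy = dose_at_response(fit_co_alone, level)
    if not (dx.ok and dy.ok):
        return None
    return IsoboleLine(level, dx.dose, dy.dose)


def classify_point(point: tuple[float, float, float],
                   fit_index: LinearDRFit, fit_co: LinearDRFit,
                   tolerance: float = 0.05,
                   baseline: str = "control_mean") -> InteractionCall:
    """Compare an observed mixture response with its response-additive
    prediction from the component fits.

    ``point`` is ``(index dose, co dose, observed response fraction)``.
    The additive prediction sums each component's percent response at its
    dose, flooring each at 0 and capping the sum at 1.  An observed
    response above the prediction by more than ``tolerance`` is called
    synergistic (the point lies below its isobole), below it
    antagonistic, otherwise additive.

    ``baseline`` selects the reference for percent response: the observed
    control mean (default) or each fit's intercept (``"intercept"``),
    which treats the fitted line's own dose-0 prediction as zero response.
    """
    dose_i, dose_c, observed = point
    if dose_i < 0 or dose_c < 0:
        raise ValueError("doses must be >= 0")
    if baseline not in ("control_mean", "intercept"):
        raise ValueError("baseline must be 'control_mean' or 'intercept'")
    if baseline == "intercept":
        fit_index = LinearDRFit.from_params(fit_index.a, fit_index.b, fit_index.a)
        fit_co = LinearDRFit.from_params(fit_co.a, fit_co.b, fit_co.a)
    pred = max(percent_response(fit_index, dose_i), 0.0) + \
        max(percent_response(fit_co, dose_c), 0.0)
    pred = min(pred, 1.0)
    dev = observed - pred
    if dev > tolerance:
        call = "synergistic"
    elif dev < -tolerance:
        call = "antagonistic"
    else:
        call = "additive"
    return InteractionCall(dose_i, dose_c, observed, pred, dev, call)


def response_additivity_table(fit_index_alone: LinearDRFit,
                              fit_co_alone: LinearDRFit,
                              mixture_regimen: Sequence[tuple[str, float, float]],
                              observed_responses: Mapping[str, float]
                              ) -> pd.DataFrame:
    """Per-group response-addition check for a binary-mixture regimen.

    ``mixture_regimen`` lists ``(group label, index conc, co conc)``;
    ``observed_responses`` maps labels to observed response fractions.
    Each component's predicted response comes from its component-study fit
    at its concentration in the mixture; the sum (capped at 1) is compared
    with the observation and flagged when it overpredicts.
    """
    records = []
    for entry in mixture_regimen:
        if len(entry) != 3:
            raise ValueError(f"regimen entry {entry!r} must be (label, index conc, co conc)")
        label, ci, cc = entry
        if ci is None or cc is None:
            raise ValueError(f"group {label!r} is missing a concentration")
        if label not in observed_responses:
            raise ValueError(f"no observed response for group {label!r}")
        p_i = percent_response(fit_index_alone, float(ci))
        p_c = percent_response(fit_co_alone, float(cc))
        pred = min(max(p_i, 0.0) + max(p_c, 0.0), 1.0)
        obs = float(observed_responses[label])
        records.append(
            {
                "group": label,
                "conc_index_ugL": float(ci),
                "conc_co_ugL": float(cc),
                "pred_index": p_i,
                "pred_co": p_c,
                "pred_sum": pred,
                "observed": obs,
                "overpredicted": pred > obs,
            }
        )
    return pd.DataFrame.from_records(records)


def observed_percent_response(table: pd.DataFrame, endpoint_column: str,
                              control_label: str | None = None) -> dict[str, float]:
    """Observed response fraction per group from a measurement table.

    The response is ``1 - group mean / control mean`` over surviving fish,
    matching the convention used for fitted curves.  ``control_label``
    defaults to the first treatment label in table order.
    """
    alive = table[table["alive"].astype(bool)]
    means = alive.groupby("treatment", sort=False)[endpoint_column].mean()
    if control_label is None:
        control_label = table["treatment"].iloc[0]
    r0 = means[control_label]
    return {label: float(1.0 - m / r0) for label, m in means.items()}


def balance_table(rows: Sequence[BalanceRow], index_name: str = "index",
                  co_name: str = "co") -> pd.DataFrame:
    """Tidy frame of an equivalent_dose_balance result."""
    return pd.DataFrame(
        {
            "response": [r.level for r in rows],
            f"{index_name}_alone_ugL": [r.dose_index_alone.dose for r in rows],
            f"{index_name}_in_mix_ugL": [r.dose_index_mix.dose for r in rows],
            "balance_ugL": [r.balance for r in rows],
            f"{co_name}_in_mix_ugL": [r.dose_co_mix.dose for r in rows],
            f"{index_name}/{co_name}": [r.rp_index_co for r in rows],
            f"{co_name}/{index_name}": [r.rp_co_index for r in rows],
            "flag": [r.flag for r in rows],
        }
    )
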