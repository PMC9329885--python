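"""Full-curve relative potency from linear dose-response fits.

Percent response is defined against the observed control mean:
``response(D) = 1 - (a + b * D) / R0``, i.e. the fractional reduction in
the endpoint mean relative to unexposed controls.  Inverting the line
gives the dose at any response level, ``D = (R0 * (1 - p) - a) / b``, and
the ratio of two chemicals' iso-effective doses traces how relative
potency varies with the response level instead of collapsing it to a
single point of departure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .drmodels import LinearDRFit

__all__ = [
    "DoseSolution",
    "RPRow",
    "percent_response",
    "dose_at_response",
    "rp_curve",
    "rp_limit",
    "rp_table",
    "DEFAULT_RESPONSE_GRID",
]

#: default response-level grid: 20% to 90% in 10-point steps
DEFAULT_RESPONSE_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.2, 0.95, 0.1), 2))

OK = "ok"
BELOW_INTERCEPT = "below_intercept"


@dataclass(frozen=True)
class DoseSolution:
    """Dose solving a response level, or a typed reason it has none.

    ``below_intercept`` means the requested response is shallower than the
    model's prediction at dose zero (the fitted line starts below the
    control mean), so no positive dose attains it.
    """

    dose: float
    status: str = OK

    @property
    def ok(self) -> bool:
        return self.status == OK


@dataclass(frozen=True)
class RPRow:
    """One response level of a relative-potency table."""

    level: float
    dose_index: DoseSolution
    dose_co: DoseSolution
    ratio_index_co: float  # index dose / co dose
    ratio_co_index: float
    status: str


def percent_response(fit: LinearDRFit, dose: float) -> float:
    """Fractional reduction from the control mean at ``dose``.

    May be negative when the predicted response exceeds the control mean
    (e.g. at dose 0 for a fit whose intercept sits above ``R0``).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not np.isfinite(fit.R0) or fit.R0 == 0:
        raise ValueError("control mean R0 must be finite and nonzero")
    return 1.0 - (fit.a + fit.b * dose) / fit.R0


def dose_at_response(fit: LinearDRFit, level: float) -> DoseSolution:
    """Invert the linear fit at a fractional response level in (0, 1)."""
    if not 0.0 < level < 1.0:
        raise ValueError("response level must lie strictly between 0 and 1")
    if fit.b == 0:
        raise ValueError("slope is zero: the model never attains the response")
    if not np.isfinite(fit.R0) or fit.R0 == 0:
        raise ValueError("control mean R0 must be finite and nonzero")
    dose = (fit.R0 * (1.0 - level) - fit.a) / fit.b
    if dose <= 0:
        return DoseSolution(float("nan"), BELOW_INTERCEPT)
    return DoseSolution(float(dose))


def rp_curve(fit_index: LinearDRFit, fit_co: LinearDRFit,
             grid: Iterable[float] = DEFAULT_RESPONSE_GRID) -> list[RPRow]:
    """Iso-effective doses and their ratios over a grid of response levels.

    Ratios are computed only where both chemicals attain the level; rows
    where either dose falls below its model's intercept carry the
    ``below_intercept`` status and NaN ratios.
    """
    rows: list[RPRow] = []
    for level in grid:
        di = dose_at_response(fit_index, level)
        dc = dose_at_response(fit_co, level)
        if di.ok and dc.ok:
            rows.append(RPRow(level, di, dc, di.dose / dc.dose, dc.dose / di.dose, OK))
        else:
            rows.append(RPRow(level, di, dc, float("nan"), float("nan"), BELOW_INTERCEPT))
    return rows


def rp_limit(fit_index: LinearDRFit, fit_co: LinearDRFit) -> float:
    """High-response limit of the co/index dose ratio.

    As the response level approaches 100% the iso-effective doses tend to
    the x-intercepts of the two lines, so the ratio converges to
    ``(a_co / |b_co|) / (a_index / |b_index|)``.  Defined for declining
    responses (both slopes negative).
    """
    if fit_index.b >= 0 or fit_co.b >= 0:
        raise ValueError("rp_limit requires strictly negative slopes")
    return (fit_co.a / abs(fit_co.b)) / (fit_index.a / abs(fit_index.b))


def rp_table(rows: Sequence[RPRow], index_name: str = "index",
             co_name: str = "co") -> pd.DataFrame:
    """Tidy frame of an rp_curve result (one row per response level)."""
    return pd.DataFrame(
        {
            "response": [r.level for r in rows],
            f"dose_{index_name}_ugL": [r.dose_index.dose for r in rows],
            f"dose_{co_name}_ugL": [r.dose_co.dose for r in rows],
            f"{index_name}/{co_name}": [r.ratio_index_co for r in rows],
            f"{co_name}/{index_name}": [r.ratio_co_index for r in rows],
            "status": [r.status for r in rows],
        }
    )
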