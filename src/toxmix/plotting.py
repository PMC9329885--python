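"""Optional matplotlib figures (isoboles, relative-potency curves).

Imported lazily so the core library has no hard matplotlib dependency.
"""

from __future__ import annotations

from typing import Sequence

from .drmodels import LinearDRFit
from .mixture import IsoboleLine
from .potency import RPRow


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_isoboles(lines: Sequence[IsoboleLine], points=None, ax=None,
                  index_label: str = "index chemical (µg/L)",
                  co_label: str = "co-chemical (µg/L)"):
    """Draw dose-addition isoboles and, optionally, observed mixture points.

    Points below a line respond more than additively (synergism), points
    above it less (antagonism).
    """
    ax = _axes(ax)
    for line in lines:
        ax.plot([line.x_intercept, 0.0], [0.0, line.y_intercept],
                label=f"{line.level:.0%} response")
    if points is not None:
        xs, ys = zip(*points)
        ax.plot(xs, ys, "ko", label="observed mixtures")
    ax.set_xlabel(index_label)
    ax.set_ylabel(co_label)
    ax.legend()
    return ax


def plot_rp_curve(rows: Sequence[RPRow], ax=None):
    """Relative potency (co/index dose ratio) versus response level."""
    ax = _axes(ax)
    ok = [r for r in rows if r.status == "ok"]
    ax.plot([r.level for r in ok], [r.ratio_co_index for r in ok], "o-")
    ax.set_xlabel("response level (fraction reduction from control mean)")
    ax.set_ylabel("co/index dose ratio")
    return ax


def plot_dr_fit(fit: LinearDRFit, ax=None, endpoint_label: str = "response"):
    """Scatter the fitted data (if retained) with the fitted line."""
    import numpy as np
    ax = _axes(ax)
    if fit.doses is not None:
        ax.plot(fit.doses, fit.responses, ".", alpha=0.4)
        grid = np.linspace(fit.doses.min(), fit.doses.max(), 100)
    else:
        grid = np.linspace(0.0, fit.a / abs(fit.b) if fit.b else 1.0, 100)
    ax.plot(grid, fit.predict(grid), "r-")
    ax.set_xlabel("dose (µg/L)")
    ax.set_ylabel(endpoint_label)
    return ax
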