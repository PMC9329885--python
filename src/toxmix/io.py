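"""Readers, writers, unit conversion and report formatting.

Concentrations are stored and computed in ug/L throughout; micromolar
values are a display conversion only.  All writers produce CSV/YAML that
their paired readers round-trip exactly.
"""

from __future__ import annotations

import hashlib
from importlib import metadata
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .drmodels import LinearDRFit
from .synthetic import (ENDPOINT_COLUMNS, MEASUREMENT_COLUMNS, EndpointTruth,
                        StudyDesign, TruthModel)

__all__ = [
    "read_measurements",
    "write_measurements",
    "convert_units",
    "concentration_ratio_report",
    "round_sig",
    "design_to_dict",
    "design_from_dict",
    "truth_to_dict",
    "truth_from_dict",
    "fits_from_config",
    "read_config",
    "write_config",
    "MeasurementValidationError",
]


class MeasurementValidationError(ValueError):
    """A measurement CSV failed validation; the message names the row."""


def read_measurements(path, known_treatments: Sequence[str] | None = None
                      ) -> pd.DataFrame:
    """Read and validate a per-fish measurement CSV.

    Requires the documented header; rejects negative endpoint values and
    (optionally) treatment labels outside ``known_treatments``, naming the
    offending row.  Missing endpoint values (dead fish) are permitted.
    """
    table = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise MeasurementValidationError(f"missing column(s): {', '.join(missing)}")
    table = table[MEASUREMENT_COLUMNS]
    for col in ("alive", "hatched"):
        table[col] = table[col].astype(bool)
    for col in ENDPOINT_COLUMNS.values():
        bad = table.index[table[col] < 0]
        if len(bad):
            raise MeasurementValidationError(
                f"negative {col} at row {int(bad[0]) + 2} of {path}"  # +2: header + 0-base
            )
    if known_treatments is not None:
        unknown = ~table["treatment"].isin(list(known_treatments))
        if unknown.any():
            row = int(table.index[unknown][0])
            raise MeasurementValidationError(
                f"unknown treatment {table['treatment'].iloc[row]!r} at row {row + 2} of {path}"
            )
    return table


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table as CSV (missing values as empty fields)."""
    table.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def convert_units(conc_ugL: float, molecular_weight: float) -> float:
    """ug/L -> uM given a molecular weight in ug per uMol."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc_ugL / molecular_weight


def concentration_ratio_report(design: StudyDesign, index: str, co: str
                               ) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Per-group co/index concentration ratios for a two-analyte regimen.

    Ratios are rounded to integers for reporting ("1:10 to 1:33" style);
    the returned range is (min, max) over dosed groups.  Groups with a
    zero index concentration are skipped.
    """
    records = []
    for label, concs in design.groups:
        ci, cc = concs.get(index, 0.0), concs.get(co, 0.0)
        if ci <= 0:
            continue
        records.append({"group": label, index: ci, co: cc,
                        "ratio": int(round(cc / ci))})
    if not records:
        raise ValueError("no groups with a nonzero index concentration")
    frame = pd.DataFrame.from_records(records)
    return frame, (int(frame["ratio"].min()), int(frame["ratio"].max()))


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (reporting precision)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(x, precision=digits, unique=False,
                                            fractional=False))


# ---------------------------------------------------------------------------
# structured config (YAML)
# ---------------------------------------------------------------------------

def design_to_dict(design: StudyDesign) -> dict:
    return {
        "name": design.name,
        "analytes": list(design.analytes),
        "groups": [{"label": label, "concentrations": dict(concs)}
                   for label, concs in design.groups],
        "n_replicates": design.n_replicates,
        "n_embryos_per_replicate": design.n_embryos_per_replicate,
        "endpoints": list(design.endpoints),
        "nominal": design.nominal,
    }


def design_from_dict(d: Mapping) -> StudyDesign:
    return StudyDesign(
        name=d["name"],
        analytes=tuple(d["analytes"]),
        groups=tuple((g["label"], dict(g["concentrations"])) for g in d["groups"]),
        n_replicates=int(d.get("n_replicates", 3)),
        n_embryos_per_replicate=int(d.get("n_embryos_per_replicate", 20)),
        endpoints=tuple(d.get("endpoints", ("BL", "SBA", "YSA"))),
        nominal=dict(d.get("nominal", {})),
    )


def truth_to_dict(truth: TruthModel) -> dict:
    return {
        "endpoints": {
            name: {"intercept": t.intercept, "slope": t.slope,
                   "noise_sd": t.noise_sd, "control_mean": t.control_mean}
            for name, t in truth.endpoints.items()
        },
        "potency_weights": dict(truth.potency_weights),
        "mortality": list(truth.mortality),
        "hatch": list(truth.hatch),
    }


def truth_from_dict(d: Mapping) -> TruthModel:
    return TruthModel(
        endpoints={name: EndpointTruth(**vals) for name, vals in d["endpoints"].items()},
        potency_weights=dict(d["potency_weights"]),
        mortality=tuple(d["mortality"]),
        hatch=tuple(d["hatch"]),
    )


def fits_from_config(d: Mapping[str, Mapping[str, float]]) -> dict[str, LinearDRFit]:
    """Build named linear fits from ``{name: {a, b, R0}}`` config entries,
    enabling exact reproduction of relative-potency tables from published
    parameter sets."""
    return {name: LinearDRFit.from_params(v["a"], v["b"], v["R0"])
            for name, v in d.items()}


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(obj: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=False)


def run_header(seed: int | None, config: Mapping | None = None) -> str:
    """Provenance comment block for report files: version, config hash, seed."""
    try:
        version = metadata.version("toxmix")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(dict(config or {}), sort_keys=True).encode()
    ).hexdigest()[:12]
    return f"# toxmix {version} | config {cfg_hash} | seed {seed}\n"


def write_report_csv(frame: pd.DataFrame, path, seed: int | None = None,
                     config: Mapping | None = None) -> None:
    """Write a report table with a provenance header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(run_header(seed, config))
        frame.to_csv(fh, index=False)
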