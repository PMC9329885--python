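import numpy as np
import pytest

from toxmix import (EndpointTruth, StudyDesign, TruthModel,
                    default_pfos_fts_designs, default_truth, generate_study)


@pytest.fixture(scope="session")
def designs():
    return default_pfos_fts_designs()


@pytest.fixture(scope="session")
def pfos_design(designs):
    return designs[0]


@pytest.fixture(scope="session")
def mixture_design(designs):
    return designs[2]


@pytest.fixture(scope="session")
def pfos_table(pfos_design):
    """One seeded synthetic PFOS component study."""
    return generate_study(pfos_design, default_truth(pfos_design), seed=20220725)


def truncated_design(design, n_groups=5):
    """Restrict a design to its lowest ``n_groups`` groups (the dose range
    over which the linear model is fitted)."""
    return StudyDesign(
        name=design.name + "_trunc",
        analytes=design.analytes,
        groups=design.groups[:n_groups],
        n_replicates=design.n_replicates,
        n_embryos_per_replicate=design.n_embryos_per_replicate,
        endpoints=design.endpoints,
    )


def sba_only_truth(design, a, b, sd, mortality=0.0):
    """Truth model exercising only the SBA endpoint with a given line."""
    n = design.n_groups
    return TruthModel(
        endpoints={
            "SBA": EndpointTruth(intercept=a, slope=b, noise_sd=sd),
            "BL": EndpointTruth(intercept=3.9, slope=-2e-5, noise_sd=0.15),
            "YSA": EndpointTruth(intercept=0.2, slope=1.5e-6, noise_sd=0.03),
        },
        potency_weights={an: 1.0 for an in design.analytes},
        mortality=tuple([mortality] * n),
        hatch=tuple([0.9] * n),
    )


def pooled_sba(table, design, analyte):
    """Per-fish (dose, SBA) arrays over surviving fish — the fitting input."""
    dose_of = dict(zip(design.labels, design.doses(analyte)))
    alive = table[table["alive"]].dropna(subset=["SBA_mm2"])
    return (alive["treatment"].map(dose_of).to_numpy(dtype=float),
            alive["SBA_mm2"].to_numpy(dtype=float))


@pytest.fixture(scope="session")
def linear_study():
    """Seeded five-group linear SBA study used by BMD/bootstrap checks."""
    pfos, _, _ = default_pfos_fts_designs()
    design = truncated_design(pfos)  # T0..T4: line stays well above zero
    truth = sba_only_truth(design, a=0.04563, b=-6.45e-6, sd=0.013)
    table = generate_study(design, truth, seed=42)
    doses, responses = pooled_sba(table, design, "PFOS")
    return design, truth, doses, responses
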