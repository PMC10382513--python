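"""Shared fixtures: simulated datasets and reduced sampler budgets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import caresae as cs
from caresae.direct_estimation import build_direct_dataset
from caresae.metrics import ItemDefinition, score_facility_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# reduced budgets: module-level tests never need 1000 retained draws
FAST = cs.SamplerConfig(n_warmup=600, n_samples=1500, n_draws=500)
MEDIUM = cs.SamplerConfig(n_warmup=1000, n_samples=4000, n_draws=1000)


def readiness_dataset(config: cs.SimConfig, years=None):
    """Simulate, score readiness, and build the stage-2 ModelData."""
    sim = cs.simulate_dataset(config)
    fac = sim["facility_table"]
    definition = ItemDefinition(
        tuple(c[len("item_"):] for c in fac.columns if c.startswith("item_"))
    )
    fac_metrics = score_facility_table(fac, definition)
    direct = build_direct_dataset(fac_metrics)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = cs.build_model_data(
            direct, sim["covariates"], sim["graph"], metric="readiness",
            years=years or config.years,
        )
    return sim, direct, data


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across read-only tests."""
    return cs.simulate_dataset(cs.SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_readiness():
    """(sim, direct, ModelData) for the default study conditions."""
    return readiness_dataset(cs.SimConfig(seed=42))


@pytest.fixture(scope="session")
def fitted_m7(default_readiness):
    """An M7 fit on the default dataset, shared by summary-level tests."""
    _, _, data = default_readiness
    draws, diag = cs.fit_model(cs.ModelSpec.from_id(7), data, MEDIUM, seed=5)
    return draws, diag


def tiny_direct_frame():
    """A small hand-checkable direct-estimate table: 3 areas x 2 years x 2
    surveys on a path graph, with one unusable cell."""
    rows = []
    rng = np.random.default_rng(7)
    for a in range(3):
        for t, year in enumerate((2015, 2016)):
            for s in ("svy_a", "svy_b"):
                rows.append({
                    "area_id": a, "year": year, "survey_id": s,
                    "metric": "readiness",
                    "p_hat": 0.5, "var_p": 0.01, "n": 5, "n_strata": 1,
                    "y_logit": rng.normal(scale=0.8),
                    "var_logit": float(rng.uniform(0.05, 0.3)),
                    "usable": True, "boundary_corrected": False,
                })
    rows[-1]["usable"] = False
    return pd.DataFrame(rows)


def tiny_model_data(use_x=True):
    direct = tiny_direct_frame()
    adj = cs.AdjacencyGraph.from_edges([(0, 1), (1, 2)], areas=[0, 1, 2])
    cov = None
    if use_x:
        rng = np.random.default_rng(3)
        cov = pd.DataFrame({
            "area_id": np.repeat([0, 1, 2], 2),
            "year": [2015, 2016] * 3,
            "x1": rng.normal(size=6),
        })
    return cs.build_model_data(direct, cov, adj, metric="readiness")
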