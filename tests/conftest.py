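"""Shared fixtures: scaled-down trial configurations and one fitted
pipeline reused across test modules.

The small configuration keeps the full structure of the default study
conditions (stepped wedge, nine subgroups, hurdle resource use) at a
size where mixed-model fits take well under a second.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from plgfcea import costing, psa, resource_models, synthetic_trial


@pytest.fixture(scope="session")
def default_config():
    return synthetic_trial.load_config()


@pytest.fixture(scope="session")
def small_config(default_config):
    cfg = copy.deepcopy(default_config)
    cfg["design"] = {
        "n_clusters": 6,
        "n_steps": 7,
        "cluster_weights": [3000, 4200, 5200, 6100, 7400, 9000],
    }
    cfg["enrolment"] = {"usual": 140, "revealed": 180}
    cfg["model"] = {"candidates": ["two_part_truncNB"], "n_quad": 7}
    cfg["psa"] = dict(cfg["psa"], iterations=400)
    return cfg


def single_cell_config(base, **overrides):
    """Point-mass subgroup configuration (everyone PlGF>100 x normal),
    used by recovery and oracle tests where a small covariate set keeps
    the likelihood landscape simple."""
    cfg = copy.deepcopy(base)
    cfg["subgroups"]["plgf_marginals"] = {"gt100": 1.0, "12to100": 0.0, "lt12": 0.0}
    cfg["subgroups"]["diagnosis_given_plgf"]["gt100"] = {
        "normal": 1.0,
        "GH_CHT_SGA": 0.0,
        "preeclampsia": 0.0,
    }
    for key, value in overrides.items():
        cfg[key] = value
    return cfg


@pytest.fixture(scope="session")
def small_records(small_config):
    return synthetic_trial.simulate_trial(small_config, seed=11)


@pytest.fixture(scope="session")
def unit_table():
    return costing.load_unit_costs()


@pytest.fixture(scope="session")
def pipeline_means(small_records):
    means, info = resource_models.fit_all_categories(
        small_records, candidates=("two_part_truncNB",)
    )
    return means


@pytest.fixture(scope="session")
def psa_result(pipeline_means, small_records, unit_table):
    config = psa.PSAConfig(n_iterations=2000, seed=5)
    weights = psa.subgroup_weights(small_records)
    return psa.run_psa(
        pipeline_means, unit_table, psa.AdverseEventInput(), config, weights
    )
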