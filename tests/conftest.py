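"""Shared fixtures: one synthetic study, built once per session."""

from __future__ import annotations

import pytest

import coexmark as cm


@pytest.fixture(scope="session")
def sim_config() -> cm.SimulationConfig:
    return cm.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """(normal, cancer, truth) for the default synthetic study, seed 1."""
    return cm.simulate_expression(sim_config)


@pytest.fixture(scope="session")
def built(sim_config, sim_data):
    """Everything downstream of the generator for the seed-1 study."""
    normal, cancer, truth = sim_data
    functional = cm.simulate_functional_network(truth, sim_config)
    filtered = cm.filter_functional_network(functional, min_score=500)
    status_n = cm.coexpression_status(normal)
    status_c = cm.coexpression_status(cancer)
    specific = cm.build_specific_network(status_n, status_c, filtered)
    modules = cm.filter_modules(cm.partition_network(specific, seed=1), min_size=5)
    results = cm.select_specific_modules(modules, normal, cancer)
    scores = cm.score_genes(results, modules, specific)
    return {
        "config": sim_config,
        "normal": normal,
        "cancer": cancer,
        "truth": truth,
        "functional": functional,
        "filtered": filtered,
        "status_normal": status_n,
        "status_cancer": status_c,
        "specific": specific,
        "modules": modules,
        "results": results,
        "scores": scores,
    }
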