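from types import SimpleNamespace

import pytest

from oncnet import (
    GeneratorConfig,
    PlantedTruth,
    build_incidence,
    generate_encounters,
    generate_population,
    project_sharing_graph,
)

from _util import worked_example_linchpin_graph, worked_example_team


@pytest.fixture()
def fig_linchpin_graph():
    return worked_example_linchpin_graph()


@pytest.fixture()
def fig_team():
    return worked_example_team()


@pytest.fixture(scope="session")
def world():
    """One moderately sized synthetic claims world shared across tests.

    Small enough to build in a few seconds, large enough that the sharing
    graph, exposure measures and both treatment cohorts are non-trivial.
    """
    cfg = GeneratorConfig(n_patients=1500, n_hrrs=6)
    truth = PlantedTruth(seed=7)
    population = generate_population(cfg, 7)
    encounters, assignments = generate_encounters(population, truth, cfg, 8)
    incidence = build_incidence(encounters, population.patients)
    graph = project_sharing_graph(incidence, physician_attrs=population.physicians)
    return SimpleNamespace(
        cfg=cfg, truth=truth, population=population, encounters=encounters,
        assignments=assignments, incidence=incidence, graph=graph,
    )
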