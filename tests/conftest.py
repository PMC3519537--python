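from __future__ import annotations

import pytest

from signet import fixtures, solve


@pytest.fixture(scope="session")
def core_graph():
    return fixtures.build_iis_tor_core()


@pytest.fixture(scope="session")
def toy():
    """(graph, facts) of the three-node A -> B -| C example."""
    return fixtures.build_toy()


@pytest.fixture(scope="session")
def experiment_answers(core_graph):
    """{name: (facts, answer)} for the four longevity experiments."""
    result = {}
    for name in fixtures.EXPERIMENT_NAMES:
        facts = fixtures.build_experiment(name, graph=core_graph)
        result[name] = (facts, solve(core_graph, facts))
    return result
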