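"""Path enumeration, phenotype prediction, classification, shortest paths."""

from __future__ import annotations

import random

import pytest

from signet import (
    EdgeSign,
    NodeState,
    PathClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    PhenotypeValue,
    SignalPath,
    classify_path,
    enumerate_signal_paths,
    predicted_phenotype_of,
    shortest_paths,
    solve,
)
from signet.fixtures import random_signed_graph
from signet.model import NodeKind
from signet.paths import PathError

from oracles import enumerate_paths_bruteforce, facts_from_states

A = NodeState.ACTIVE
I = NodeState.INACTIVE


def steps_of(paths):
    return {p.steps for p in paths if not p.impaired}


class TestEnumerationOnExperiments:
    def test_adaptor_knockout_primary_route(self, core_graph, experiment_answers):
        facts, answer = experiment_answers["chico"]
        enumeration = enumerate_signal_paths(core_graph, answer, facts)
        expected = (
            ("chico", I), ("Pi3K", I), ("Akt1", I), ("foxo", A), ("longevity", A)
        )
        assert expected in steps_of(enumeration.paths)
        assert not enumeration.truncated

    def test_autophagy_kinase_feedback_route(self, core_graph, experiment_answers):
        facts, answer = experiment_answers["Lnk"]
        enumeration = enumerate_signal_paths(core_graph, answer, facts)
        expected = (
            ("Atg1", A), ("S6k", I), ("chico", A), ("Pi3K", A),
            ("Akt1", A), ("foxo", I), ("longevity", I),
        )
        assert expected in steps_of(enumeration.paths)

    def test_start_without_route_yields_no_complete_path(self):
        graph = PathwayGraph(
            nodes=[PathwayNode("A"), PathwayNode("B"),
                   PathwayNode("P", kind=NodeKind.PHENOTYPE)],
            edges=[PathwayEdge("B", "P", EdgeSign.ACTIVATES)],
        )
        facts = facts_from_states({"A": A})
        enumeration = enumerate_signal_paths(graph, solve(graph, facts), facts)
        assert enumeration.paths == []

    def test_missing_phenotype_node_is_an_error(self, toy):
        graph, facts = toy
        answer = solve(graph, facts)
        with pytest.raises(PathError, match="phenotype"):
            enumerate_signal_paths(graph, answer, facts)

    def test_every_step_obeys_the_parity_rule(self, core_graph, experiment_answers):
        edge_signs = {
            (e.source, e.target, e.sign) for e in core_graph.edges
        }
        for facts, answer in experiment_answers.values():
            enumeration = enumerate_signal_paths(
                core_graph, answer, facts, include_impaired=True
            )
            for path in enumeration.paths:
                for (n1, s1), (n2, s2) in zip(path.steps, path.steps[1:]):
                    flipped = s2 is not s1
                    sign = EdgeSign.INHIBITS if flipped else EdgeSign.ACTIVATES
                    assert (n1, n2, sign) in edge_signs


class TestEnumerationOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_networkx_simple_path_filtering(self, seed):
        rng = random.Random(4000 + seed)
        graph = random_signed_graph(seed, n_nodes=8, edge_probability=0.3,
                                    inhibit_fraction=0.4)
        nodes = sorted(graph.node_ids - {"phen"})
        fixed = {
            n: rng.choice([A, I]) for n in rng.sample(nodes, 3)
        }
        facts = facts_from_states(fixed)
        answer = solve(graph, facts)
        enumeration = enumerate_signal_paths(graph, answer, facts)
        assert steps_of(enumeration.paths) == enumerate_paths_bruteforce(
            graph, answer, facts
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_truncation_flag_iff_cap_exceeded(self, seed):
        rng = random.Random(5000 + seed)
        graph = random_signed_graph(seed, n_nodes=7, edge_probability=0.45,
                                    inhibit_fraction=0.3)
        nodes = sorted(graph.node_ids - {"phen"})
        facts = facts_from_states({n: rng.choice([A, I]) for n in rng.sample(nodes, 2)})
        answer = solve(graph, facts)
        full = enumerate_signal_paths(graph, answer, facts)
        total = len(full.paths)
        if total == 0:
            pytest.skip("no complete path in this draw")
        capped = enumerate_signal_paths(graph, answer, facts, max_paths=total)
        assert not capped.truncated and len(capped.paths) == total
        tight = enumerate_signal_paths(
            graph, answer, facts, max_paths=max(1, total - 1)
        )
        assert tight.truncated == (total > 1)


class TestClassification:
    def test_primary_supports_observation(self, core_graph, experiment_answers):
        facts, _ = experiment_answers["chico"]
        path = SignalPath(steps=(
            ("chico", I), ("Pi3K", I), ("Akt1", I), ("foxo", A), ("longevity", A)
        ))
        assert classify_path(path, facts) is PathClass.PRIMARY

    def test_de_route_contradicting_observation_is_negative_feedback(
        self, experiment_answers
    ):
        facts, _ = experiment_answers["chico"]
        path = SignalPath(steps=(
            ("Ilp2", A), ("InR", A), ("Lnk", A), ("Pi3K", A),
            ("Akt1", A), ("foxo", I), ("longevity", I),
        ))
        assert classify_path(path, facts) is PathClass.NEGATIVE_FEEDBACK

    def test_de_route_supporting_observation_is_positive_feedback(
        self, experiment_answers
    ):
        facts, _ = experiment_answers["foxo"]
        path = SignalPath(steps=(
            ("Pk61C", A), ("Akt1", A), ("foxo", I), ("longevity", I)
        ))
        assert classify_path(path, facts) is PathClass.POSITIVE_FEEDBACK

    def test_blocked_chain_is_impaired(self, core_graph, experiment_answers):
        facts, answer = experiment_answers["foxo"]
        enumeration = enumerate_signal_paths(
            core_graph, answer, facts, include_impaired=True
        )
        blocked = [
            p for p in enumeration.paths
            if p.impaired and p.start == "Ilp3" and p.blocked_at == "foxo"
        ]
        assert blocked, "down-regulated ILP chain should be disrupted at foxo"
        for path in blocked:
            assert classify_path(path, facts) is PathClass.IMPAIRED
            assert path.steps[-1] == ("foxo", A)
            assert path.predicted_phenotype is None

    def test_perturbed_start_contradicting_observation_flagged(self):
        graph = PathwayGraph(
            nodes=[PathwayNode("g"), PathwayNode("P", kind=NodeKind.PHENOTYPE)],
            edges=[PathwayEdge("g", "P", EdgeSign.ACTIVATES)],
        )
        facts = facts_from_states({"g": I})  # observed long_lived
        answer = solve(graph, facts)
        (path,) = enumerate_signal_paths(graph, answer, facts).paths
        assert classify_path(path, facts) is PathClass.INCONSISTENT_PRIMARY

    def test_unattributable_start_is_an_error(self, experiment_answers):
        facts, _ = experiment_answers["chico"]
        rogue = SignalPath(steps=(("wdb", I), ("Akt1", A)))
        with pytest.raises(PathError, match="wdb"):
            classify_path(rogue, facts)

    def test_phenotype_prediction_mapping(self):
        assert predicted_phenotype_of(A) is PhenotypeValue.LONG_LIVED
        assert predicted_phenotype_of(I) is PhenotypeValue.SHORT_LIVED
        assert predicted_phenotype_of(A) is not predicted_phenotype_of(I)


class TestShortestPaths:
    def test_single_path_is_its_own_minimum(self, experiment_answers):
        facts, _ = experiment_answers["chico"]
        path = SignalPath(steps=(
            ("chico", I), ("Pi3K", I), ("Akt1", I), ("foxo", A), ("longevity", A)
        ))
        result = shortest_paths([path], facts)
        assert result == {("chico", PathClass.PRIMARY): [path]}

    def test_agrees_with_bruteforce_minimum(self, core_graph, experiment_answers):
        for facts, answer in experiment_answers.values():
            complete = [
                p for p in enumerate_signal_paths(core_graph, answer, facts).paths
                if not p.impaired
            ]
            result = shortest_paths(complete, facts)
            for (start, cls), group in result.items():
                rivals = [
                    p for p in complete
                    if p.start == start and classify_path(p, facts) is cls
                ]
                minimum = min(len(p) for p in rivals)
                assert {p.steps for p in group} == {
                    p.steps for p in rivals if len(p) == minimum
                }

    def test_ties_are_all_retained_in_order(self, core_graph, experiment_answers):
        facts, answer = experiment_answers["InR"]
        complete = [
            p for p in enumerate_signal_paths(core_graph, answer, facts).paths
            if not p.impaired
        ]
        primaries = shortest_paths(complete, facts)[("InR", PathClass.PRIMARY)]
        assert [p.nodes for p in primaries] == sorted(p.nodes for p in primaries)
        assert len(primaries) == 2
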