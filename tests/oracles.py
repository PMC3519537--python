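"""Independent reference implementations used to cross-check the package.

Each oracle recomputes a result by a different route than the library:
bounded-iteration walk closure instead of a worklist fixpoint, networkx
simple-path enumeration plus filtering instead of guided DFS, and
exhaustive substring enumeration instead of dynamic programming.
"""

from __future__ import annotations

import random

import networkx as nx

from signet import (
    Direction,
    EdgeSign,
    ExperimentFacts,
    NodeState,
    Perturbation,
    PerturbationKind,
    PathwayGraph,
    PhenotypeValue,
    RelationAtom,
)


def facts_from_states(states: dict[str, NodeState]) -> ExperimentFacts:
    """Wrap an arbitrary fixed-state assignment as experiment facts.

    The lexicographically first node becomes the perturbation (knockout
    for inactive, overexpression for active); the rest are encoded as DE
    directions.  ``ExperimentFacts.fixed_states()`` recovers exactly
    ``states``.
    """
    ordered = sorted(states)
    first = ordered[0]
    kind = (
        PerturbationKind.KNOCKOUT
        if states[first] is NodeState.INACTIVE
        else PerturbationKind.OVEREXPRESSION
    )
    de = {
        node: (Direction.UP if states[node] is NodeState.ACTIVE else Direction.DOWN)
        for node in ordered[1:]
    }
    return ExperimentFacts(
        perturbations=frozenset({Perturbation(first, kind)}),
        de_states=de,
        observed_phenotype=PhenotypeValue.LONG_LIVED,
    )


def walk_closure(graph: PathwayGraph, fixed: dict[str, NodeState]):
    """States reachable by signal walks of length <= 2*|nodes|.

    Naive bounded iteration over the full edge set — no worklist — so it
    is an independent route to the same closure the engine computes.
    Returns (atoms, achievable, impairment_points).
    """
    rounds = 2 * len(graph) + 1
    achievable: dict[str, set[NodeState]] = {n: set() for n in graph.node_ids}
    for node, state in fixed.items():
        achievable[node].add(state)
    atoms: set[RelationAtom] = set()
    impairments: set[tuple[str, NodeState]] = set()
    edges = list(graph.edges)
    for _ in range(rounds):
        for edge in edges:
            for state in list(achievable[edge.source]):
                conferred = (
                    state if edge.sign is EdgeSign.ACTIVATES else state.flip()
                )
                if edge.target in fixed and fixed[edge.target] is conferred.flip():
                    impairments.add((edge.target, conferred))
                    continue
                atoms.add(RelationAtom(edge.source, edge.target, conferred))
                achievable[edge.target].add(conferred)
    return atoms, achievable, impairments


def solve_shuffled(graph: PathwayGraph, facts: ExperimentFacts, rng: random.Random):
    """Fixpoint with randomised propagation order (stack, shuffled edges)."""
    fixed = facts.fixed_states()
    achievable: dict[str, set[NodeState]] = {n: set() for n in graph.node_ids}
    atoms: set[RelationAtom] = set()
    stack = list(fixed.items())
    rng.shuffle(stack)
    for node, state in fixed.items():
        achievable[node].add(state)
    edges_by_source: dict[str, list] = {}
    for edge in graph.edges:
        edges_by_source.setdefault(edge.source, []).append(edge)
    while stack:
        source, state = stack.pop(rng.randrange(len(stack)))
        out = list(edges_by_source.get(source, []))
        rng.shuffle(out)
        for edge in out:
            conferred = state if edge.sign is EdgeSign.ACTIVATES else state.flip()
            if edge.target in fixed and fixed[edge.target] is conferred.flip():
                continue
            atoms.add(RelationAtom(source, edge.target, conferred))
            if conferred not in achievable[edge.target]:
                achievable[edge.target].add(conferred)
                stack.append((edge.target, conferred))
    return atoms


def enumerate_paths_bruteforce(graph: PathwayGraph, answer, facts):
    """All complete signal paths via networkx simple-path enumeration.

    Enumerates every simple node sequence from each start to the
    phenotype node with nx.all_simple_paths, assigns states by sign
    parity from the seed, and keeps sequences whose every step's relation
    atom was derived.  Returns a set of step tuples.
    """
    digraph = nx.DiGraph()
    digraph.add_nodes_from(graph.node_ids)
    signs: dict[tuple[str, str], set[EdgeSign]] = {}
    for edge in graph.edges:
        digraph.add_edge(edge.source, edge.target)
        signs.setdefault((edge.source, edge.target), set()).add(edge.sign)

    fixed = facts.fixed_states()
    phenotype = graph.phenotype_node
    found: set[tuple[tuple[str, NodeState], ...]] = set()
    for start, seed in fixed.items():
        if start == phenotype or not nx.has_path(digraph, start, phenotype):
            continue
        for node_path in nx.all_simple_paths(digraph, start, phenotype):
            # expand over the sign choices of each consecutive pair
            partial = [[(start, seed)]]
            for source, target in zip(node_path, node_path[1:]):
                extended = []
                for steps in partial:
                    state = steps[-1][1]
                    for sign in signs[(source, target)]:
                        conferred = (
                            state if sign is EdgeSign.ACTIVATES else state.flip()
                        )
                        if RelationAtom(source, target, conferred) in answer.atoms:
                            extended.append(steps + [(target, conferred)])
                partial = extended
            for steps in partial:
                found.add(tuple(steps))
    return found


def contains_run(tokens: tuple, run: tuple) -> bool:
    return any(
        tokens[i : i + len(run)] == run for i in range(len(tokens) - len(run) + 1)
    )


def lcs_pair_bruteforce(a: tuple, b: tuple) -> set[tuple]:
    """All maximal common contiguous runs (>= 2 tokens) of two sequences."""
    candidates = {
        a[i:j] for i in range(len(a)) for j in range(i + 2, len(a) + 1)
    }
    common = {run for run in candidates if contains_run(b, run)}
    if not common:
        return set()
    best = max(len(run) for run in common)
    return {run for run in common if len(run) == best}
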