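"""Sign-consistency inference on a signed pathway graph.

Given the graph and an experiment's fact base, the engine derives every
``activates``/``inactivates`` relation that can be realised by a chain of
signalling starting from the experimentally fixed nodes.  The semantics is
per-route signal flow, not steady state: a free node may be achievable in
both states through different routes, and only experimentally fixed nodes
are single-valued.  Propagation follows one rule —

    state(target) = state(source)            if the edge activates
    state(target) = flipped state(source)    if the edge inhibits

— subject to one integrity constraint: a signal may not confer on a fixed
node the opposite of its fixed state.  Where that happens the chain stops
and the blocked ``(node, state)`` pair is recorded as an impairment point
(e.g. a knocked-out transcription factor can never be driven active, so
any chain that needs it active is disrupted there).

The closure is a least fixpoint over the ``(node, state)`` product space,
so it is unique, independent of propagation order, and loop-safe even in
cyclic pathways.  Under these semantics every solvable experiment has
exactly one consistent answer set.
"""

from __future__ import annotations

from collections import deque

from .engine_types import AnswerSet, NodeState, RelationAtom
from .experiments import ExperimentFacts
from .model import EdgeSign, PathwayGraph


class InferenceError(ValueError):
    """Raised when the fact base cannot be solved against the graph."""


def solve(graph: PathwayGraph, facts: ExperimentFacts) -> AnswerSet:
    """Compute the unique answer set for ``facts`` on ``graph``.

    Raises
    ------
    InferenceError
        If the facts fix no node at all, or fix a node absent from the
        graph.
    """
    fixed = facts.fixed_states()
    if not fixed:
        raise InferenceError("no fixed states: nothing to propagate from")
    node_ids = graph.node_ids
    unknown = sorted(set(fixed) - node_ids)
    if unknown:
        raise InferenceError(
            "fixed states reference nodes absent from the graph: "
            + ", ".join(unknown)
        )

    adjacency = graph.adjacency()
    achievable: dict[str, set[NodeState]] = {n: set() for n in node_ids}
    atoms: set[RelationAtom] = set()
    impairments: set[tuple[str, NodeState]] = set()

    worklist: deque[tuple[str, NodeState]] = deque(sorted(fixed.items()))
    for node, state in fixed.items():
        achievable[node].add(state)

    while worklist:
        source, state = worklist.popleft()
        for edge in adjacency.get(source, ()):
            conferred = (
                state if edge.sign is EdgeSign.ACTIVATES else state.flip()
            )
            blocked = (
                edge.target in fixed and fixed[edge.target] is conferred.flip()
            )
            if blocked:
                impairments.add((edge.target, conferred))
                continue
            atoms.add(RelationAtom(source, edge.target, conferred))
            if conferred not in achievable[edge.target]:
                achievable[edge.target].add(conferred)
                worklist.append((edge.target, conferred))

    return AnswerSet(
        atoms=frozenset(atoms),
        achievable={n: frozenset(s) for n, s in achievable.items()},
        impairment_points=frozenset(impairments),
    )


def count_answer_sets(graph: PathwayGraph, facts: ExperimentFacts) -> int:
    """Number of distinct consistent answer sets for the experiment.

    The least-fixpoint closure is unique, so this is 1 whenever
    :func:`solve` succeeds.  An empty fact base (no fixed states) is the
    recoverable degenerate case and yields 0; structural errors still
    raise.
    """
    if not facts.fixed_states():
        return 0
    solve(graph, facts)
    return 1


def relations_from(answer: AnswerSet, node: str) -> frozenset[RelationAtom]:
    """All derived relations whose source is ``node``.

    Raises ``KeyError`` for a node outside the solved graph.
    """
    if node not in answer.achievable:
        raise KeyError(f"unknown node {node!r}")
    return frozenset(a for a in answer.atoms if a.source == node)
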