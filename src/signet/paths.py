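"""Signalling-path enumeration and classification.

Every perturbed or differentially expressed component is a potential
signal source.  This module enumerates all simple paths (no repeated
nodes) from each such start — seeded with its experimentally fixed state —
to the phenotype node, stepping only along relations present in the
answer set.  Each complete path predicts a phenotype from the state it
confers on the phenotype node (active → long-lived, inactive →
short-lived) and is classified against the observed phenotype:

* ``primary`` — starts at a perturbed gene and supports the observed
  phenotype (the direct effect of the intervention);
* ``inconsistent_primary`` — starts at a perturbed gene but contradicts
  the observation, flagging model/data inconsistency;
* ``negative_feedback`` — starts at a DE-only gene and contradicts the
  observation (transcription pushing back against the intervention);
* ``positive_feedback`` — starts at a DE-only gene and supports it;
* ``impaired`` — a chain disrupted because a component's fixed state
  contradicts the state the signal would need (reported on request).

Cycles in the pathway are handled implicitly: a loop's edges appear
across different simple paths, so nothing is lost by forbidding node
repetition, and the enumeration stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .engine_types import AnswerSet, NodeState, RelationAtom
from .experiments import ExperimentFacts, PhenotypeValue
from .model import EdgeSign, PathwayGraph

#: Default cap on the number of enumerated paths.
DEFAULT_MAX_PATHS = 100_000


class PathClass(str, Enum):
    PRIMARY = "primary"
    NEGATIVE_FEEDBACK = "negative_feedback"
    POSITIVE_FEEDBACK = "positive_feedback"
    IMPAIRED = "impaired"
    INCONSISTENT_PRIMARY = "inconsistent_primary"


class PathError(ValueError):
    """Raised on malformed path queries (e.g. no phenotype node)."""


def predicted_phenotype_of(state: NodeState) -> PhenotypeValue:
    """Phenotype implied by the phenotype node's state at the path end."""
    return (
        PhenotypeValue.LONG_LIVED
        if state is NodeState.ACTIVE
        else PhenotypeValue.SHORT_LIVED
    )


@dataclass(frozen=True)
class SignalPath:
    """An ordered chain of (node, state) steps realising one signal."""

    steps: tuple[tuple[str, NodeState], ...]
    impaired: bool = False
    blocked_at: str | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a signal path needs at least one step")
        if self.impaired and self.blocked_at is None:
            raise ValueError("impaired paths must name their blocking node")

    @property
    def start(self) -> str:
        return self.steps[0][0]

    @property
    def end(self) -> tuple[str, NodeState]:
        return self.steps[-1]

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(node for node, _ in self.steps)

    @property
    def predicted_phenotype(self) -> PhenotypeValue | None:
        """Phenotype the path predicts; ``None`` for impaired chains."""
        if self.impaired:
            return None
        return predicted_phenotype_of(self.steps[-1][1])

    def render(self) -> str:
        """Human-readable ``node(state) -> node(state) -> ...`` form."""
        return " -> ".join(f"{n}({s.value})" for n, s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class PathEnumeration:
    """Result of a path search: the paths plus a truncation flag."""

    paths: list[SignalPath]
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def enumerate_signal_paths(
    graph: PathwayGraph,
    answer: AnswerSet,
    facts: ExperimentFacts,
    max_paths: int = DEFAULT_MAX_PATHS,
    include_impaired: bool = False,
) -> PathEnumeration:
    """All simple signal paths from perturbed/DE starts to the phenotype.

    Each start is seeded with its fixed state; every step must correspond
    to a relation atom in ``answer`` (so only signals the engine derived
    are walked).  With ``include_impaired`` the maximal prefixes stopped
    at a contradicting fixed node are reported too, ending at the blocking
    node with the state the signal would have conferred.

    Enumeration halts with ``truncated=True`` once ``max_paths`` paths
    have been collected.
    """
    if graph.phenotype_node is None:
        raise PathError("graph has no phenotype node")
    if max_paths < 1:
        raise ValueError("max_paths must be positive")

    fixed = facts.fixed_states()
    adjacency = graph.adjacency()
    atoms = answer.atoms
    phenotype = graph.phenotype_node

    collected: list[SignalPath] = []
    truncated = False

    def dfs(steps: list[tuple[str, NodeState]], visited: set[str]) -> bool:
        """Depth-first extension; returns False once the cap is hit."""
        nonlocal truncated
        node, state = steps[-1]
        if node == phenotype:
            if len(collected) >= max_paths:
                truncated = True
                return False
            collected.append(SignalPath(steps=tuple(steps)))
            return True
        for edge in adjacency.get(node, ()):
            target = edge.target
            if target in visited:
                continue
            conferred = (
                state if edge.sign is EdgeSign.ACTIVATES else state.flip()
            )
            blocked = target in fixed and fixed[target] is conferred.flip()
            if blocked:
                if include_impaired:
                    if len(collected) >= max_paths:
                        truncated = True
                        return False
                    collected.append(
                        SignalPath(
                            steps=tuple(steps) + ((target, conferred),),
                            impaired=True,
                            blocked_at=target,
                        )
                    )
                continue
            if RelationAtom(node, target, conferred) not in atoms:
                continue
            visited.add(target)
            steps.append((target, conferred))
            ok = dfs(steps, visited)
            steps.pop()
            visited.remove(target)
            if not ok:
                return False
        return True

    for start in sorted(set(fixed)):
        if start == phenotype:
            continue
        if not dfs([(start, fixed[start])], {start}):
            break

    collected.sort(key=lambda p: (p.start, p.nodes, p.impaired))
    return PathEnumeration(paths=collected, truncated=truncated)


def classify_path(path: SignalPath, facts: ExperimentFacts) -> PathClass:
    """Assign the path its effect class relative to the observed phenotype."""
    if path.impaired:
        return PathClass.IMPAIRED
    observed = facts.observed_phenotype
    if observed is None:
        raise PathError("facts carry no observed phenotype to classify against")
    predicted = path.predicted_phenotype
    if path.start in facts.perturbed_genes:
        return (
            PathClass.PRIMARY
            if predicted is observed
            else PathClass.INCONSISTENT_PRIMARY
        )
    if path.start in facts.de_states:
        return (
            PathClass.POSITIVE_FEEDBACK
            if predicted is observed
            else PathClass.NEGATIVE_FEEDBACK
        )
    raise PathError(
        f"path start {path.start!r} is neither perturbed nor differentially "
        "expressed"
    )


def shortest_paths(
    paths: Iterable[SignalPath],
    facts: ExperimentFacts,
) -> dict[tuple[str, PathClass], list[SignalPath]]:
    """Minimal-length paths per (start node, class), ties all retained.

    Output lists are deterministically ordered by node-id sequence.
    """
    grouped: dict[tuple[str, PathClass], list[SignalPath]] = {}
    for path in paths:
        key = (path.start, classify_path(path, facts))
        grouped.setdefault(key, []).append(path)
    result: dict[tuple[str, PathClass], list[SignalPath]] = {}
    for key, group in sorted(grouped.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        minimum = min(len(p) for p in group)
        winners = [p for p in group if len(p) == minimum]
        winners.sort(key=lambda p: p.nodes)
        result[key] = winners
    return result
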