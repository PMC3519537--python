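"""Signed directed pathway graphs.

A pathway is a directed graph whose nodes are proteins, complexes,
transcription factors or abstract processes, and whose edges carry a sign:
``activates`` (the source, when active, activates the target) or
``inhibits`` (the source, when active, inhibits the target).  At most one
node — the phenotype node, e.g. FOXO-mediated longevity — marks the
endpoint of signalling; it never has outgoing edges.

Graphs are deliberately permissive at construction time: invalid structures
can be built and then inspected with :meth:`PathwayGraph.validate`, which
reports violations as data rather than raising.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class NodeKind(str, Enum):
    """Biological role of a pathway node."""

    PROTEIN = "protein"
    COMPLEX = "complex"
    TRANSCRIPTION_FACTOR = "transcription_factor"
    PROCESS = "process"
    PHENOTYPE = "phenotype"


class EdgeSign(str, Enum):
    """Qualitative effect of the source on the target."""

    ACTIVATES = "activates"
    INHIBITS = "inhibits"


def default_kind(node_id: str) -> NodeKind:
    """Kind assigned to an undeclared node: complexes are named ``c_*``."""
    return NodeKind.COMPLEX if node_id.startswith("c_") else NodeKind.PROTEIN


@dataclass(frozen=True)
class PathwayNode:
    """A node of the signalling network."""

    id: str
    label: str = ""
    kind: NodeKind = NodeKind.PROTEIN

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True, order=True)
class PathwayEdge:
    """A signed directed interaction between two nodes."""

    source: str
    target: str
    sign: EdgeSign


class GraphFormatError(ValueError):
    """Raised when an input document cannot be parsed at all."""


class GraphValidationError(ValueError):
    """Raised when a parsed document violates graph semantics."""


class PathwayGraph:
    """A signed directed signalling network with an optional phenotype node.

    Parameters
    ----------
    nodes :
        Iterable of :class:`PathwayNode`.
    edges :
        Iterable of :class:`PathwayEdge`; endpoints should name declared
        nodes (checked by :meth:`validate`, not at construction).
    phenotype_node :
        Id of the phenotype endpoint, or ``None``.  If ``None`` and exactly
        one node has kind ``phenotype``, that node is used.
    """

    def __init__(
        self,
        nodes: Iterable[PathwayNode] = (),
        edges: Iterable[PathwayEdge] = (),
        phenotype_node: str | None = None,
    ) -> None:
        self._nodes: list[PathwayNode] = list(nodes)
        self._edges: list[PathwayEdge] = list(edges)
        if phenotype_node is None:
            marked = [n.id for n in self._nodes if n.kind is NodeKind.PHENOTYPE]
            if len(marked) == 1:
                phenotype_node = marked[0]
        self.phenotype_node = phenotype_node

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[PathwayNode, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[PathwayEdge, ...]:
        return tuple(self._edges)

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n.id for n in self._nodes)

    def node(self, node_id: str) -> PathwayNode:
        for n in self._nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def __contains__(self, node_id: str) -> bool:
        return any(n.id == node_id for n in self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def add_node(self, node: PathwayNode) -> None:
        self._nodes.append(node)

    def add_edge(self, edge: PathwayEdge) -> None:
        self._edges.append(edge)

    def successors(self, node_id: str) -> Iterator[PathwayEdge]:
        """Outgoing edges of ``node_id`` in deterministic (sorted) order."""
        return iter(sorted(e for e in self._edges if e.source == node_id))

    def adjacency(self) -> dict[str, tuple[PathwayEdge, ...]]:
        """Outgoing-edge map with deterministically sorted edge lists."""
        adj: dict[str, list[PathwayEdge]] = {n.id: [] for n in self._nodes}
        for e in sorted(self._edges):
            adj.setdefault(e.source, []).append(e)
        return {k: tuple(v) for k, v in adj.items()}

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Check every structural invariant; return one message per violation.

        An empty list means the graph is valid.  Violations are returned,
        never raised, so callers can collect and report them all at once.
        """
        violations: list[str] = []
        ids = [n.id for n in self._nodes]
        for node_id, count in Counter(ids).items():
            if count > 1:
                violations.append(f"duplicate node id {node_id!r}")
        for n in self._nodes:
            if not n.id:
                violations.append("node with empty id")
        phenos = [n.id for n in self._nodes if n.kind is NodeKind.PHENOTYPE]
        if len(phenos) > 1:
            violations.append(
                "more than one phenotype node: " + ", ".join(sorted(phenos))
            )
        known = set(ids)
        for e in self._edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    violations.append(
                        f"edge {e.source}-[{e.sign.value}]->{e.target} "
                        f"references unknown node {endpoint!r}"
                    )
        for triple, count in Counter(self._edges).items():
            if count > 1:
                violations.append(
                    f"duplicate edge {triple.source}-[{triple.sign.value}]->"
                    f"{triple.target}"
                )
        if self.phenotype_node is not None:
            if self.phenotype_node not in known:
                violations.append(
                    f"phenotype node {self.phenotype_node!r} is not declared"
                )
            for e in self._edges:
                if e.source == self.phenotype_node:
                    violations.append(
                        "phenotype node has outgoing edge "
                        f"{e.source}-[{e.sign.value}]->{e.target}"
                    )
        return violations

    def require_valid(self) -> "PathwayGraph":
        """Raise :class:`GraphValidationError` on the first invalid graph."""
        violations = self.validate()
        if violations:
            raise GraphValidationError("; ".join(violations))
        return self

    # -- comparison --------------------------------------------------------

    def structurally_equal(self, other: "PathwayGraph") -> bool:
        """Id-, kind- and sign-preserving equality (order-insensitive)."""
        return (
            {(n.id, n.kind) for n in self._nodes}
            == {(n.id, n.kind) for n in other._nodes}
            and set(self._edges) == set(other._edges)
            and self.phenotype_node == other.phenotype_node
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathwayGraph({len(self._nodes)} nodes, {len(self._edges)} edges, "
            f"phenotype={self.phenotype_node!r})"
        )
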