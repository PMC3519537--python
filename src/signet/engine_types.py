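"""Value types shared by the inference engine and its consumers."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping


class NodeState(str, Enum):
    """Qualitative activity of a pathway component."""

    ACTIVE = "active"
    INACTIVE = "inactive"

    def flip(self) -> "NodeState":
        return NodeState.INACTIVE if self is NodeState.ACTIVE else NodeState.ACTIVE


def flip(state: NodeState) -> NodeState:
    """Involution exchanging active and inactive."""
    return state.flip()


@dataclass(frozen=True, order=True)
class RelationAtom:
    """A derived signalling relation: ``source`` confers ``result_state`` on
    ``target`` through one graph edge.

    The atom's label follows the relation vocabulary of the logic encoding:
    ``activates(source,target)`` when the conferred state is active,
    ``inactivates(source,target)`` otherwise.
    """

    source: str
    target: str
    result_state: NodeState

    @property
    def label(self) -> str:
        verb = (
            "activates" if self.result_state is NodeState.ACTIVE else "inactivates"
        )
        return f"{verb}({self.source},{self.target})"


@dataclass(frozen=True)
class AnswerSet:
    """The unique consistent closure of signal propagation.

    Attributes
    ----------
    atoms :
        All derivable :class:`RelationAtom`; closed under the propagation
        rule (least fixpoint).
    achievable :
        For every graph node, the set of states some signal chain can put
        it in.  Experimentally fixed nodes are achievable only in their
        fixed state; free nodes may be achievable in both states via
        different routes.
    impairment_points :
        ``(node, blocked_state)`` pairs where propagation wanted to confer
        ``blocked_state`` on a node whose fixed state contradicts it; the
        signal is disrupted there.
    """

    atoms: frozenset[RelationAtom]
    achievable: Mapping[str, frozenset[NodeState]]
    impairment_points: frozenset[tuple[str, NodeState]]
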