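"""Longest common sub-path mining across signalling paths.

Distinct signals frequently share long segments — e.g. three different
insulin-like peptides triggering the same receptor cascade down to the
phenotype.  Comparing whole paths misses this, because the starts differ.
Here every path is tokenised into a sequence of ``node:state`` tokens,
every unordered pair of paths is compared, and the maximal-length common
*contiguous* token runs of each pair are collected; each collected run is
then counted across all input paths.  Matching is per token, never per
character, so node names sharing prefixes (Ilp2 vs Ilp25) can never
produce spurious matches.

A sub-path must span at least two tokens — one relation — to be
reportable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .engine_types import NodeState
from .paths import SignalPath

Tokens = tuple[str, ...]


@dataclass(frozen=True)
class TokenPath:
    """A path as an ordered sequence of ``node:state`` tokens."""

    tokens: Tokens
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError(
                "a token path must contain at least one relation (2 tokens)"
            )

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SubPathCount:
    """A shared contiguous sub-path with its occurrence frequency."""

    tokens: Tokens
    frequency: int

    def render(self) -> str:
        parts = []
        for token in self.tokens:
            node, _, state = token.rpartition(":")
            parts.append(f"{node}({state})")
        return " -> ".join(parts)


def tokenize(path: SignalPath, provenance: str = "") -> TokenPath:
    """Turn a :class:`SignalPath` into its token sequence.

    A one-step path carries no relation and raises ``ValueError``.
    """
    if len(path) < 2:
        raise ValueError("cannot tokenize a path with fewer than 2 steps")
    return TokenPath(
        tokens=tuple(f"{node}:{state.value}" for node, state in path.steps),
        provenance=provenance,
    )


def detokenize(token_path: TokenPath) -> list[tuple[str, NodeState]]:
    """Recover the (node, state) sequence from a token path.

    States are encoded as the suffix after the *last* colon, so node ids
    themselves may contain colons.
    """
    steps = []
    for token in token_path.tokens:
        node, _, state = token.rpartition(":")
        steps.append((node, NodeState(state)))
    return steps


def longest_common_subpath_pair(a: TokenPath, b: TokenPath) -> set[Tokens]:
    """All maximal-length common contiguous token runs of two paths.

    Classic longest-common-substring dynamic programming over tokens,
    keeping *every* tied maximum.  Runs shorter than two tokens (no
    common relation) yield the empty set.
    """
    ta, tb = a.tokens, b.tokens
    best = 0
    hits: set[Tokens] = set()
    # dp[j] = length of common run ending at ta[i], tb[j]
    previous = [0] * (len(tb) + 1)
    for i, token in enumerate(ta):
        current = [0] * (len(tb) + 1)
        for j, other in enumerate(tb):
            if token == other:
                run = previous[j] + 1
                current[j + 1] = run
                if run > best:
                    best = run
                    hits = {ta[i - run + 1 : i + 1]}
                elif run == best:
                    hits.add(ta[i - run + 1 : i + 1])
        previous = current
    if best < 2:
        return set()
    return hits


def count_subpaths(paths: Sequence[TokenPath]) -> list[SubPathCount]:
    """Collect pairwise longest common sub-paths and count their carriers.

    Every unordered pair of input paths contributes its maximal common
    runs; each distinct run is then assigned the number of input paths
    that contain it contiguously.  The result is sorted by frequency
    (descending), then run length (descending), then lexicographically —
    so the most recurrent, longest shared routes come first.

    Raises ``ValueError`` with fewer than two input paths.
    """
    if len(paths) < 2:
        raise ValueError("sub-path mining needs at least two paths")
    collected: set[Tokens] = set()
    for a, b in combinations(paths, 2):
        collected |= longest_common_subpath_pair(a, b)
    counts = [
        SubPathCount(tokens=run, frequency=sum(1 for p in paths if _contains(p.tokens, run)))
        for run in collected
    ]
    counts.sort(key=lambda c: (-c.frequency, -len(c.tokens), c.tokens))
    return counts


def _contains(tokens: Tokens, run: Tokens) -> bool:
    """True if ``run`` occurs contiguously within ``tokens``."""
    n, m = len(tokens), len(run)
    return any(tokens[i : i + m] == run for i in range(n - m + 1))
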