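"""Deterministic plain-text reports and their parsers.

All reports are tab-separated with stable sort orders, so identical
inputs always produce byte-identical files and downstream tooling can
diff them.  Path reports can be parsed back into token paths, which lets
sub-path mining consume the reports of several experiments at once.
"""

from __future__ import annotations

import re
from typing import IO, Iterable, Mapping, Sequence

from .engine_types import AnswerSet, NodeState, RelationAtom
from .experiments import ExperimentFacts
from .paths import PathClass, SignalPath, classify_path
from .subpaths import SubPathCount, TokenPath

_STEP_RE = re.compile(r"^(?P<node>.+)\((?P<state>active|inactive)\)$")


# -- answer sets -----------------------------------------------------------

def render_answer_set(answer: AnswerSet, stream: IO) -> None:
    """Write the sorted atom table: label, source, target, result state."""
    for atom in sorted(answer.atoms):
        stream.write(
            f"{atom.label}\t{atom.source}\t{atom.target}\t"
            f"{atom.result_state.value}\n"
        )


def parse_answer_set(stream: IO) -> frozenset[RelationAtom]:
    """Read an atom table back into a set of relation atoms."""
    atoms = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
        _, source, target, state = parts
        atoms.add(RelationAtom(source, target, NodeState(state)))
    return frozenset(atoms)


# -- paths -----------------------------------------------------------------

def _path_row(experiment: str, path: SignalPath, facts: ExperimentFacts) -> str:
    cls = classify_path(path, facts)
    predicted = path.predicted_phenotype
    return "\t".join(
        (
            experiment,
            path.start,
            cls.value,
            predicted.value if predicted is not None else "-",
            str(len(path)),
            path.render(),
        )
    )


def render_path_report(
    experiment: str,
    paths: Iterable[SignalPath],
    facts: ExperimentFacts,
    stream: IO,
) -> int:
    """Write one classified row per path; returns the row count."""
    rows = [_path_row(experiment, p, facts) for p in paths]
    for row in rows:
        stream.write(row + "\n")
    return len(rows)


def render_shortest_report(
    experiment: str,
    shortest: Mapping[tuple[str, PathClass], Sequence[SignalPath]],
    facts: ExperimentFacts,
    stream: IO,
) -> int:
    """Write the shortest-paths-per-(start, class) table."""
    count = 0
    for (_, _), group in shortest.items():
        for path in group:
            stream.write(_path_row(experiment, path, facts) + "\n")
            count += 1
    return count


def parse_rendered_path(text: str) -> TokenPath:
    """Parse ``node(state) -> node(state) -> ...`` into a token path."""
    tokens = []
    for segment in text.split(" -> "):
        match = _STEP_RE.match(segment.strip())
        if match is None:
            raise ValueError(f"unparseable path step {segment!r}")
        tokens.append(f"{match['node']}:{match['state']}")
    return TokenPath(tokens=tuple(tokens))


def parse_path_report(stream: IO) -> list[TokenPath]:
    """Extract the token paths from a path report (complete paths only).

    Impaired rows (predicted phenotype ``-``) are skipped: disrupted
    chains are not signalling routes and do not enter sub-path mining.
    """
    token_paths = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        experiment, start, _cls, predicted, _length, rendered = parts
        if predicted == "-":
            continue
        token_path = parse_rendered_path(rendered)
        token_paths.append(
            TokenPath(tokens=token_path.tokens, provenance=f"{experiment}:{start}:{lineno}")
        )
    return token_paths


# -- sub-paths -------------------------------------------------------------

def render_subpath_report(counts: Sequence[SubPathCount], stream: IO) -> None:
    """Write frequency, length and rendering of each common sub-path."""
    for count in counts:
        stream.write(
            f"{count.frequency}\t{len(count.tokens)}\t{count.render()}\n"
        )
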