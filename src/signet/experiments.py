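"""Experiment descriptions: perturbations, differential expression, phenotype.

An experiment perturbs one or more genes (knockout, heterozygous knockout,
dominant negative, or overexpression), measures genome-wide transcription,
and records a discrete longevity phenotype (long-lived, short-lived,
unchanged).  This module turns those three ingredients into the fact base
consumed by the inference engine:

* perturbed genes receive a *fixed* activity state — loss-of-function
  perturbations fix the node inactive, overexpression fixes it active;
* differentially expressed (DE) genes — adjusted P below a cutoff
  (default 0.005) — are seeded active when up-regulated and inactive when
  down-regulated, on the premise that transcript levels qualitatively
  proxy protein availability;
* the observed phenotype is carried along for path classification.

The DE table itself is the output of a standard microarray linear-model
fit (moderated t-statistics with multiplicity-adjusted P-values); it is
read as-is and never recomputed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd

from .engine_types import NodeState
from .model import PathwayGraph

logger = logging.getLogger(__name__)

#: Default adjusted-P cutoff for calling a gene differentially expressed.
DEFAULT_DE_THRESHOLD = 0.005


class PerturbationKind(str, Enum):
    KNOCKOUT = "knockout"
    HETEROZYGOUS_KNOCKOUT = "heterozygous_knockout"
    DOMINANT_NEGATIVE = "dominant_negative"
    OVEREXPRESSION = "overexpression"


class PhenotypeValue(str, Enum):
    LONG_LIVED = "long_lived"
    SHORT_LIVED = "short_lived"
    UNCHANGED = "unchanged"


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class ExpressionRecord:
    """One row of a differential-expression table."""

    gene: str
    log_fold_change: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError(
                f"adjusted P for {self.gene!r} outside [0, 1]: {self.adjusted_p}"
            )


@dataclass(frozen=True)
class Perturbation:
    """A primary genetic intervention on one gene."""

    gene: str
    kind: PerturbationKind

    @property
    def fixed_state(self) -> NodeState:
        """Activity state the intervention imposes on the gene product."""
        if self.kind is PerturbationKind.OVEREXPRESSION:
            return NodeState.ACTIVE
        return NodeState.INACTIVE


class FactsError(ValueError):
    """Raised when an experiment description cannot be turned into facts."""


class TableFormatError(ValueError):
    """Raised when a DE table lacks a mandatory column."""


@dataclass(frozen=True)
class ExperimentFacts:
    """The fact base for one experiment, fed to the inference engine."""

    perturbations: frozenset[Perturbation]
    de_states: Mapping[str, Direction]
    observed_phenotype: PhenotypeValue | None
    de_threshold: float = DEFAULT_DE_THRESHOLD

    @property
    def perturbed_genes(self) -> frozenset[str]:
        return frozenset(p.gene for p in self.perturbations)

    def fixed_states(self) -> dict[str, NodeState]:
        """Node states imposed by perturbations and DE evidence.

        Perturbations win over DE entries, but :func:`build_facts` already
        guarantees the two sets are disjoint.
        """
        states: dict[str, NodeState] = {}
        for gene, direction in self.de_states.items():
            states[gene] = (
                NodeState.ACTIVE if direction is Direction.UP else NodeState.INACTIVE
            )
        for p in self.perturbations:
            states[p.gene] = p.fixed_state
        return states


def load_expression_table(
    stream: IO,
    gene_column: str = "gene",
    lfc_column: str = "logFC",
    p_column: str = "adj.P.Val",
) -> list[ExpressionRecord]:
    """Read a tab-separated DE table into :class:`ExpressionRecord` rows.

    Column names follow the conventional linear-model output layout but are
    configurable.  Rows with a missing adjusted P are dropped with a
    logged warning; a missing mandatory column is an error.
    """
    table = pd.read_csv(stream, sep="\t")
    for column in (gene_column, lfc_column, p_column):
        if column not in table.columns:
            raise TableFormatError(f"mandatory column {column!r} not in table")
    records: list[ExpressionRecord] = []
    n_dropped = 0
    # iterrows rather than itertuples: column names like "adj.P.Val" do not
    # survive namedtuple attribute mangling
    for _, row in table.iterrows():
        p_value = row[p_column]
        if pd.isna(p_value):
            n_dropped += 1
            continue
        records.append(
            ExpressionRecord(
                gene=str(row[gene_column]),
                log_fold_change=float(row[lfc_column]),
                adjusted_p=float(p_value),
            )
        )
    if n_dropped:
        logger.warning("dropped %d rows with missing adjusted P", n_dropped)
    return records


def select_de_genes(
    records: Iterable[ExpressionRecord],
    threshold: float = DEFAULT_DE_THRESHOLD,
    strict: bool = True,
) -> dict[str, Direction]:
    """Call DE genes at an adjusted-P cutoff and direction by fold-change sign.

    ``strict`` controls whether the comparison at the cutoff is
    ``adjusted_p < threshold`` (default) or ``<=``.  A gene surviving the
    cutoff with contradictory fold-change signs across rows is ambiguous
    evidence and raises :class:`FactsError`.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    selected: dict[str, Direction] = {}
    for record in records:
        passes = (
            record.adjusted_p < threshold
            if strict
            else record.adjusted_p <= threshold
        )
        if not passes:
            continue
        if record.log_fold_change == 0 or not math.isfinite(record.log_fold_change):
            raise FactsError(
                f"gene {record.gene!r} passes the cutoff but has "
                f"non-informative log fold-change {record.log_fold_change}"
            )
        direction = (
            Direction.UP if record.log_fold_change > 0 else Direction.DOWN
        )
        previous = selected.get(record.gene)
        if previous is not None and previous is not direction:
            raise FactsError(
                f"gene {record.gene!r} has conflicting DE directions at "
                f"threshold {threshold}"
            )
        selected[record.gene] = direction
    return selected


def build_facts(
    graph: PathwayGraph,
    perturbations: Iterable[Perturbation],
    de: Mapping[str, Direction],
    phenotype: PhenotypeValue | None,
    de_threshold: float = DEFAULT_DE_THRESHOLD,
) -> ExperimentFacts:
    """Assemble validated :class:`ExperimentFacts` against a pathway graph.

    DE genes missing from the graph are dropped with a warning (genome-wide
    tables always contain genes outside the pathway model); a perturbed
    gene missing from the graph is an error, as is an empty perturbation
    set — an experiment must have a primary intervention.  A gene that is
    both perturbed and DE keeps only its perturbation: the intervention is
    the stronger statement about its state.
    """
    perturbations = frozenset(perturbations)
    if not perturbations:
        raise FactsError("an experiment must declare at least one perturbation")
    node_ids = graph.node_ids
    for p in perturbations:
        if p.gene not in node_ids:
            raise FactsError(f"perturbed gene {p.gene!r} is not a pathway node")
    perturbed = {p.gene for p in perturbations}
    de_states: dict[str, Direction] = {}
    for gene, direction in de.items():
        if gene in perturbed:
            logger.info(
                "gene %r is perturbed; dropping its DE entry (%s)",
                gene, direction.value,
            )
            continue
        if gene not in node_ids:
            logger.warning("DE gene %r is not a pathway node; dropped", gene)
            continue
        de_states[gene] = direction
    return ExperimentFacts(
        perturbations=perturbations,
        de_states=de_states,
        observed_phenotype=phenotype,
        de_threshold=de_threshold,
    )
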