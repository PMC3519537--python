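"""Built-in worked examples and generators.

* :func:`build_toy` — the three-component teaching example (A induces B,
  B inhibits C; knocking out A leaves B inactivated and C activated by
  lack of inhibition).
* :func:`build_iis_tor_core` — a curated core of the *Drosophila*
  insulin/insulin-like signalling (IIS) pathway and its cross-talk with
  the TOR pathway: ILPs → INR → CHICO/LNK → PI3K → PDK1 (Pk61C) → AKT1 ⊣
  FOXO → longevity, plus the JNK branch (TAK1 → HEP → BSK → FOXO), the
  TOR couplings (L ⊣ TOR-C1 ⊣ TOR-C2 → AKT1, TSC ⊣ RHEB → TOR-C1,
  ATG1 ⊣ S6K ⊣ CHICO) and the modulators IMP-L2, WDB, PTEN and HPO.
  It is a faithful sub-network, not the full hand-curated diagram: it
  contains exactly the interactions needed to realise every reported
  shortest signalling path of the four longevity experiments.
* :func:`build_experiment` — the fact sets of the four fly longevity
  experiments (chico¹/+, Lnk null, dominant-negative InR, foxo null).
* :func:`random_signed_graph` — seeded random signed graphs for
  property tests.
"""

from __future__ import annotations

import numpy as np

from .experiments import (
    Direction,
    ExperimentFacts,
    Perturbation,
    PerturbationKind,
    PhenotypeValue,
    build_facts,
)
from .model import (
    EdgeSign,
    NodeKind,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    default_kind,
)

EXPERIMENT_NAMES = ("chico", "Lnk", "InR", "foxo")

_ACT = EdgeSign.ACTIVATES
_INH = EdgeSign.INHIBITS


def build_toy() -> tuple[PathwayGraph, ExperimentFacts]:
    """Three-node example: A activates B, B inhibits C; A knocked out.

    Solving it derives ``inactivates(A,B)`` (B stays inactivated by the
    absent A) and ``activates(B,C)`` (C activated by lack of inhibition).
    The toy has no phenotype node and no observed phenotype.
    """
    graph = PathwayGraph(
        nodes=[PathwayNode("A"), PathwayNode("B"), PathwayNode("C")],
        edges=[
            PathwayEdge("A", "B", _ACT),
            PathwayEdge("B", "C", _INH),
        ],
    )
    facts = build_facts(
        graph,
        perturbations=[Perturbation("A", PerturbationKind.KNOCKOUT)],
        de={},
        phenotype=None,
    )
    return graph, facts


#: Signed edges of the IIS/TOR core network.
_CORE_EDGES: tuple[tuple[str, str, EdgeSign], ...] = (
    # insulin-like peptides converge on the receptor
    ("Ilp2", "InR", _ACT),
    ("Ilp3", "InR", _ACT),
    ("Ilp5", "InR", _ACT),
    ("Ilp6", "InR", _ACT),
    # the secreted IGFBP7 homologue sequesters ILP2 and ILP5
    ("ImpL2", "Ilp2", _INH),
    ("ImpL2", "Ilp5", _INH),
    # receptor recruits the two parallel adaptors
    ("InR", "chico", _ACT),
    ("InR", "Lnk", _ACT),
    ("chico", "Pi3K", _ACT),
    ("Lnk", "Pi3K", _ACT),
    # PI3K drives AKT1 directly and through PDK1 (Pk61C)
    ("Pi3K", "Akt1", _ACT),
    ("Pi3K", "Pk61C", _ACT),
    ("Pk61C", "Akt1", _ACT),
    # AKT1 retains FOXO in the cytoplasm; active FOXO mediates longevity
    ("Akt1", "foxo", _INH),
    ("foxo", "longevity", _ACT),
    # phosphatase modulators of AKT1
    ("wdb", "Akt1", _INH),
    ("Pten", "Akt1", _INH),
    # Hippo kinase promotes FOXO activity
    ("hpo", "foxo", _ACT),
    # TOR/autophagy coupling back into IIS through S6K and CHICO
    ("Atg1", "S6k", _INH),
    ("S6k", "chico", _INH),
    # JNK branch antagonising IIS via FOXO activation
    ("Tak1", "hep", _ACT),
    ("hep", "bsk", _ACT),
    ("bsk", "foxo", _ACT),
    # TOR complexes and their regulators
    ("L", "c_TOR-C1", _INH),
    ("c_TOR-C1", "c_TOR-C2", _INH),
    ("c_TOR-C2", "Akt1", _ACT),
    ("c_TSC", "Rheb", _INH),
    ("Rheb", "c_TOR-C1", _ACT),
)

_CORE_KINDS: dict[str, NodeKind] = {
    "Pi3K": NodeKind.COMPLEX,
    "foxo": NodeKind.TRANSCRIPTION_FACTOR,
    "longevity": NodeKind.PHENOTYPE,
}


def build_iis_tor_core() -> PathwayGraph:
    """The IIS/TOR core network with ``longevity`` as phenotype node."""
    order: list[str] = []
    for source, target, _ in _CORE_EDGES:
        for node_id in (source, target):
            if node_id not in order:
                order.append(node_id)
    nodes = [
        PathwayNode(id=i, kind=_CORE_KINDS.get(i, default_kind(i)))
        for i in order
    ]
    edges = [PathwayEdge(s, t, sign) for s, t, sign in _CORE_EDGES]
    graph = PathwayGraph(nodes=nodes, edges=edges, phenotype_node="longevity")
    return graph.require_valid()


_UP = Direction.UP
_DOWN = Direction.DOWN

#: Perturbation, DE directions and observed phenotype per experiment.
_EXPERIMENTS: dict[str, dict] = {
    "chico": dict(
        perturbation=Perturbation("chico", PerturbationKind.HETEROZYGOUS_KNOCKOUT),
        de={"Ilp2": _UP, "Ilp3": _UP, "Ilp5": _UP},
        extended_de={},
        phenotype=PhenotypeValue.LONG_LIVED,
    ),
    "Lnk": dict(
        perturbation=Perturbation("Lnk", PerturbationKind.KNOCKOUT),
        de={
            "Ilp2": _UP, "Ilp3": _UP, "Ilp5": _UP, "Ilp6": _UP,
            "ImpL2": _DOWN, "wdb": _DOWN, "chico": _UP, "Atg1": _UP,
        },
        extended_de={},
        phenotype=PhenotypeValue.LONG_LIVED,
    ),
    "InR": dict(
        perturbation=Perturbation("InR", PerturbationKind.DOMINANT_NEGATIVE),
        de={"Ilp6": _UP, "L": _UP, "Tak1": _UP},
        extended_de={"Thor": _UP, "myc": _UP},
        phenotype=PhenotypeValue.LONG_LIVED,
    ),
    "foxo": dict(
        perturbation=Perturbation("foxo", PerturbationKind.KNOCKOUT),
        de={
            "Ilp3": _DOWN, "ImpL2": _UP, "Pk61C": _UP,
            "hpo": _DOWN, "Pten": _DOWN,
        },
        extended_de={"Tor": _DOWN, "Sin1": _DOWN, "Thor": _UP, "myc": _UP},
        phenotype=PhenotypeValue.SHORT_LIVED,
    ),
}


def build_experiment(
    name: str,
    graph: PathwayGraph | None = None,
    extended: bool = False,
) -> ExperimentFacts:
    """Fact set of one of the four longevity experiments.

    Parameters
    ----------
    name :
        One of ``chico``, ``Lnk``, ``InR``, ``foxo``.
    graph :
        Pathway to resolve genes against; defaults to the IIS/TOR core.
    extended :
        Also include DE genes reported for the experiment but lying
        outside the core sub-network (e.g. Thor, myc); these are dropped
        with a warning when the default core graph is used.
    """
    if name not in _EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; expected one of {EXPERIMENT_NAMES}"
        )
    if graph is None:
        graph = build_iis_tor_core()
    recipe = _EXPERIMENTS[name]
    de = dict(recipe["de"])
    if extended:
        de.update(recipe["extended_de"])
    return build_facts(
        graph,
        perturbations=[recipe["perturbation"]],
        de=de,
        phenotype=recipe["phenotype"],
    )


def random_signed_graph(
    seed: int,
    n_nodes: int,
    edge_probability: float,
    inhibit_fraction: float,
) -> PathwayGraph:
    """Seeded random signed digraph with one terminal phenotype node.

    Every ordered pair of distinct nodes (excluding edges out of the
    phenotype node) receives an edge with ``edge_probability``; each edge
    inhibits with ``inhibit_fraction`` and activates otherwise.  Node ids
    are ``n0 ... n{k-2}`` plus the phenotype ``phen``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if not 0.0 < edge_probability < 1.0:
        raise ValueError("edge_probability must be in (0, 1)")
    if not 0.0 <= inhibit_fraction <= 1.0:
        raise ValueError("inhibit_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"n{i}" for i in range(n_nodes - 1)] + ["phen"]
    nodes = [
        PathwayNode(id=i, kind=NodeKind.PHENOTYPE if i == "phen" else NodeKind.PROTEIN)
        for i in ids
    ]
    edges = []
    for source in ids:
        if source == "phen":
            continue
        for target in ids:
            if target == source:
                continue
            if rng.random() < edge_probability:
                sign = _INH if rng.random() < inhibit_fraction else _ACT
                edges.append(PathwayEdge(source, target, sign))
    return PathwayGraph(
        nodes=nodes, edges=edges, phenotype_node="phen"
    ).require_valid()
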