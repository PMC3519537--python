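"""Reading and writing pathway graphs.

Two serialisations are supported:

* **GraphML** — the interchange format used for the hand-curated pathway
  diagram.  Edge signs live in a first-class ``sign`` data attribute
  (``activates`` / ``inhibits``) and node roles in a ``kind`` attribute.
  Files exported from the yEd diagram editor, which encode the sign
  graphically instead, are handled by a best-effort fallback: a plain
  arrowhead on the target end maps to activation, a T-bar to inhibition.
* **Edge list** — a SIF-like tab-separated dialect,
  ``source<TAB>relation<TAB>target`` with ``relation`` in
  {activates, inhibits}, plus optional ``#kind`` and ``#phenotype``
  header lines.
"""

from __future__ import annotations

from typing import IO, Iterable

from lxml import etree

from .model import (
    EdgeSign,
    GraphFormatError,
    GraphValidationError,
    NodeKind,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    default_kind,
)

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
_G = "{%s}" % GRAPHML_NS

#: yEd target-arrow styles interpreted as plain activation arrows.
_YED_ACTIVATING_ARROWS = frozenset(
    {"standard", "delta", "plain", "short", "concave", "convex", "arrow"}
)
#: yEd target-arrow styles interpreted as inhibition T-bars.
_YED_INHIBITING_ARROWS = frozenset({"t_shape", "dash", "skewed_dash"})


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def read_graphml(stream: IO) -> PathwayGraph:
    """Parse a GraphML document into a validated :class:`PathwayGraph`.

    Raises
    ------
    GraphFormatError
        If the XML is malformed.
    GraphValidationError
        If an edge references an undeclared node, a sign cannot be
        determined for an edge, or any graph invariant is violated.
    """
    data = stream.read()
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise GraphFormatError(f"malformed GraphML: {exc}") from exc

    # Map <key> declarations to their attribute names, so data elements can
    # be resolved whatever id the writer chose.
    key_names: dict[str, str] = {}
    for key in root.iter(_G + "key"):
        kid = key.get("id")
        name = key.get("attr.name")
        if kid and name:
            key_names[kid] = name

    def data_values(element: etree._Element) -> dict[str, str]:
        values: dict[str, str] = {}
        for d in element.findall(_G + "data"):
            name = key_names.get(d.get("key", ""), d.get("key", ""))
            text = "".join(d.itertext()).strip()
            if name:
                values[name] = text
        return values

    nodes: list[PathwayNode] = []
    edges: list[PathwayEdge] = []
    for node_el in root.iter(_G + "node"):
        node_id = node_el.get("id")
        if node_id is None:
            raise GraphValidationError("GraphML node without an id attribute")
        values = data_values(node_el)
        kind_text = values.get("kind", "")
        if kind_text:
            try:
                kind = NodeKind(kind_text)
            except ValueError as exc:
                raise GraphValidationError(
                    f"node {node_id!r} has unknown kind {kind_text!r}"
                ) from exc
        else:
            kind = default_kind(node_id)
        nodes.append(
            PathwayNode(id=node_id, label=values.get("label", node_id), kind=kind)
        )

    for edge_el in root.iter(_G + "edge"):
        source = edge_el.get("source")
        target = edge_el.get("target")
        if source is None or target is None:
            raise GraphValidationError("GraphML edge missing source or target")
        values = data_values(edge_el)
        sign_text = values.get("sign", "")
        if sign_text:
            try:
                sign = EdgeSign(sign_text)
            except ValueError as exc:
                raise GraphValidationError(
                    f"edge {source}->{target} has unmappable sign {sign_text!r}"
                ) from exc
        else:
            sign = _yed_arrow_sign(edge_el, source, target)
        edges.append(PathwayEdge(source=source, target=target, sign=sign))

    return PathwayGraph(nodes=nodes, edges=edges).require_valid()


def _yed_arrow_sign(edge_el: etree._Element, source: str, target: str) -> EdgeSign:
    """Best-effort sign recovery from yEd ``<y:Arrows target=...>`` styling."""
    for descendant in edge_el.iter():
        if etree.QName(descendant).localname == "Arrows":
            style = (descendant.get("target") or "").lower()
            if style in _YED_INHIBITING_ARROWS:
                return EdgeSign.INHIBITS
            if style in _YED_ACTIVATING_ARROWS:
                return EdgeSign.ACTIVATES
            raise GraphValidationError(
                f"edge {source}->{target} has unmappable arrow style {style!r}"
            )
    raise GraphValidationError(
        f"edge {source}->{target} carries no 'sign' attribute and no "
        "recognisable arrow styling"
    )


def write_graphml(graph: PathwayGraph, stream: IO) -> None:
    """Serialise ``graph`` as GraphML invertible by :func:`read_graphml`."""
    graph.require_valid()
    root = etree.Element(_G + "graphml", nsmap={None: GRAPHML_NS})
    for key_id, domain, name in (
        ("d_label", "node", "label"),
        ("d_kind", "node", "kind"),
        ("d_sign", "edge", "sign"),
    ):
        key = etree.SubElement(root, _G + "key", id=key_id)
        key.set("for", domain)
        key.set("attr.name", name)
        key.set("attr.type", "string")
    graph_el = etree.SubElement(root, _G + "graph", id="pathway")
    graph_el.set("edgedefault", "directed")
    for node in graph.nodes:
        node_el = etree.SubElement(graph_el, _G + "node", id=node.id)
        etree.SubElement(node_el, _G + "data", key="d_label").text = node.label
        etree.SubElement(node_el, _G + "data", key="d_kind").text = node.kind.value
    for i, edge in enumerate(graph.edges):
        edge_el = etree.SubElement(
            graph_el, _G + "edge", id=f"e{i}", source=edge.source, target=edge.target
        )
        etree.SubElement(edge_el, _G + "data", key="d_sign").text = edge.sign.value
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")
    stream.write(text)


# ---------------------------------------------------------------------------
# Edge-list dialect
# ---------------------------------------------------------------------------

def read_edge_list(stream: IO) -> PathwayGraph:
    """Parse the tab-separated edge-list dialect.

    Grammar (one record per line)::

        #kind <node-id> <kind>       declare a node kind
        #phenotype <node-id>         declare the phenotype endpoint
        <source>\\t<relation>\\t<target>

    with ``relation`` in {activates, inhibits}.  Undeclared nodes default
    to kind ``protein`` (``complex`` when the id starts with ``c_``).
    """
    declared_kinds: dict[str, NodeKind] = {}
    phenotype: str | None = None
    edges: list[PathwayEdge] = []
    seen: set[PathwayEdge] = set()
    order: list[str] = []

    def remember(node_id: str) -> None:
        if node_id not in order:
            order.append(node_id)

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if not fields:
                continue
            directive, args = fields[0], fields[1:]
            if directive == "kind":
                if len(args) != 2:
                    raise GraphFormatError(
                        f"line {lineno}: expected '#kind <node> <kind>'"
                    )
                try:
                    declared_kinds[args[0]] = NodeKind(args[1])
                except ValueError as exc:
                    raise GraphValidationError(
                        f"line {lineno}: unknown node kind {args[1]!r}"
                    ) from exc
                remember(args[0])
            elif directive == "phenotype":
                if len(args) != 1:
                    raise GraphFormatError(
                        f"line {lineno}: expected '#phenotype <node>'"
                    )
                phenotype = args[0]
                declared_kinds.setdefault(phenotype, NodeKind.PHENOTYPE)
                remember(phenotype)
            # other comment lines are ignored
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphFormatError(
                f"line {lineno}: expected 'source<TAB>relation<TAB>target', "
                f"got {line!r}"
            )
        source, relation, target = (p.strip() for p in parts)
        try:
            sign = EdgeSign(relation)
        except ValueError as exc:
            raise GraphValidationError(
                f"line {lineno}: unknown relation {relation!r}"
            ) from exc
        edge = PathwayEdge(source=source, target=target, sign=sign)
        if edge in seen:
            raise GraphValidationError(
                f"line {lineno}: duplicate edge "
                f"{source}-[{sign.value}]->{target}"
            )
        seen.add(edge)
        edges.append(edge)
        remember(source)
        remember(target)

    nodes = [
        PathwayNode(id=i, kind=declared_kinds.get(i, default_kind(i)))
        for i in order
    ]
    return PathwayGraph(nodes=nodes, edges=edges,
                        phenotype_node=phenotype).require_valid()


def write_edge_list(graph: PathwayGraph, stream: IO) -> None:
    """Serialise ``graph`` in the edge-list dialect (inverts read_edge_list)."""
    graph.require_valid()
    for node in graph.nodes:
        if any(c.isspace() for c in node.id):
            raise GraphFormatError(
                f"node id {node.id!r} contains whitespace; not representable "
                "in the edge-list dialect"
            )
    # Every node gets a #kind line so isolated nodes survive the round trip.
    for node in graph.nodes:
        stream.write(f"#kind {node.id} {node.kind.value}\n")
    if graph.phenotype_node is not None:
        stream.write(f"#phenotype {graph.phenotype_node}\n")
    for edge in graph.edges:
        stream.write(f"{edge.source}\t{edge.sign.value}\t{edge.target}\n")
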