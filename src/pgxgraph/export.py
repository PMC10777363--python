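"""Machine-readable graph export: GraphML and node-link JSON.

Both formats round-trip losslessly through networkx: node roles, labels,
occurrence counters, symbols, attached guideline ids (with the guideline
payloads JSON-encoded at graph level), variant calls, edge styles and
collapsed counts are all preserved, so ``import_graph(export_graph(g, f), f)``
is the identity up to graph isomorphism.
"""

from __future__ import annotations

import json

import networkx as nx

from .graph_builder import AnnotatedGraph, ContradictionReport, GraphEdge, GraphNode
from .report import GeneVariantCall, Guideline

__all__ = ["to_networkx", "from_networkx", "export_graph", "import_graph", "FORMATS"]

FORMATS = ("graphml", "node_link")


def to_networkx(g: AnnotatedGraph) -> nx.MultiDiGraph:
    """Convert to a networkx multidigraph with scalar-only attributes.

    Complex payloads (guidelines, variants, contradictions) are JSON-encoded
    strings so the graph is GraphML-serializable as-is.
    """
    G = nx.MultiDiGraph()
    G.graph["drug_label"] = g.drug_label
    guideline_payloads: dict[str, dict] = {}
    for n in g.nodes:
        for gl in n.guidelines:
            guideline_payloads[gl.guideline_id] = gl.model_dump()
        G.add_node(
            n.node_id,
            role=n.role,
            label=n.label,
            occurrence=n.occurrence,
            symbol=n.symbol,
            guideline_ids=",".join(gl.guideline_id for gl in n.guidelines),
            variant=json.dumps(n.variant.model_dump()) if n.variant else "",
            severity_display=-1 if n.severity_display is None else n.severity_display,
            multi_source=n.multi_source,
        )
    for gl in g.orphan_guidelines:
        guideline_payloads[gl.guideline_id] = gl.model_dump()
    for e in g.edges:
        G.add_edge(
            e.from_id,
            e.to_id,
            key=e.reaction_id,
            reaction_id=e.reaction_id,
            style=e.style,
            collapsed_count=-1 if e.collapsed_count is None else e.collapsed_count,
        )
    G.graph["guidelines_json"] = json.dumps(guideline_payloads, sort_keys=True)
    G.graph["orphan_guideline_ids"] = ",".join(gl.guideline_id for gl in g.orphan_guidelines)
    G.graph["contradictions_json"] = json.dumps(g.contradictions.model_dump(), sort_keys=True)
    return G


def from_networkx(G: nx.MultiDiGraph) -> AnnotatedGraph:
    """Inverse of :func:`to_networkx`."""
    payloads = {
        gid: Guideline(**d) for gid, d in json.loads(G.graph.get("guidelines_json", "{}")).items()
    }
    nodes = []
    for nid, d in G.nodes(data=True):
        gids = [x for x in str(d.get("guideline_ids", "")).split(",") if x]
        sev = int(d.get("severity_display", -1))
        variant_raw = d.get("variant", "")
        nodes.append(
            GraphNode(
                node_id=nid,
                role=d["role"],
                label=d["label"],
                occurrence=int(d.get("occurrence", 1)),
                symbol=d.get("symbol", "plain"),
                guidelines=[payloads[x] for x in gids],
                variant=GeneVariantCall(**json.loads(variant_raw)) if variant_raw else None,
                severity_display=None if sev < 0 else sev,
                multi_source=bool(d.get("multi_source", False)),
            )
        )
    edges = []
    for u, v, d in G.edges(data=True):
        cc = int(d.get("collapsed_count", -1))
        edges.append(
            GraphEdge(
                from_id=u,
                to_id=v,
                reaction_id=d["reaction_id"],
                style=d["style"],
                collapsed_count=None if cc < 0 else cc,
            )
        )
    orphan_ids = [x for x in str(G.graph.get("orphan_guideline_ids", "")).split(",") if x]
    contradictions = ContradictionReport(**json.loads(G.graph.get("contradictions_json", "{}")))
    return AnnotatedGraph(
        drug_label=G.graph.get("drug_label", ""),
        nodes=nodes,
        edges=edges,
        orphan_guidelines=[payloads[x] for x in orphan_ids],
        contradictions=contradictions,
    )


def export_graph(g: AnnotatedGraph, format: str) -> str:
    """Serialize the annotated graph to ``graphml`` or ``node_link`` text."""
    G = to_networkx(g)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(G, named_key_ids=True)) + "\n"
    if format == "node_link":
        return json.dumps(nx.node_link_data(G, edges="edges"), indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown export format {format!r}; expected one of {FORMATS}")


def import_graph(data: str, format: str) -> AnnotatedGraph:
    """Re-import a serialized graph; inverse of :func:`export_graph`."""
    if format == "graphml":
        import io

        G = nx.read_graphml(io.StringIO(data), force_multigraph=True)
    elif format == "node_link":
        G = nx.node_link_graph(json.loads(data), multigraph=True, directed=True, edges="edges")
    else:
        raise ValueError(f"unknown export format {format!r}; expected one of {FORMATS}")
    return from_networkx(G)
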