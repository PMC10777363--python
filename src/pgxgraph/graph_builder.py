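"""Join a pathway with matched guidelines into the annotated, renderable graph.

Enzymes are interposed as nodes on the substrate→product path (substrate →
enzyme → product) rather than decorating chemical–chemical edges: tooltips
and metabolizer-status symbols live on enzyme nodes. A gene catalyzing k
reactions appears as k separate nodes, one per (gene, reaction) incidence.
Duplicating gene nodes keeps the pathway drawn as a chain instead of a tight
hub-and-spoke cluster around shared enzymes.

Contradiction detection compares the recommendation directions of all
guidelines attached to the graph: "increase dose", "decrease dose" and
"avoid" oppose each other pairwise; "standard" and open-ended categories
never participate (no action cannot oppose an action without clinical
semantics the data does not carry).
"""

from __future__ import annotations

from itertools import combinations
from typing import Literal, Optional

from pydantic import BaseModel, Field

from .pathway_io import Pathway
from .report import GeneVariantCall, Guideline

__all__ = [
    "GraphNode",
    "GraphEdge",
    "AnnotatedGraph",
    "ContradictionReport",
    "SYMBOLS",
    "assign_symbol",
    "build_graph",
    "detect_contradictions",
    "collapse_unaffected",
]

#: The five non-plain symbol classes of the legend, plus "plain".
SYMBOLS = (
    "arrow_down_pm",
    "arrow_lowerright_im",
    "arrow_right_nm",
    "arrow_up_um",
    "circle_variant_no_status",
    "plain",
)

_STATUS_SYMBOL = {
    "PM": "arrow_down_pm",
    "IM": "arrow_lowerright_im",
    "NM": "arrow_right_nm",
    "UM": "arrow_up_um",
}

#: Unordered category pairs that count as contradictory. Whether
#: avoid-vs-decrease is clinically a contradiction is configurable;
#: the default says yes.
DEFAULT_OPPOSING: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("increase_dose", "decrease_dose"),
        ("increase_dose", "avoid"),
        ("decrease_dose", "avoid"),
    ]
)


def assign_symbol(status: str, has_variant: bool) -> str:
    """Map a metabolizer status (plus variant presence) to its node symbol.

    Total and deterministic: PM ↓, IM ↘, NM →, UM ↑; a gene with a variant
    call but no status gets the circled-variant symbol; otherwise plain.
    """
    if status in _STATUS_SYMBOL:
        return _STATUS_SYMBOL[status]
    return "circle_variant_no_status" if has_variant else "plain"


class GraphNode(BaseModel):
    node_id: str
    role: Literal["chemical", "gene"]
    label: str
    occurrence: int = 1
    symbol: str = "plain"
    guidelines: list[Guideline] = Field(default_factory=list)
    variant: Optional[GeneVariantCall] = None
    severity_display: Optional[int] = None
    multi_source: bool = False


class GraphEdge(BaseModel):
    from_id: str
    to_id: str
    reaction_id: str
    style: Literal["solid_biochemical", "dashed_other", "collapsed"]
    collapsed_count: Optional[int] = None


class ContradictionReport(BaseModel):
    """Divergent recommendation directions among one drug's guidelines.

    ``varying`` counts distinct categories excluding "standard";
    ``conflicts`` lists each cross-group guideline-id pair once.
    """

    drug_label: str = ""
    varying: int = 0
    conflicts: list[tuple[str, str]] = Field(default_factory=list)


class AnnotatedGraph(BaseModel):
    drug_label: str
    nodes: list[GraphNode] = Field(default_factory=list)
    edges: list[GraphEdge] = Field(default_factory=list)
    orphan_guidelines: list[Guideline] = Field(default_factory=list)
    contradictions: ContradictionReport = Field(default_factory=ContradictionReport)

    def node_map(self) -> dict[str, GraphNode]:
        return {n.node_id: n for n in self.nodes}

    @property
    def root_id(self) -> str:
        """Node id of the root chemical (label matches the drug, or first chemical)."""
        want = self.drug_label.strip().lower()
        for n in self.nodes:
            if n.role == "chemical" and n.label.strip().lower() == want:
                return n.node_id
        for n in self.nodes:
            if n.role == "chemical":
                return n.node_id
        raise ValueError("graph has no chemical node")

    def canonical(self) -> "AnnotatedGraph":
        """Copy with nodes and edges in a canonical sort order.

        Two graphs are isomorphic in the export/import sense iff their
        canonical forms compare equal (node ids are stable identifiers).
        """
        return self.model_copy(
            update={
                "nodes": sorted(self.nodes, key=lambda n: n.node_id),
                "edges": sorted(self.edges, key=lambda e: (e.from_id, e.to_id, e.reaction_id)),
            }
        )

    def gene_nodes(self, gene: Optional[str] = None) -> list[GraphNode]:
        out = [n for n in self.nodes if n.role == "gene"]
        if gene is not None:
            out = [n for n in out if n.label.upper() == gene.upper()]
        return out


def detect_contradictions(
    guidelines: list[Guideline],
    drug_label: str = "",
    opposing: frozenset[frozenset[str]] = DEFAULT_OPPOSING,
) -> ContradictionReport:
    """Find pairs of guidelines whose recommendation directions oppose.

    All guidelines are assumed to concern the same drug. Each cross-group
    pair is listed once, in input order; the report is symmetric and
    irreflexive by construction.
    """
    cats = {g.recommendation_category for g in guidelines}
    varying = len(cats - {"standard"})
    conflicts: list[tuple[str, str]] = []
    for a, b in combinations(guidelines, 2):
        if frozenset((a.recommendation_category, b.recommendation_category)) in opposing:
            conflicts.append((a.guideline_id, b.guideline_id))
    return ContradictionReport(drug_label=drug_label, varying=varying, conflicts=conflicts)


def _display_guideline(attached: list[Guideline]) -> Optional[Guideline]:
    """Guideline whose status drives the node symbol: max severity, first wins ties."""
    if not attached:
        return None
    return max(attached, key=lambda g: g.severity)  # max() keeps the first maximum


def build_graph(
    p: Pathway,
    guidelines: list[Guideline],
    variants: list[GeneVariantCall],
    opposing: frozenset[frozenset[str]] = DEFAULT_OPPOSING,
) -> AnnotatedGraph:
    """Expand a pathway into the annotated graph for one drug.

    Each reaction with k catalysts becomes k parallel substrate→gene→product
    chains (gene nodes duplicated per incidence, ids ``GENE#reaction_id``);
    a catalyst-free reaction becomes a direct substrate→product edge.
    Guidelines are attached to every node of their gene (symbol-keyed);
    guidelines matching the drug but no pathway gene are kept as orphans —
    nothing is silently dropped.
    """
    # Ensure stable guideline ids for conflict reporting and export.
    gls: list[Guideline] = []
    for i, g in enumerate(guidelines):
        gls.append(g if g.guideline_id else g.model_copy(update={"guideline_id": f"g{i + 1}"}))

    by_gene: dict[str, list[Guideline]] = {}
    for g in gls:
        by_gene.setdefault(g.gene.upper(), []).append(g)
    var_by_gene = {v.gene.upper(): v for v in variants}

    nodes: list[GraphNode] = []
    edges: list[GraphEdge] = []
    for e in p.entities:
        nodes.append(GraphNode(node_id=e.entity_id, role="chemical", label=e.label))

    occurrence: dict[str, int] = {}
    attached_ids: set[str] = set()
    for r in p.reactions:
        style = "solid_biochemical" if r.is_biochemical else "dashed_other"
        if not r.catalysts:
            edges.append(GraphEdge(from_id=r.substrate_id, to_id=r.product_id, reaction_id=r.reaction_id, style=style))
            continue
        for gene in r.catalysts:
            occurrence[gene] = occurrence.get(gene, 0) + 1
            attached = by_gene.get(gene, [])
            variant = var_by_gene.get(gene)
            disp = _display_guideline(attached)
            status = disp.metabolizer_status if disp else "UNKNOWN"
            node = GraphNode(
                node_id=f"{gene}#{r.reaction_id}",
                role="gene",
                label=gene,
                occurrence=occurrence[gene],
                symbol=assign_symbol(status, variant is not None),
                guidelines=attached,
                variant=variant,
                severity_display=max((g.severity for g in attached), default=None),
                multi_source=len({g.recommendation_category for g in attached}) > 1,
            )
            attached_ids.update(g.guideline_id for g in attached)
            nodes.append(node)
            edges.append(GraphEdge(from_id=r.substrate_id, to_id=node.node_id, reaction_id=r.reaction_id, style=style))
            edges.append(GraphEdge(from_id=node.node_id, to_id=r.product_id, reaction_id=r.reaction_id, style=style))

    orphans = [g for g in gls if g.guideline_id not in attached_ids]
    attached_gls = [g for g in gls if g.guideline_id in attached_ids]
    contradictions = detect_contradictions(attached_gls, drug_label=p.drug_name, opposing=opposing)
    return AnnotatedGraph(
        drug_label=p.drug_name,
        nodes=nodes,
        edges=edges,
        orphan_guidelines=orphans,
        contradictions=contradictions,
    )


def collapse_unaffected(g: AnnotatedGraph) -> AnnotatedGraph:
    """Elide pathway steps untouched by the patient's variants.

    A reaction is *affected* iff any of its gene nodes carries a non-plain
    symbol. Maximal runs of unaffected reactions between two retained
    chemicals are replaced by a single ``collapsed(count)`` edge; the root,
    every chemical adjacent to an affected reaction, terminal metabolites
    and chemical-level branch points are always retained. Idempotent, and
    never removes a node with a non-plain symbol.
    """
    nmap = g.node_map()

    # Reconstruct reaction-level structure from edges.
    reactions: dict[str, dict] = {}
    collapsed_edges: list[GraphEdge] = []
    for e in g.edges:
        if e.style == "collapsed":
            collapsed_edges.append(e)
            continue
        r = reactions.setdefault(e.reaction_id, {"genes": [], "sub": None, "prod": None, "edges": []})
        r["edges"].append(e)
        src, dst = nmap[e.from_id], nmap[e.to_id]
        if src.role == "chemical":
            r["sub"] = src.node_id
        if dst.role == "chemical":
            r["prod"] = dst.node_id
        if src.role == "gene":
            r["genes"].append(src.node_id)

    def affected(rid: str) -> bool:
        return any(nmap[gid].symbol != "plain" for gid in set(reactions[rid]["genes"]))

    affected_rids = {rid for rid in reactions if affected(rid)}

    # Chemical-level adjacency over all reactions and collapsed edges.
    out_deg: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    succ: dict[str, list[tuple[str, str]]] = {}  # chem -> [(reaction_id, product_chem)]
    for rid, r in reactions.items():
        out_deg[r["sub"]] = out_deg.get(r["sub"], 0) + 1
        in_deg[r["prod"]] = in_deg.get(r["prod"], 0) + 1
        succ.setdefault(r["sub"], []).append((rid, r["prod"]))
    for e in collapsed_edges:
        out_deg[e.from_id] = out_deg.get(e.from_id, 0) + 1
        in_deg[e.to_id] = in_deg.get(e.to_id, 0) + 1

    chemicals = [n.node_id for n in g.nodes if n.role == "chemical"]
    retained: set[str] = {g.root_id}
    for rid in affected_rids:
        retained.add(reactions[rid]["sub"])
        retained.add(reactions[rid]["prod"])
    for e in collapsed_edges:
        retained.add(e.from_id)
        retained.add(e.to_id)
    for c in chemicals:
        if out_deg.get(c, 0) == 0:  # terminal metabolite
            retained.add(c)
        if out_deg.get(c, 0) > 1 or in_deg.get(c, 0) > 1:  # branch point
            retained.add(c)

    # Walk maximal unaffected runs from each retained chemical.
    new_edges: list[GraphEdge] = list(collapsed_edges)
    keep_rids: set[str] = set(affected_rids)
    for start in sorted(retained):
        for rid, nxt in succ.get(start, ()):
            if rid in affected_rids:
                continue
            count = 1
            cur = nxt
            seen = {start}
            while cur not in retained and cur not in seen:
                seen.add(cur)
                steps = [s for s in succ.get(cur, ()) if s[0] not in affected_rids]
                if len(steps) != 1:  # defensive; branch points are retained
                    break
                count += 1
                cur = steps[0][1]
            new_edges.append(
                GraphEdge(
                    from_id=start,
                    to_id=cur,
                    reaction_id=f"collapsed:{start}->{cur}",
                    style="collapsed",
                    collapsed_count=count,
                )
            )

    for rid in sorted(keep_rids):  # sorted: edge order independent of hash seed
        new_edges.extend(reactions[rid]["edges"])

    used: set[str] = {g.root_id}
    for e in new_edges:
        used.add(e.from_id)
        used.add(e.to_id)
    new_nodes = [n for n in g.nodes if n.node_id in used]

    return AnnotatedGraph(
        drug_label=g.drug_label,
        nodes=new_nodes,
        edges=new_edges,
        orphan_guidelines=list(g.orphan_guidelines),
        contradictions=g.contradictions.model_copy(deep=True),
    )
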