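"""Graph construction: duplication, symbols, contradictions, collapse."""

from itertools import combinations, combinations_with_replacement

import networkx as nx
import pytest

from pgxgraph import (
    AnnotatedGraph,
    Guideline,
    SyntheticSpec,
    assign_symbol,
    build_graph,
    collapse_unaffected,
    detect_contradictions,
    generate_case,
    match_guidelines,
    parse_pathway,
)
from pgxgraph.graph_builder import GraphEdge, GraphNode

# ---------------------------------------------------------------- build_graph


def test_worked_example_cyp2d6_duplicated(clomipramine_graph):
    """CYP2D6 catalyzes two steps, so it appears as two nodes, each PM-marked."""
    nodes = clomipramine_graph.gene_nodes("CYP2D6")
    assert len(nodes) == 2
    assert sorted(n.occurrence for n in nodes) == [1, 2]
    for n in nodes:
        assert n.symbol == "arrow_down_pm"
        assert [g.guideline_id for g in n.guidelines] == ["gl-cyp2d6-clomipramine"]


def test_worked_example_symbols(clomipramine_graph):
    by_gene = {}
    for n in clomipramine_graph.gene_nodes():
        by_gene.setdefault(n.label, set()).add(n.symbol)
    assert by_gene["CYP2D6"] == {"arrow_down_pm"}
    assert by_gene["CYP2C19"] == {"arrow_up_um"}
    assert by_gene["CYP3A4"] == {"circle_variant_no_status"}  # variant, no status
    assert by_gene["CYP1A2"] == {"plain"}  # no variant, no guideline


def test_no_guidelines_no_variants_all_plain(worked_example):
    p, _ = worked_example
    g = build_graph(p, [], [])
    assert {n.symbol for n in g.gene_nodes()} == {"plain"}
    assert g.contradictions.conflicts == [] and g.contradictions.varying == 0


def test_zero_catalyst_reaction_becomes_direct_edge():
    p = parse_pathway("From\tTo\tController\nDrugX\tM1\t\n", "DrugX")
    g = build_graph(p, [], [])
    assert [(e.from_id, e.to_id) for e in g.edges] == [("drugx", "m1")]
    assert g.gene_nodes() == []


def test_degenerate_root_only_pathway():
    p = parse_pathway("From\tTo\tController\n", "DrugX")
    g = build_graph(p, [], [])
    assert len(g.nodes) == 1 and g.edges == []


@pytest.mark.parametrize("seed", range(20))
def test_gene_node_duplication_theorem_random(seed):
    """Node count per gene equals its reaction-incidence count (brute force)."""
    pathway, record = generate_case(SyntheticSpec(seed=seed, n_metabolites=8, n_genes=4))
    g = build_graph(pathway, record.guidelines, record.variants)
    for gene in pathway.catalyst_genes():
        incidences = sum(1 for r in pathway.reactions if gene in r.catalysts)
        assert len(g.gene_nodes(gene)) == incidences


def test_guideline_conservation(worked_example):
    """attached (deduplicated) + orphans = input guidelines; no silent drops."""
    p, r = worked_example
    gls = match_guidelines(r, r.prescriptions[0])
    extra = Guideline(guideline_id="gx", gene="UGT1A4", drug_name="clomipramine",
                      metabolizer_status="NM")
    g = build_graph(p, gls + [extra], r.variants)
    attached = {gl.guideline_id for n in g.gene_nodes() for gl in n.guidelines}
    orphan = {gl.guideline_id for gl in g.orphan_guidelines}
    assert attached | orphan == {gl.guideline_id for gl in gls} | {"gx"}
    assert attached & orphan == set()
    assert orphan == {"gx"}


# --------------------------------------------------------------- assign_symbol


def test_assign_symbol_total_and_injective():
    table = {
        ("PM", False): "arrow_down_pm",
        ("IM", False): "arrow_lowerright_im",
        ("NM", False): "arrow_right_nm",
        ("UM", False): "arrow_up_um",
        ("UNKNOWN", True): "circle_variant_no_status",
        ("UNKNOWN", False): "plain",
    }
    for (status, has_variant), expected in table.items():
        assert assign_symbol(status, has_variant) == expected
        assert assign_symbol(status, not has_variant if status == "UNKNOWN" else has_variant)
    statuses = ["PM", "IM", "NM", "UM"]
    symbols = [assign_symbol(s, False) for s in statuses]
    assert len(set(symbols)) == len(statuses)  # injective on known statuses


# ------------------------------------------------------- detect_contradictions

CATEGORY_ALPHABET = ["increase_dose", "decrease_dose", "avoid", "standard", "watch closely"]
OPPOSING = {
    frozenset({"increase_dose", "decrease_dose"}),
    frozenset({"increase_dose", "avoid"}),
    frozenset({"decrease_dose", "avoid"}),
}


def _brute_force(guidelines):
    """Independent oracle: explicit pairwise enumeration."""
    conflicts = [
        (a.guideline_id, b.guideline_id)
        for a, b in combinations(guidelines, 2)
        if frozenset({a.recommendation_category, b.recommendation_category}) in OPPOSING
    ]
    varying = len({g.recommendation_category for g in guidelines} - {"standard"})
    return varying, conflicts


def _mk(categories):
    return [
        Guideline(guideline_id=f"g{i}", gene=f"G{i}", drug_name="d",
                  recommendation_category=c)
        for i, c in enumerate(categories)
    ]


def test_worked_example_contradiction_pair():
    gls = _mk(["decrease_dose", "avoid"])
    rep = detect_contradictions(gls, drug_label="clomipramine")
    assert rep.varying == 2
    assert rep.conflicts == [("g0", "g1")]


def test_single_guideline_no_conflict():
    rep = detect_contradictions(_mk(["avoid"]))
    assert rep.varying <= 1 and rep.conflicts == []


def test_contradictions_match_exhaustive_oracle():
    """All category multisets of size <= 4 over the full alphabet."""
    for size in range(5):
        for cats in combinations_with_replacement(CATEGORY_ALPHABET, size):
            gls = _mk(cats)
            rep = detect_contradictions(gls)
            varying, conflicts = _brute_force(gls)
            assert rep.varying == varying, cats
            assert sorted(rep.conflicts) == sorted(conflicts), cats
            # invariants: irreflexive, and varying >= 2 whenever conflicts exist
            assert all(a != b for a, b in rep.conflicts)
            if rep.conflicts:
                assert rep.varying >= 2


def test_standard_and_other_never_conflict():
    rep = detect_contradictions(_mk(["standard", "watch closely", "standard"]))
    assert rep.conflicts == []


# ------------------------------------------------------------------- collapse


def _chain_graph():
    """root -> A -> B -> C, only root->A affected (PM gene)."""
    pm = Guideline(guideline_id="g1", gene="GENE1", drug_name="d",
                   metabolizer_status="PM", recommendation_category="decrease_dose")
    nodes = [
        GraphNode(node_id="root", role="chemical", label="d"),
        GraphNode(node_id="a", role="chemical", label="A"),
        GraphNode(node_id="b", role="chemical", label="B"),
        GraphNode(node_id="c", role="chemical", label="C"),
        GraphNode(node_id="GENE1#r1", role="gene", label="GENE1", symbol="arrow_down_pm",
                  guidelines=[pm]),
        GraphNode(node_id="GENE2#r2", role="gene", label="GENE2"),
        GraphNode(node_id="GENE3#r3", role="gene", label="GENE3"),
    ]
    edges = [
        GraphEdge(from_id="root", to_id="GENE1#r1", reaction_id="r1", style="solid_biochemical"),
        GraphEdge(from_id="GENE1#r1", to_id="a", reaction_id="r1", style="solid_biochemical"),
        GraphEdge(from_id="a", to_id="GENE2#r2", reaction_id="r2", style="solid_biochemical"),
        GraphEdge(from_id="GENE2#r2", to_id="b", reaction_id="r2", style="solid_biochemical"),
        GraphEdge(from_id="b", to_id="GENE3#r3", reaction_id="r3", style="solid_biochemical"),
        GraphEdge(from_id="GENE3#r3", to_id="c", reaction_id="r3", style="solid_biochemical"),
    ]
    return AnnotatedGraph(drug_label="d", nodes=nodes, edges=edges)


def test_collapse_chain_hand_computed():
    g = collapse_unaffected(_chain_graph())
    ids = {n.node_id for n in g.nodes}
    assert "b" not in ids and "GENE2#r2" not in ids and "GENE3#r3" not in ids
    assert {"root", "a", "c", "GENE1#r1"} <= ids
    collapsed = [e for e in g.edges if e.style == "collapsed"]
    assert len(collapsed) == 1
    assert (collapsed[0].from_id, collapsed[0].to_id, collapsed[0].collapsed_count) == ("a", "c", 2)


def test_collapse_fully_affected_graph_is_identity(clomipramine_graph):
    assert collapse_unaffected(clomipramine_graph) == clomipramine_graph


def _reachability(g: AnnotatedGraph, over: set) -> set:
    G = nx.DiGraph((e.from_id, e.to_id) for e in g.edges)
    G.add_nodes_from(n.node_id for n in g.nodes)
    return {(u, v) for u in over for v in over if u != v and nx.has_path(G, u, v)}


@pytest.mark.parametrize("seed", range(15))
def test_collapse_preserves_reachability_and_symbols(seed):
    """Breadth-first-search oracle: retained-node reachability unchanged."""
    pathway, record = generate_case(SyntheticSpec(seed=seed, n_metabolites=7, n_genes=3))
    g = build_graph(pathway, record.guidelines, record.variants)
    gc = collapse_unaffected(g)
    retained = {n.node_id for n in gc.nodes}
    assert _reachability(g, retained) == _reachability(gc, retained)
    nonplain_before = {n.node_id for n in g.nodes if n.symbol != "plain"}
    assert nonplain_before <= retained
    assert collapse_unaffected(gc) == gc  # idempotent
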