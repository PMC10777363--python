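"""Deterministic layout, SVG/HTML rendering, and graph export round trips."""

import math

import pytest

from pgxgraph import (
    AnnotatedGraph,
    build_graph,
    export_graph,
    force_layout,
    import_graph,
    parse_pathway,
    render_document,
    render_svg,
    two_node_equilibrium_distance,
)
from pgxgraph.graph_builder import GraphEdge, GraphNode

# --------------------------------------------------------------------- layout


def _two_node_graph():
    return AnnotatedGraph(
        drug_label="a",
        nodes=[
            GraphNode(node_id="a", role="chemical", label="a"),
            GraphNode(node_id="b", role="chemical", label="b"),
        ],
        edges=[GraphEdge(from_id="a", to_id="b", reaction_id="r", style="solid_biochemical")],
    )


def test_layout_deterministic(clomipramine_graph):
    la = force_layout(clomipramine_graph, seed=7)
    lb = force_layout(clomipramine_graph, seed=7)
    assert la == lb  # bit-identical, including stress history
    lc = force_layout(clomipramine_graph, seed=8)
    assert lc.positions != la.positions


def test_stress_non_increasing_and_bounded(clomipramine_graph):
    lay = force_layout(clomipramine_graph, seed=3)
    h = lay.stress_history
    assert all(h[i + 1] <= h[i] for i in range(len(h) - 1))
    assert lay.final_stress <= h[0]
    assert lay.final_stress >= 0.0
    assert all(math.isfinite(c) for xy in lay.positions.values() for c in xy)


def test_two_node_equilibrium_matches_closed_form():
    """The attraction d^2/k and repulsion k^3/d^2 balance exactly at d = k."""
    k = 1.0
    lay = force_layout(_two_node_graph(), seed=11, max_iter=500, k=k)
    (x1, y1), (x2, y2) = lay.positions["a"], lay.positions["b"]
    assert math.hypot(x1 - x2, y1 - y2) == pytest.approx(two_node_equilibrium_distance(k), abs=1e-6)


def test_minimum_node_separation(clomipramine_graph):
    node_radius = 0.05
    lay = force_layout(clomipramine_graph, seed=1)
    pts = list(lay.positions.values())
    dmin = min(
        math.hypot(p[0] - q[0], p[1] - q[1])
        for i, p in enumerate(pts)
        for q in pts[i + 1 :]
    )
    assert dmin > node_radius


def test_layout_argument_errors(clomipramine_graph):
    with pytest.raises(ValueError):
        force_layout(clomipramine_graph, seed=1, max_iter=0)
    with pytest.raises(ValueError):
        force_layout(AnnotatedGraph(drug_label="x"), seed=1)


def test_single_node_layout():
    g = AnnotatedGraph(drug_label="x", nodes=[GraphNode(node_id="x", role="chemical", label="x")])
    lay = force_layout(g, seed=5)
    assert set(lay.positions) == {"x"} and lay.final_stress == 0.0


# ------------------------------------------------------------------ rendering


def test_svg_element_counts(clomipramine_graph):
    lay = force_layout(clomipramine_graph, seed=1)
    svg = render_svg(clomipramine_graph, lay)
    assert svg.count('class="node"') == len(clomipramine_graph.nodes)
    assert svg.count('class="edge"') == len(clomipramine_graph.edges)
    assert render_svg(clomipramine_graph, lay) == svg  # deterministic


def test_svg_single_node():
    g = AnnotatedGraph(drug_label="x", nodes=[GraphNode(node_id="x", role="chemical", label="x")])
    svg = render_svg(g, force_layout(g, seed=1))
    assert svg.count('class="node"') == 1 and svg.count('class="edge"') == 0


def test_svg_collapsed_edge_styling():
    g = AnnotatedGraph(
        drug_label="a",
        nodes=[
            GraphNode(node_id="a", role="chemical", label="a"),
            GraphNode(node_id="b", role="chemical", label="b"),
        ],
        edges=[
            GraphEdge(from_id="a", to_id="b", reaction_id="c1", style="collapsed", collapsed_count=3)
        ],
    )
    svg = render_svg(g, force_layout(g, seed=1))
    assert 'data-style="collapsed"' in svg and "stroke-dasharray" in svg
    assert "3 step(s)" in svg


def test_svg_rejects_incomplete_layout(clomipramine_graph):
    lay = force_layout(clomipramine_graph, seed=1)
    lay2 = lay.model_copy(update={"positions": {k: v for k, v in list(lay.positions.items())[:-1]}})
    with pytest.raises(ValueError):
        render_svg(clomipramine_graph, lay2)


def test_document_contents(clomipramine_graph, worked_example):
    _, record = worked_example
    doc = render_document(clomipramine_graph, record, force_layout(clomipramine_graph, seed=1))
    # patient panel
    for token in ("John Doe", "54", "male", "26.3"):
        assert token in doc
    # legend: exactly the five non-plain symbol classes
    assert doc.count("legend-entry") == 5
    # drug selector lists both prescriptions
    assert 'id="drug-selector"' in doc
    assert "clomipramine" in doc and "atomoxetine" in doc
    # tooltip content: status, recommendation, activity score, severity
    assert "status PM" in doc and "recommendation decrease dose" in doc
    assert "activity score 0.0" in doc and "severity 3" in doc
    # contradiction banner names both directions
    assert "contradiction-banner" in doc
    assert "avoid vs decrease_dose" in doc
    # expandable full-text section with source link
    assert "<details" in doc and "https://www.pharmgkb.org" in doc


def test_document_without_guidelines_has_no_banner(worked_example):
    p, record = worked_example
    g = build_graph(p, [], [])
    doc = render_document(g, record.model_copy(update={"prescriptions": record.prescriptions[:1]}),
                          force_layout(g, seed=1))
    assert '<div class="contradiction-banner"' not in doc
    assert 'id="drug-selector"' not in doc  # single prescription: no selector


# -------------------------------------------------------------------- export


@pytest.mark.parametrize("fmt", ["graphml", "node_link"])
def test_export_import_round_trip(clomipramine_graph, fmt):
    data = export_graph(clomipramine_graph, fmt)
    back = import_graph(data, fmt)
    assert back.canonical() == clomipramine_graph.canonical()


@pytest.mark.parametrize("fmt", ["graphml", "node_link"])
def test_export_preserves_collapsed_counts(fmt):
    from pgxgraph import SyntheticSpec, collapse_unaffected, generate_case

    pathway, record = generate_case(SyntheticSpec(seed=5, n_metabolites=7, n_genes=2))
    from pgxgraph import build_graph as bg

    g = collapse_unaffected(bg(pathway, record.guidelines, record.variants))
    back = import_graph(export_graph(g, fmt), fmt)
    assert back.canonical() == g.canonical()
    counts = sorted(e.collapsed_count for e in back.edges if e.style == "collapsed")
    assert counts == sorted(e.collapsed_count for e in g.edges if e.style == "collapsed")


@pytest.mark.parametrize("fmt", ["graphml", "node_link"])
def test_export_single_node_graph(fmt):
    g = AnnotatedGraph(drug_label="x", nodes=[GraphNode(node_id="x", role="chemical", label="x")])
    assert import_graph(export_graph(g, fmt), fmt).canonical() == g.canonical()


def test_export_unknown_format_errors(clomipramine_graph):
    with pytest.raises(ValueError):
        export_graph(clomipramine_graph, "dot")
    with pytest.raises(ValueError):
        import_graph("{}", "dot")
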