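"""Static SVG and self-contained interactive HTML rendering.

Shapes are contractual, colors are configuration defaults (shape carries the
meaning for color-blind readers): PM blue ↓, IM light-blue ↘, NM green →,
UM red ↑, variant-without-status blue circle with yellow border. The HTML
document is a single self-contained file — styles, script and data inline,
no network fetches — because clinical environments are offline-hostile.
"""

from __future__ import annotations

import html
import json
from string import Template
from typing import Optional

from .graph_builder import AnnotatedGraph, GraphNode
from .layout import LayoutResult
from .report import PatientRecord

__all__ = ["render_svg", "render_document", "SYMBOL_LEGEND", "SYMBOL_COLORS"]

#: Legend text for the five non-plain symbol classes.
SYMBOL_LEGEND: dict[str, str] = {
    "arrow_down_pm": "Poor metabolizer (PM): arrow down",
    "arrow_lowerright_im": "Intermediate metabolizer (IM): arrow to lower right",
    "arrow_right_nm": "Normal metabolizer (NM): arrow right",
    "arrow_up_um": "Ultrarapid metabolizer (UM): arrow up",
    "circle_variant_no_status": "Gene variant present, no metabolizer status: circle",
}

SYMBOL_COLORS: dict[str, str] = {
    "arrow_down_pm": "#1f77b4",
    "arrow_lowerright_im": "#9ecae1",
    "arrow_right_nm": "#2ca02c",
    "arrow_up_um": "#d62728",
    "circle_variant_no_status": "#1f77b4",
    "plain": "#bbbbbb",
}

# Arrow glyph outlines in a local -1..1 box, one per symbol class.
_ARROWS = {
    "arrow_down_pm": "M -0.35 -1 L 0.35 -1 L 0.35 0.2 L 0.8 0.2 L 0 1 L -0.8 0.2 L -0.35 0.2 Z",
    "arrow_up_um": "M -0.35 1 L 0.35 1 L 0.35 -0.2 L 0.8 -0.2 L 0 -1 L -0.8 -0.2 L -0.35 -0.2 Z",
    "arrow_right_nm": "M -1 -0.35 L 0.2 -0.35 L 0.2 -0.8 L 1 0 L 0.2 0.8 L 0.2 0.35 L -1 0.35 Z",
    "arrow_lowerright_im": "M -0.9 -0.45 L -0.05 0.4 L -0.35 0.7 L 0.75 0.75 L 0.7 -0.35 L 0.4 -0.05 L -0.45 -0.9 Z",
}

_GLYPH_SIZE = 14.0


def _scale_positions(layout: LayoutResult, width: float, height: float, pad: float) -> dict[str, tuple[float, float]]:
    xs = [p[0] for p in layout.positions.values()]
    ys = [p[1] for p in layout.positions.values()]
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    sx = (width - 2 * pad) / (x1 - x0) if x1 > x0 else 0.0
    sy = (height - 2 * pad) / (y1 - y0) if y1 > y0 else 0.0
    return {
        nid: (pad + (x - x0) * sx, pad + (y - y0) * sy)
        for nid, (x, y) in layout.positions.items()
    }


def _node_glyph(n: GraphNode, x: float, y: float) -> str:
    s = _GLYPH_SIZE
    color = SYMBOL_COLORS[n.symbol]
    title = html.escape(n.label)
    if n.role == "chemical":
        body = f'<ellipse rx="{s * 1.4:.1f}" ry="{s * 0.8:.1f}" fill="#f5f0e6" stroke="#555"/>'
    elif n.symbol == "circle_variant_no_status":
        body = f'<circle r="{s * 0.8:.1f}" fill="{color}" stroke="#e6c200" stroke-width="3"/>'
    elif n.symbol in _ARROWS:
        body = f'<path d="{_ARROWS[n.symbol]}" transform="scale({s * 0.8:.1f})" fill="{color}" stroke="#333" stroke-width="0.05"/>'
    else:  # plain gene
        body = f'<circle r="{s * 0.6:.1f}" fill="{color}" stroke="#777"/>'
    label = f'<text y="{s * 1.9:.1f}" text-anchor="middle" font-size="11">{title}</text>'
    return (
        f'<g class="node" data-node-id="{html.escape(n.node_id)}" data-symbol="{n.symbol}" '
        f'transform="translate({x:.2f},{y:.2f})">{body}{label}</g>'
    )


def render_svg(
    g: AnnotatedGraph,
    layout: LayoutResult,
    width: float = 900.0,
    height: float = 620.0,
) -> str:
    """Render the graph as a static SVG string.

    Exactly one ``<g class="node">`` glyph per node and one
    ``<path class="edge">`` per edge; collapsed edges get a distinct dotted
    stroke and a label with the number of elided reactions. Deterministic
    for fixed inputs.
    """
    missing = [n.node_id for n in g.nodes if n.node_id not in layout.positions]
    if missing:
        raise ValueError(f"layout does not cover nodes {missing!r}")
    pos = _scale_positions(layout, width, height, pad=50.0)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {width:.0f} {height:.0f}" '
        f'font-family="sans-serif">',
        '<defs><marker id="arrowhead" markerWidth="8" markerHeight="8" refX="7" refY="3" orient="auto">'
        '<path d="M0,0 L7,3 L0,6 Z" fill="#666"/></marker></defs>',
    ]
    labels = []
    for e in g.edges:
        (x1, y1), (x2, y2) = pos[e.from_id], pos[e.to_id]
        dash = ""
        if e.style == "dashed_other":
            dash = ' stroke-dasharray="6,4"'
        elif e.style == "collapsed":
            dash = ' stroke-dasharray="2,5"'
        parts.append(
            f'<path class="edge" data-style="{e.style}" d="M {x1:.2f} {y1:.2f} L {x2:.2f} {y2:.2f}" '
            f'stroke="#666" fill="none" marker-end="url(#arrowhead)"{dash}/>'
        )
        if e.style == "collapsed" and e.collapsed_count is not None:
            mx, my = (x1 + x2) / 2, (y1 + y2) / 2
            labels.append(
                f'<text class="collapsed-count" x="{mx:.2f}" y="{my - 4:.2f}" text-anchor="middle" '
                f'font-size="10" fill="#666">&#8943; {e.collapsed_count} step(s)</text>'
            )
    parts.extend(labels)
    for n in g.nodes:
        x, y = pos[n.node_id]
        parts.append(_node_glyph(n, x, y))
    parts.append("</svg>")
    return "\n".join(parts)


def _tooltip_lines(n: GraphNode) -> list[str]:
    """Concise per-gene-node summary: status, recommendation, activity score, severity."""
    lines = []
    score = n.variant.activity_score if n.variant else None
    for gl in n.guidelines:
        lines.append(
            f"{n.label} {gl.diplotype}: status {gl.metabolizer_status}; "
            f"recommendation {gl.recommendation_category.replace('_', ' ')}; "
            f"activity score {score if score is not None else 'n/a'}; severity {gl.severity}"
        )
    if not n.guidelines and n.variant:
        lines.append(
            f"{n.label} {n.variant.diplotype}: variant present, no metabolizer status; "
            f"activity score {score if score is not None else 'n/a'}"
        )
    return lines


_PAGE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>PGx pathway report: $drug</title>
<style>
body { font-family: sans-serif; margin: 0; display: flex; }
#patient-panel { width: 230px; padding: 1em; background: #f2f2f2; }
#main { flex: 1; padding: 1em; }
#legend { width: 260px; padding: 1em; background: #fafafa; }
#legend li { margin-bottom: 0.5em; }
.contradiction-banner { background: #ffe0e0; border: 1px solid #d62728;
  padding: 0.6em; margin-bottom: 0.8em; }
.tooltip { display: none; position: absolute; background: #fff; border: 1px solid #999;
  padding: 0.4em; max-width: 320px; font-size: 12px; }
.node:hover + .tooltip, .node.active + .tooltip { display: block; }
details { margin-bottom: 0.6em; }
</style>
</head>
<body>
<aside id="patient-panel">
  <h2>Patient</h2>
  <p><b>Name:</b> $name<br><b>Age:</b> $age<br><b>Sex:</b> $sex<br>
  <b>BMI:</b> $bmi</p>
  <p><b>Diagnoses:</b> <span title="$diagnoses">$n_diagnoses</span><br>
  <b>Prescriptions:</b> <span title="$prescriptions">$n_prescriptions</span></p>
  $selector
</aside>
<main id="main">
  <h1>$drug metabolism pathway</h1>
  $banner
  $svg
  $tooltips
  <section id="guideline-details">
    <h2>Guideline details</h2>
    $details
  </section>
</main>
<aside id="legend">
  <h2>Legend</h2>
  <ul>
$legend
  </ul>
</aside>
<script type="application/json" id="graph-data">$graph_json</script>
<script>
// Click a gene node to pin its tooltip open (hover already shows it via CSS).
document.querySelectorAll('g.node').forEach(function (el) {
  el.addEventListener('click', function () { el.classList.toggle('active'); });
});
</script>
</body>
</html>
"""
)


def render_document(
    g: AnnotatedGraph,
    r: PatientRecord,
    layout: LayoutResult,
    tooltip_budget: int = 240,
) -> str:
    """Render the full interactive report as one self-contained HTML page.

    Contains the patient panel, the SVG graph, a legend with all five
    non-plain symbol classes, per-gene-node tooltips (status, recommendation,
    activity score, severity — truncated to ``tooltip_budget`` characters
    with the full text in the expandable guideline section), a contradiction
    banner when recommendation directions conflict, and a drug selector when
    the record holds more than one prescription.
    """
    svg = render_svg(g, layout)

    legend_items = "\n".join(
        f'    <li class="legend-entry" data-symbol="{sym}">{html.escape(text)}</li>'
        for sym, text in SYMBOL_LEGEND.items()
    )

    tooltips = []
    for n in g.nodes:
        if n.role != "gene":
            continue
        text = " | ".join(_tooltip_lines(n))
        if not text:
            continue
        if len(text) > tooltip_budget:
            text = text[: tooltip_budget - 1] + "… (see guideline details below)"
        tooltips.append(
            f'<div class="tooltip" data-node-id="{html.escape(n.node_id)}">{html.escape(text)}</div>'
        )

    details = []
    seen_gids = set()
    for gl in [x for n in g.gene_nodes() for x in n.guidelines] + list(g.orphan_guidelines):
        if gl.guideline_id in seen_gids:
            continue
        seen_gids.add(gl.guideline_id)
        body = (
            f"<p><b>Status:</b> {html.escape(gl.metabolizer_status)} &mdash; "
            f"<b>Category:</b> {html.escape(gl.recommendation_category)} &mdash; "
            f"<b>Severity:</b> {gl.severity} &mdash; "
            f"<b>Evidence:</b> {html.escape(gl.evidence_level)}</p>"
            f"<p><b>Effect on metabolism:</b> {html.escape(gl.effect_text)}</p>"
            f"<p>{html.escape(gl.recommendation_text)}</p>"
        )
        if gl.source_url:
            body += f'<p><a href="{html.escape(gl.source_url)}">Source</a></p>'
        details.append(
            f'<details class="guideline" data-guideline-id="{html.escape(gl.guideline_id)}">'
            f"<summary>{html.escape(gl.gene)} {html.escape(gl.diplotype)} &times; "
            f"{html.escape(gl.drug_name or g.drug_label)}</summary>{body}</details>"
        )

    banner = ""
    if g.contradictions.conflicts:
        gid_map = {gl.guideline_id: gl for n in g.gene_nodes() for gl in n.guidelines}
        cat_pairs = sorted(
            {
                " vs ".join(
                    sorted(
                        (
                            gid_map[a].recommendation_category,
                            gid_map[b].recommendation_category,
                        )
                    )
                )
                for a, b in g.contradictions.conflicts
                if a in gid_map and b in gid_map
            }
        )
        banner = (
            '<div class="contradiction-banner"><b>Contradictory recommendations:</b> '
            + html.escape("; ".join(cat_pairs))
            + f" ({g.contradictions.varying} varying categories)</div>"
        )

    selector = ""
    if len(r.prescriptions) > 1:
        opts = "\n".join(
            f'    <option value="{html.escape(rx.drug_name)}"'
            + (" selected" if rx.drug_name.strip().lower() == g.drug_label.strip().lower() else "")
            + f">{html.escape(rx.drug_name)}</option>"
            for rx in r.prescriptions
        )
        selector = f'<label>Drug: <select id="drug-selector">\n{opts}\n  </select></label>'

    graph_json = json.dumps(
        {
            "drug": g.drug_label,
            "nodes": [n.node_id for n in g.nodes],
            "contradictions": g.contradictions.model_dump(),
        },
        sort_keys=True,
    )

    return _PAGE.substitute(
        drug=html.escape(g.drug_label),
        name=html.escape(r.name),
        age=r.age if r.age is not None else "n/a",
        sex=html.escape(r.sex),
        bmi=r.bmi if r.bmi is not None else "n/a",
        diagnoses=html.escape(", ".join(r.diagnoses)),
        n_diagnoses=len(r.diagnoses),
        prescriptions=html.escape(", ".join(rx.drug_name for rx in r.prescriptions)),
        n_prescriptions=len(r.prescriptions),
        selector=selector,
        banner=banner,
        svg=svg,
        tooltips="\n".join(tooltips),
        details="\n".join(details),
        legend=legend_items,
        graph_json=graph_json,
    )
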