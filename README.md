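# pgxgraph

Graph-based visualization of pharmacogenomic (PGx) plausibility-check
reports for clinical decision support.

## The problem

When a clinical decision support system (CDSS) screens a prescription
against a patient's pharmacogene variants, the result is a stack of
text-based guidelines: "CYP2D6 \*4/\*6 is a poor metabolizer for
clomipramine — lower the dose to 70 percent", "CYP2C19 \*17/\*17 is an
ultrarapid metabolizer — avoid tertiary amines", and so on. For a drug
metabolized by several polymorphic enzymes these recommendations rarely
agree, and reading them as prose makes the contradictions easy to miss.

`pgxgraph` turns the report into a picture: it joins the drug's metabolism
pathway (a PharmGKB-style table of substrate → product reactions with their
catalyzing enzymes) with the patient's guideline list, and renders an
annotated network in which each enzyme node carries a metabolizer-status
symbol — PM ↓, IM ↘, NM →, UM ↑, and a circled marker for a variant with no
assigned status — plus the attached dose recommendations, and an explicit
flag when recommendations for the same drug pull in opposite directions.
The intended reader is a medical practitioner who wants the patient-specific
pathway at a glance rather than a page of guideline prose.

## The model

* **Pathway**: a rooted directed graph. Exactly one entity is the drug
  (root); each reaction converts one substrate into one product under zero
  or more catalyst genes. Non-enzymatic relationship types (transport,
  inhibition, complex assembly) are kept and drawn dashed.
* **Enzyme interposition and duplication**: a reaction with *k* catalysts
  expands to *k* parallel chains substrate → enzyme → product. A gene
  catalyzing *m* reactions appears as *m* separate nodes (node count per
  gene ≡ its reaction incidence), which keeps the drawing a chain rather
  than a hub-and-spoke cluster.
* **Annotation**: guidelines are joined to enzyme nodes by gene symbol;
  the node symbol follows the metabolizer status (of the highest-severity
  guideline when several sources attach). Guidelines matching the drug but
  no pathway gene are kept as orphans — nothing is dropped silently.
* **Contradictions**: among the closed recommendation directions
  {increase dose, decrease dose, avoid}, every cross pair opposes;
  "standard" and open-ended categories never conflict. The report lists
  each conflicting guideline pair and the number of varying categories.
* **Collapse**: steps unaffected by the patient's variants can be elided
  into a single counted edge, preserving reachability between all retained
  nodes.
* **Layout**: a seeded deterministic spring embedder (pairwise repulsion
  `k³/d²`, edge attraction `d²/k`, energy-descent stepping) — identical
  inputs give bit-identical coordinates, and an isolated connected pair
  settles at distance exactly `k`.

Outputs: a self-contained interactive HTML document (patient panel, symbol
legend, hover tooltips, expandable guideline texts, drug selector,
contradiction banner), static SVG, GraphML and node-link JSON.

## Worked example

The package ships a complete fictitious case: John Doe, 54, male, diagnosed
with ADHD and depression, prescribed atomoxetine and clomipramine, with
variant calls CYP2D6\*4/\*6, CYP2C19\*17/\*17 and CYP3A4\*1A/\*1B.

```python
>>> import pgxgraph as pg
>>> pathway, record = pg.make_worked_example()
>>> guidelines = pg.match_guidelines(record, record.prescriptions[0])
>>> graph = pg.build_graph(pathway, guidelines, record.variants)
>>> len(graph.gene_nodes("CYP2D6"))          # CYP2D6 catalyzes two steps
2
>>> node = graph.gene_nodes("CYP2D6")[0]
>>> node.symbol, node.guidelines[0].metabolizer_status, node.guidelines[0].dose_percent
('arrow_down_pm', 'PM', 70.0)
>>> graph.contradictions.varying, graph.contradictions.conflicts
(2, [('gl-cyp2d6-clomipramine', 'gl-cyp2c19-clomipramine')])
```

CYP2D6 appears twice (once per hydroxylation step it catalyzes), marked as
a poor metabolizer with a 70 % dose recommendation, while the CYP2C19
ultrarapid-metabolizer guideline says to avoid the drug — two varying
recommendation directions, reported as one contradictory pair.

From the shell:

```sh
pgxgraph demo --out demo/            # writes the inputs + rendered report.html
pgxgraph render --pathway demo/clomipramine_pathway.tsv \
    --report demo/john_doe_report.json --drug clomipramine \
    --format svg --out clomipramine.svg --seed 1
```

## Documentation

* `docs/methods.md` — the model, parameters, numerical choices and known
  limitations.
* `docs/patient_report.schema.json` — JSON Schema of the patient report
  interchange document.
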