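# Methods

## Scope and data flow

`pgxgraph` visualizes the output of a pharmacogenomic prescription check.
It consumes two inputs and produces annotated network renderings:

1. a **drug-metabolism pathway table** (tab-separated, one relationship per
   row: source entity, target entity, reaction type, controller genes), the
   dialect used by curated pathway resources such as PharmGKB;
2. a **patient report document** (JSON) from an upstream rule-based CDSS:
   demographics, prescriptions, star-allele variant calls, and per
   drug–gene-variant dosing guidelines.

The package does not translate genotypes to phenotypes, author guidelines,
or talk to any live service; the upstream CDSS is the authority for
diplotypes and metabolizer statuses. Only the join, the graph semantics,
the layout and the renderings are computed here.

## Pathway parsing

Upstream TSV exports are schema-inconsistent, so header matching is
lenient by design: `{From, Source, Substrate}`, `{To, Target, Product}`,
`{Controller, Genes, Enzymes}` and `{Reaction Type, Type}` are accepted
case-insensitively in any column order. Multi-catalyst cells split on
comma/semicolon and gene symbols are uppercased (the downstream join is
symbol-keyed). Rows sharing (substrate, product, reaction type) merge into
one reaction with the union of catalysts — a demethylation step performed
by three enzymes is one edge with three catalysts, not three edges.
Verbatim duplicates are dropped with an info issue; rows missing source or
target are rejected with an error issue; nothing is silently lost
(`parse_pathway_detailed` exposes the full row → reaction assignment, so
row-count conservation is a testable property).

Parsed pathways are canonicalized — root entity first, remaining entities
and reactions sorted by id — which makes parsing insensitive to row/column
permutations and makes parse ∘ serialize the identity. The canonical
serializer is bit-stable. Root resolution is exact case-insensitive label
match, then unique prefix; ambiguity is fatal rather than guessed. A
header-only table yields a synthesized root and a warning. Entity
`compartment` is an in-memory annotation only; the canonical table does not
carry it.

Unrecognized reaction types (transport, inhibition, complex assembly) are
preserved verbatim and rendered dashed. Discarding them would hide real
pathway structure; treating them as enzymatic would overstate it.

## Report semantics

* **Metabolizer status** is stored on the guideline (per drug–gene pair),
  not on the variant call: the same diplotype can imply different
  phenotypes for different substrates. Normalization accepts both the
  abbreviation and spelled-out vocabularies (PM/"poor metabolizer", …,
  with EM/"extensive metabolizer" folded into NM); anything outside the
  table raises, so typos fail loudly rather than mis-annotate.
* **Recommendation categories** normalize by substring — increase →
  `increase_dose`; lower/decrease/reduce → `decrease_dose`; avoid →
  `avoid`; standard/"no action" → `standard` — and otherwise pass through
  verbatim as open categories. A closed set is required by the
  contradiction logic; open categories are displayed but never conflict.
* **Severity** is a 3-tier ordinal (1 informational, 2 warning,
  3 critical), matching typical CDSS alert tiers. The parser clamps
  out-of-range values with a warning; the validator flags them as errors on
  directly constructed records.
* **Dose fractions**: if a recommendation text quantifies the adjustment as
  a percentage ("to 70 percent of the standard dose"), the first percentage
  is extracted into `dose_percent` so the number is machine-readable.
* **CAS numbers** are check-digit validated (positional weighted sum mod
  10); failures are warnings, since upstream data quality varies.
* **Brand aliasing** is a small explicit table (shipped with
  anafranil → clomipramine); no external drug-name service, for
  determinism. Matching prefers CAS equality when both sides carry one,
  falling back to case-insensitive name/brand/alias comparison.

## Graph construction

Enzymes are interposed as nodes (substrate → enzyme → product) because the
status symbols and tooltips live on enzymes. Gene nodes are duplicated per
(gene, reaction) incidence with ids `GENE#reaction_id` (stable,
diff-friendly); duplication keeps the drawing chain-like. The node symbol
mapping is total: PM ↓, IM ↘, NM →, UM ↑, variant-without-status circled,
otherwise plain. When several sources attach to one gene, the displayed
status comes from the maximum-severity guideline (first wins ties), the
displayed severity is the maximum, and a `multi_source` flag marks category
disagreement — fail-safe display over averaging.

Contradiction detection treats every unordered pair among
{increase_dose, decrease_dose, avoid} as opposing (whether avoid vs
decrease counts clinically is configurable via the `opposing` set; the
default says yes, since both cannot be followed simultaneously). `varying`
counts distinct categories excluding `standard`.

### Collapse of unaffected reactions

A reaction is *affected* iff one of its gene nodes has a non-plain symbol.
Retained chemicals are: the root, endpoints of affected reactions,
terminal metabolites, and chemical-level branch points. Every maximal run
of unaffected reactions between two retained chemicals — including a
single such reaction — becomes one `collapsed(count)` edge; intermediate
chemicals and plain gene nodes are elided. Collapsing single unaffected
reactions too is what makes the operation idempotent. Reachability between
retained nodes is preserved by construction (verified against a
breadth-first-search oracle on seeded cases), and a non-plain node can
never be removed because its reaction is affected by definition.

## Layout

The embedder is a deterministic spring model: inverse-square repulsion
`k³/d²` between all pairs and attraction `d²/k` along edges, with ideal
edge length `k = 1` abstract canvas unit (the renderer rescales to the
viewport, so units are arbitrary). These force laws integrate to the
non-negative energy `E = Σ_edges d³/(3k) + k³ Σ_pairs 1/d`, reported as the
layout *stress*. Each epoch moves nodes along the net force with a damped
step (learning rate 0.1, chosen well inside the stability bound for the
pair stiffness `E''(k) = 4`), capped by a cooling temperature (initially
0.2 × the initial placement span, × 0.98 per epoch); a candidate move is
accepted only if it does not increase E, halving the step up to 30 times
otherwise, and the run stops early when no improving move exists at any
scale. Consequences, each of which is tested:

* positions are a pure function of (graph, seed, max_iter, k) —
  bit-identical across runs;
* the stress history is non-increasing and the final stress never exceeds
  that of the seeded random initialization;
* an isolated connected pair converges to the closed-form equilibrium
  `d²/k = k³/d²  ⇒  d = k` (observed error at machine precision, far below
  the 1e-6 test tolerance).

Default `max_iter` is 300 epochs, ample for the graph sizes at hand
(tens of nodes).

## Rendering and export

The HTML report is one self-contained file (inline styles, script and
data; no network fetches) because clinical environments are
offline-hostile. It contains the patient panel, the SVG graph (one glyph
per node, one path per edge — count conservation is tested), a legend
enumerating exactly the five non-plain symbol classes, per-enzyme tooltips
(status, recommendation, activity score, severity) truncated at a
configurable character budget with the full text in an expandable
guideline section with source links, a contradiction banner naming the
conflicting directions, and a drug selector when the record holds more
than one prescription. Shapes are contractual; colors are defaults
(shape carries the meaning for color-blind readers).

GraphML and node-link JSON exports go through networkx with complex
payloads JSON-encoded into scalar attributes; import reconstructs the
annotated graph up to node/edge ordering (`AnnotatedGraph.canonical()`
defines the comparison order), so export ∘ import is the identity up to
isomorphism, collapsed counts included.

## Synthetic case generator

`generate_case(SyntheticSpec)` emulates CDSS output at configurable scale:
a root-connected pathway built as a random spanning tree (metabolite *i*
attaches to an earlier chemical) plus Poisson-many extra forward edges at
rate (branching − 1); catalysts assigned round-robin so every gene
catalyzes at least one reaction (guaranteeing guideline attachment);
phenotypes drawn from `status_probs`; and recommendation directions kept
mutually consistent unless the case is drawn as conflicting (probability
`conflict_rate`), in which case two genes are forced to PM/decrease and
UM/avoid. The observed contradiction frequency therefore equals
`conflict_rate` by construction, which the Monte-Carlo calibration test
checks at ±0.05 over 1000 cases. The pathway is emitted as canonical TSV
and run through the real parser, so generated cases satisfy parser
invariants by construction.

Defaults (6 metabolites, 3 genes, branching 1.3, status distribution
0.15/0.15/0.40/0.15/0.15 over PM/IM/NM/UM/unknown, conflict rate 0.3) are
sized to the small, clearly structured pathways the tool targets — a
handful of metabolites and a few polymorphic CYP enzymes.

What the generator does **not** emulate: real star-allele frequencies,
real guideline prose, schema noise in upstream TSVs beyond header/ordering
variation, multi-drug records, or pathway cycles (generated graphs are
DAGs, although the data model permits cycles). Passing property suites on
synthetic cases therefore demonstrates structural correctness of the
join/duplication/collapse/layout machinery, not clinical fidelity of any
particular guideline content.

## Worked example fidelity

The packaged case reproduces its source material literally, including one
internal tension: the CYP2D6 guideline is marked PM while its effect text
("Increased metabolism of TCAs to less active compounds compared to NMs…")
describes ultrarapid metabolism. The fixture keeps the text as published;
detecting such semantic mismatches between status and effect prose is out
of scope. The exact three-enzyme assignment of the demethylation step
(CYP3A4, CYP2C19, CYP1A2) with CYP2D6 on the two hydroxylation steps
follows the described topology; the upstream database's full pathway
contains further steps not needed for the visualization semantics.

## Known limitations

* Only reaction-level pathway structure is modeled; no pharmacokinetic
  quantities (blood levels, clearances) are computed.
* Contradiction semantics are purely categorical; the magnitude of dose
  adjustments is displayed but not compared.
* The drug selector in the static HTML lists the prescriptions but
  re-rendering for another drug requires another `render` invocation; the
  document embeds one graph.
* Very large pathways (many dozens of metabolites) will produce cluttered
  drawings; collapse mitigates but does not remove this.
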