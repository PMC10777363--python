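"""Parsing, validation and canonical serialization of drug-metabolism pathways.

A pathway is read from the tab-separated dialect used by curated pathway
databases such as PharmGKB: one row per relationship, with a source entity, a
target entity, a reaction type and the controller genes (the enzymes
catalyzing the step). Upstream TSV exports do not follow a single schema, so
header matching is deliberately lenient: column synonyms are accepted and
header case and column order are ignored.

The in-memory model is a rooted directed graph: exactly one entity is the
drug itself (the pathway root), all other entities are metabolites, and each
:class:`Reaction` converts one substrate into one product under zero or more
catalyst genes.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import IO, Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .issues import Issue

__all__ = [
    "ChemicalEntity",
    "Reaction",
    "Pathway",
    "PathwayParseError",
    "RootNotFoundError",
    "ParseResult",
    "parse_pathway",
    "parse_pathway_detailed",
    "validate_pathway",
    "serialize_pathway",
]

#: Reaction type label for ordinary enzymatic conversions. Anything else
#: (inhibition, transport, complex assembly, ...) is kept verbatim and later
#: rendered with a dashed edge rather than silently dropped.
BIOCHEMICAL = "biochemical"

# Accepted header synonyms, all matched case-insensitively after stripping.
_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "from": ("from", "source", "substrate"),
    "to": ("to", "target", "product"),
    "controller": ("controller", "genes", "enzymes", "controllers", "gene"),
    "reaction_type": ("reaction type", "type", "reaction_type", "reactiontype"),
}

_CATALYST_SPLIT = re.compile(r"[;,]")


class PathwayParseError(ValueError):
    """The pathway stream could not be parsed at all."""


class RootNotFoundError(PathwayParseError):
    """No entity in the table matches the requested drug name."""


class ChemicalEntity(BaseModel):
    """A chemical species in the pathway: the drug itself or a metabolite."""

    entity_id: str
    label: str
    kind: Literal["drug", "metabolite"]
    compartment: Optional[str] = None

    @field_validator("label")
    @classmethod
    def _label_non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("entity label must be non-empty")
        return v


class Reaction(BaseModel):
    """One metabolic step: substrate -> product, catalyzed by zero or more genes.

    ``reaction_type`` is :data:`BIOCHEMICAL` for enzymatic conversions;
    unrecognized upstream types are preserved verbatim (lower-cased).
    """

    reaction_id: str
    substrate_id: str
    product_id: str
    catalysts: tuple[str, ...] = ()
    reaction_type: str = BIOCHEMICAL

    @property
    def is_biochemical(self) -> bool:
        return self.reaction_type == BIOCHEMICAL


class Pathway(BaseModel):
    """A drug's metabolism network rooted at the drug entity."""

    drug_name: str
    drug_cas: Optional[str] = None
    entities: list[ChemicalEntity] = Field(default_factory=list)
    reactions: list[Reaction] = Field(default_factory=list)

    @property
    def root(self) -> ChemicalEntity:
        """The unique drug entity. Raises ``ValueError`` if absent."""
        drugs = [e for e in self.entities if e.kind == "drug"]
        if len(drugs) != 1:
            raise ValueError(f"pathway must have exactly one drug entity, found {len(drugs)}")
        return drugs[0]

    def entity_map(self) -> dict[str, ChemicalEntity]:
        return {e.entity_id: e for e in self.entities}

    def catalyst_genes(self) -> set[str]:
        """All gene symbols appearing as catalysts anywhere in the pathway."""
        return {g for r in self.reactions for g in r.catalysts}


class ParseResult(BaseModel):
    """Pathway plus full per-row accounting of the parse.

    ``row_assignments[i]`` is the reaction_id the i-th data row contributed
    to, or ``None`` if the row was rejected (in which case an error issue
    names the row). Every input row is therefore accounted for.
    """

    pathway: Pathway
    issues: list[Issue] = Field(default_factory=list)
    row_assignments: list[Optional[str]] = Field(default_factory=list)


def _slug(label: str) -> str:
    """Stable entity id from a display label."""
    return re.sub(r"[^a-z0-9_-]+", "_", label.strip().lower()).strip("_")


def _resolve_columns(header: list[str]) -> dict[str, str]:
    """Map canonical role -> actual column name, case-insensitively."""
    lowered = {h.strip().lower(): h for h in header}
    resolved: dict[str, str] = {}
    for role, synonyms in _COLUMN_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                resolved[role] = lowered[syn]
                break
    return resolved


def _split_catalysts(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    parts = [p.strip().upper() for p in _CATALYST_SPLIT.split(str(cell))]
    seen: list[str] = []
    for p in parts:
        if p and p not in seen:
            seen.append(p)
    return tuple(seen)


def _read_table(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    try:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        elif isinstance(source, str):
            # A TSV payload necessarily contains a tab or newline; a bare
            # token is taken to be a filesystem path.
            text = source if ("\t" in source or "\n" in source) else Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
    except OSError as exc:
        raise PathwayParseError(f"unreadable pathway stream: {exc}") from exc
    if not text.strip():
        raise PathwayParseError("empty pathway stream (no header row)")
    try:
        return pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise PathwayParseError(f"cannot parse pathway table: {exc}") from exc


def parse_pathway_detailed(
    source: Union[str, Path, IO[str]],
    drug_name: str,
) -> ParseResult:
    """Parse a pathway table with full row-level accounting.

    ``source`` may be a path, an open text stream, or the TSV text itself
    (anything containing a tab or newline is treated as literal content).

    Rows sharing (substrate, product, reaction type) are merged into a single
    :class:`Reaction` with the union of their catalyst lists — a step drawn
    once with three enzymes, not three parallel edges. Verbatim duplicate
    rows are deduplicated with an info issue; rows missing source or target
    are rejected with an error issue, never a crash.
    """
    df = _read_table(source)
    issues: list[Issue] = []
    columns = _resolve_columns(list(df.columns))
    if "from" not in columns or "to" not in columns:
        raise PathwayParseError(
            f"cannot identify source/target columns in header {list(df.columns)!r}"
        )

    # First pass: collect rows into (substrate, product, type) groups.
    groups: dict[tuple[str, str, str], dict] = {}
    row_keys: list[Optional[tuple[str, str, str]]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        src = str(rowd.get(columns["from"], "")).strip()
        dst = str(rowd.get(columns["to"], "")).strip()
        loc = f"row {i + 1}"
        if not src or not dst:
            issues.append(Issue(severity="error", message="missing source or target entity", location=loc))
            row_keys.append(None)
            continue
        if src.lower() == dst.lower():
            issues.append(Issue(severity="error", message=f"substrate equals product ({src!r})", location=loc))
            row_keys.append(None)
            continue
        rtype_raw = str(rowd.get(columns.get("reaction_type", ""), "")).strip().lower() if "reaction_type" in columns else ""
        rtype = rtype_raw or BIOCHEMICAL
        if rtype != BIOCHEMICAL:
            issues.append(Issue(severity="info", message=f"non-biochemical reaction type {rtype!r} retained", location=loc))
        catalysts = _split_catalysts(rowd.get(columns["controller"])) if "controller" in columns else ()
        key = (_slug(src), _slug(dst), rtype)
        if key in groups:
            g = groups[key]
            if catalysts and set(catalysts) <= set(g["catalysts"]):
                issues.append(Issue(severity="info", message="duplicate relationship row merged", location=loc))
            for c in catalysts:
                if c not in g["catalysts"]:
                    g["catalysts"].append(c)
        else:
            groups[key] = {"src_label": src, "dst_label": dst, "rtype": rtype, "catalysts": list(catalysts)}
        row_keys.append(key)

    # Entities, in first-appearance order.
    labels: dict[str, str] = {}
    for g in groups.values():
        for lab in (g["src_label"], g["dst_label"]):
            labels.setdefault(_slug(lab), lab)

    root_id = _resolve_root(labels, drug_name, issues)

    entities = [
        ChemicalEntity(entity_id=eid, label=lab, kind="drug" if eid == root_id else "metabolite")
        for eid, lab in labels.items()
    ]

    reactions = []
    key_to_rid: dict[tuple[str, str, str], str] = {}
    for (src_id, dst_id, rtype), g in groups.items():
        rid = f"{src_id}->{dst_id}" + (f"#{rtype}" if rtype != BIOCHEMICAL else "")
        key_to_rid[(src_id, dst_id, rtype)] = rid
        reactions.append(
            Reaction(
                reaction_id=rid,
                substrate_id=src_id,
                product_id=dst_id,
                catalysts=tuple(g["catalysts"]),
                reaction_type=rtype,
            )
        )

    # Canonical order: root entity first, the rest by id; reactions by id.
    # This makes parse order-insensitive (column/row permutations of the same
    # relationships parse to identical Pathways) and parse∘serialize an identity.
    entities.sort(key=lambda e: (e.kind != "drug", e.entity_id))
    reactions.sort(key=lambda r: r.reaction_id)
    pathway = Pathway(drug_name=drug_name, entities=entities, reactions=reactions)
    assignments = [key_to_rid[k] if k is not None else None for k in row_keys]
    return ParseResult(pathway=pathway, issues=issues, row_assignments=assignments)


def _resolve_root(labels: dict[str, str], drug_name: str, issues: list[Issue]) -> str:
    """Find the root entity id, synthesizing one for an empty table.

    Exact case-insensitive label match first, then unique prefix match;
    ambiguity or no match is fatal.
    """
    if not labels:
        issues.append(Issue(severity="warning", message="table has no relationship rows; synthesized root entity"))
        rid = _slug(drug_name) or "drug"
        labels[rid] = drug_name
        return rid
    want = drug_name.strip().lower()
    exact = [eid for eid, lab in labels.items() if lab.strip().lower() == want]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        raise RootNotFoundError(f"ambiguous root: {len(exact)} entities labeled {drug_name!r}")
    prefix = [eid for eid, lab in labels.items() if lab.strip().lower().startswith(want)]
    if len(prefix) == 1:
        return prefix[0]
    if len(prefix) > 1:
        raise RootNotFoundError(f"ambiguous root: {len(prefix)} entity labels start with {drug_name!r}")
    raise RootNotFoundError(f"root not found: no entity matches drug name {drug_name!r}")


def parse_pathway(
    source: Union[str, Path, IO[str]],
    drug_name: str,
    issues: Optional[list[Issue]] = None,
) -> Pathway:
    """Parse a pathway table into a :class:`Pathway`.

    Parameters
    ----------
    source:
        Path, open text stream, or literal TSV text with a header row.
    drug_name:
        Display name of the drug; must match the root entity's label
        (case-insensitive, with unique-prefix fallback).
    issues:
        Optional list that collected parse issues are appended to.
    """
    result = parse_pathway_detailed(source, drug_name)
    if issues is not None:
        issues.extend(result.issues)
    return result.pathway


def validate_pathway(p: Pathway) -> list[Issue]:
    """Check all pathway invariants; pure function, never mutates ``p``.

    Errors: duplicate ids, dangling reaction references, substrate==product,
    not exactly one drug entity. Warnings: entities unreachable from the root.
    """
    issues: list[Issue] = []
    seen_e: set[str] = set()
    for e in p.entities:
        if e.entity_id in seen_e:
            issues.append(Issue(severity="error", message=f"duplicate entity id {e.entity_id!r}", location=e.entity_id))
        seen_e.add(e.entity_id)
    drugs = [e for e in p.entities if e.kind == "drug"]
    if len(drugs) != 1:
        issues.append(Issue(severity="error", message=f"pathway must have exactly one drug entity, found {len(drugs)}"))
    seen_r: set[str] = set()
    for r in p.reactions:
        if r.reaction_id in seen_r:
            issues.append(Issue(severity="error", message=f"duplicate reaction id {r.reaction_id!r}", location=r.reaction_id))
        seen_r.add(r.reaction_id)
        for ref in (r.substrate_id, r.product_id):
            if ref not in seen_e and ref not in {e.entity_id for e in p.entities}:
                issues.append(Issue(severity="error", message=f"reaction references unknown entity {ref!r}", location=r.reaction_id))
        if r.substrate_id == r.product_id:
            issues.append(Issue(severity="error", message="substrate equals product", location=r.reaction_id))
    # Reachability from the root over directed reactions (breadth-first).
    if len(drugs) == 1:
        adj: dict[str, list[str]] = {}
        for r in p.reactions:
            adj.setdefault(r.substrate_id, []).append(r.product_id)
        reached = {drugs[0].entity_id}
        frontier = [drugs[0].entity_id]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in reached:
                        reached.add(v)
                        nxt.append(v)
            frontier = nxt
        for e in p.entities:
            if e.entity_id not in reached:
                issues.append(Issue(severity="warning", message=f"entity {e.label!r} unreachable from root", location=e.entity_id))
    return issues


def serialize_pathway(p: Pathway) -> str:
    """Canonical, bit-stable TSV serialization.

    Columns ``From, To, Reaction Type, Controller``; reactions sorted by
    reaction_id; catalysts comma-joined. ``parse_pathway(serialize_pathway(p),
    p.drug_name)`` is the identity on parsed pathways.
    """
    emap = p.entity_map()
    lines = ["From\tTo\tReaction Type\tController"]
    for r in sorted(p.reactions, key=lambda r: r.reaction_id):
        lines.append(
            "\t".join(
                [
                    emap[r.substrate_id].label,
                    emap[r.product_id].label,
                    r.reaction_type,
                    ", ".join(r.catalysts),
                ]
            )
        )
    return "\n".join(lines) + "\n"
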