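"""The patient PGx report record: parsing, validation, guideline matching.

The second input of the visualization pipeline is a JSON document produced
by an upstream rule-based clinical decision support system (CDSS). It holds
demographics, the current prescriptions, the patient's gene-variant calls
(star-allele diplotypes with activity scores), and a list of evidence-based
dosing guidelines, one per drug–gene-variant pair.

Genotype→phenotype translation is out of scope: the metabolizer status (PM,
IM, NM, UM) is taken as given from the CDSS, attached to the guideline (the
status is per drug–gene pair, not per gene). Free-text statuses and
recommendation directions from heterogeneous sources (PharmGKB clinical
annotations, DPWG dose guidelines) are normalized to closed vocabularies so
downstream contradiction logic can compare them.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import IO, Optional, Union

from pydantic import BaseModel, Field

from .issues import Issue

__all__ = [
    "GeneVariantCall",
    "Guideline",
    "Prescription",
    "PatientRecord",
    "ReportParseError",
    "parse_report",
    "serialize_report",
    "validate_report",
    "match_guidelines",
    "normalize_status",
    "normalize_category",
    "validate_cas",
    "BRAND_ALIASES",
]

METABOLIZER_STATUSES = ("PM", "IM", "NM", "UM", "UNKNOWN")
EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3", "4", "NONE")
#: Closed recommendation-direction vocabulary used by contradiction logic.
#: Values outside this set are "other" categories carried verbatim.
CLOSED_CATEGORIES = ("increase_dose", "decrease_dose", "avoid", "standard")

#: Explicit brand-name → active-agent table. Deliberately tiny and local:
#: no external drug-name service is consulted.
BRAND_ALIASES: dict[str, str] = {"anafranil": "clomipramine"}

_DIPLOTYPE_RE = re.compile(r"^\*[^/\s]+/\*[^/\s]+$")
_PERCENT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(?:%|percent\b)", re.IGNORECASE)

# Metabolizer-status synonym table (DPWG and PharmGKB vocabularies).
_STATUS_TABLE: dict[str, str] = {
    "pm": "PM", "poor metabolizer": "PM",
    "im": "IM", "intermediate metabolizer": "IM",
    "nm": "NM", "em": "NM", "normal metabolizer": "NM", "extensive metabolizer": "NM",
    "um": "UM", "ultrarapid metabolizer": "UM", "ultra-rapid metabolizer": "UM",
    "unknown": "UNKNOWN", "": "UNKNOWN",
}


class ReportParseError(ValueError):
    """The report document is not well-formed."""


def normalize_status(text: Optional[str]) -> str:
    """Normalize a metabolizer-status string to PM/IM/NM/UM/UNKNOWN.

    Total over the documented synonym table (case-insensitive); raises
    ``ValueError`` for anything outside it.
    """
    key = (text or "").strip().lower()
    try:
        return _STATUS_TABLE[key]
    except KeyError:
        raise ValueError(f"unrecognized metabolizer status {text!r}") from None


def normalize_category(text: Optional[str]) -> str:
    """Normalize a recommendation direction to the closed category vocabulary.

    Substring rules: "increase" → increase_dose; "lower"/"decrease"/"reduce"
    → decrease_dose; "avoid" → avoid; "standard"/"no action" → standard.
    Anything else is carried verbatim as an open "other" category.
    """
    raw = (text or "").strip()
    low = raw.lower()
    if not low:
        return "standard"
    if low in CLOSED_CATEGORIES:
        return low
    if "increase" in low:
        return "increase_dose"
    if "lower" in low or "decrease" in low or "reduce" in low:
        return "decrease_dose"
    if "avoid" in low:
        return "avoid"
    if "standard" in low or "no action" in low:
        return "standard"
    return raw


def validate_cas(cas: str) -> bool:
    """CAS registry number check-digit validation.

    The check digit equals the sum of the other digits, each weighted by its
    position counted from the right, modulo 10.
    """
    m = re.fullmatch(r"(\d{2,7})-(\d{2})-(\d)", cas.strip())
    if not m:
        return False
    digits = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


def extract_dose_percent(text: str) -> Optional[float]:
    """First percentage mentioned in a recommendation text, if any."""
    m = _PERCENT_RE.search(text or "")
    return float(m.group(1)) if m else None


class GeneVariantCall(BaseModel):
    """A patient's star-allele diplotype for one pharmacogene."""

    gene: str
    diplotype: str
    activity_score: Optional[float] = None


class Guideline(BaseModel):
    """One evidence-based drug–gene-variant dosing recommendation.

    ``metabolizer_status`` is per drug–gene pair (the same diplotype can
    imply different phenotypes for different substrates). ``dose_percent``
    is derived from ``recommendation_text`` at parse time when the text
    quantifies the adjustment as a percentage.
    """

    guideline_id: str = ""
    gene: str
    diplotype: str = ""
    metabolizer_status: str = "UNKNOWN"
    drug_name: str = ""
    drug_cas: str = ""
    recommendation_text: str = ""
    recommendation_category: str = "standard"
    severity: int = 1
    evidence_level: str = "NONE"
    source_url: str = ""
    effect_text: str = ""
    dose_percent: Optional[float] = None

    @property
    def is_actionable(self) -> bool:
        return self.recommendation_category in ("increase_dose", "decrease_dose", "avoid")


class Prescription(BaseModel):
    """A prescribed drug, optionally under a brand name."""

    drug_name: str
    drug_cas: Optional[str] = None
    brand_name: Optional[str] = None


class PatientRecord(BaseModel):
    """Demographics + prescriptions + variant calls + guidelines."""

    name: str = ""
    age: Optional[int] = None
    sex: str = ""
    bmi: Optional[float] = None
    diagnoses: list[str] = Field(default_factory=list)
    prescriptions: list[Prescription] = Field(default_factory=list)
    variants: list[GeneVariantCall] = Field(default_factory=list)
    guidelines: list[Guideline] = Field(default_factory=list)

    def variant_for(self, gene: str) -> Optional[GeneVariantCall]:
        for v in self.variants:
            if v.gene.upper() == gene.upper():
                return v
        return None


_KNOWN_TOP = set(PatientRecord.model_fields)
_KNOWN_GUIDELINE = set(Guideline.model_fields)
_KNOWN_VARIANT = set(GeneVariantCall.model_fields)
_KNOWN_RX = set(Prescription.model_fields)


def _warn_unknown(d: dict, known: set[str], where: str, issues: list[Issue]) -> dict:
    for k in d:
        if k not in known:
            issues.append(Issue(severity="warning", message=f"unknown field {k!r} ignored", location=where))
    return {k: v for k, v in d.items() if k in known}


def parse_report(
    source: Union[str, Path, IO[str]],
    issues: Optional[list[Issue]] = None,
) -> PatientRecord:
    """Parse a patient report JSON document into a :class:`PatientRecord`.

    Unknown fields are ignored with a warning; metabolizer statuses and
    recommendation categories are normalized; severities outside 1..3 are
    clamped with a warning; a guideline missing both drug identifiers is
    rejected with an issue. A malformed document is fatal.
    """
    collected: list[Issue] = []
    try:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        elif isinstance(source, str):
            text = source if source.lstrip().startswith(("{", "[")) else Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
        doc = json.loads(text)
    except (OSError, json.JSONDecodeError) as exc:
        raise ReportParseError(f"malformed report document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ReportParseError("report document must be a JSON object")

    top = _warn_unknown(doc, _KNOWN_TOP, "record", collected)

    variants = []
    for i, v in enumerate(top.pop("variants", []) or []):
        v = _warn_unknown(dict(v), _KNOWN_VARIANT, f"variants[{i}]", collected)
        v["gene"] = str(v.get("gene", "")).strip().upper()
        variants.append(GeneVariantCall(**v))

    prescriptions = []
    for i, rx in enumerate(top.pop("prescriptions", []) or []):
        rx = _warn_unknown(dict(rx), _KNOWN_RX, f"prescriptions[{i}]", collected)
        prescriptions.append(Prescription(**rx))

    guidelines = []
    for i, g in enumerate(top.pop("guidelines", []) or []):
        where = f"guidelines[{i}]"
        g = _warn_unknown(dict(g), _KNOWN_GUIDELINE, where, collected)
        if not str(g.get("drug_name", "")).strip() and not str(g.get("drug_cas", "")).strip():
            collected.append(Issue(severity="error", message="guideline missing both drug name and CAS; rejected", location=where))
            continue
        g["gene"] = str(g.get("gene", "")).strip().upper()
        try:
            g["metabolizer_status"] = normalize_status(g.get("metabolizer_status"))
        except ValueError as exc:
            collected.append(Issue(severity="warning", message=f"{exc}; treated as UNKNOWN", location=where))
            g["metabolizer_status"] = "UNKNOWN"
        g["recommendation_category"] = normalize_category(g.get("recommendation_category"))
        sev = int(g.get("severity", 1))
        if not 1 <= sev <= 3:
            collected.append(Issue(severity="warning", message=f"severity {sev} clamped into 1..3", location=where))
            g["severity"] = min(3, max(1, sev))
        cas = str(g.get("drug_cas", "")).strip()
        if cas and not validate_cas(cas):
            collected.append(Issue(severity="warning", message=f"CAS number {cas!r} fails check-digit validation", location=where))
        if not g.get("guideline_id"):
            g["guideline_id"] = f"g{len(guidelines) + 1}"
        gl = Guideline(**g)
        if gl.dose_percent is None:
            gl = gl.model_copy(update={"dose_percent": extract_dose_percent(gl.recommendation_text)})
        guidelines.append(gl)

    record = PatientRecord(
        **top, variants=variants, prescriptions=prescriptions, guidelines=guidelines
    )
    if issues is not None:
        issues.extend(collected)
    return record


def serialize_report(r: PatientRecord) -> str:
    """Canonical JSON serialization; ``parse_report`` of it round-trips."""
    return json.dumps(r.model_dump(), indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def validate_report(r: PatientRecord) -> list[Issue]:
    """Check all record invariants; pure function.

    Errors: empty gene symbols, malformed diplotypes, severity outside 1..3,
    unknown status/evidence enums, guideline with no drug identifier,
    negative activity scores. Warnings: a guideline whose gene has no
    variant call; invalid CAS check digits.
    """
    issues: list[Issue] = []
    variant_genes = {v.gene.upper() for v in r.variants}
    for i, v in enumerate(r.variants):
        loc = f"variants[{i}]"
        if not v.gene.strip():
            issues.append(Issue(severity="error", message="variant gene symbol empty", location=loc))
        elif v.gene != v.gene.upper():
            issues.append(Issue(severity="error", message=f"gene symbol {v.gene!r} not uppercase", location=loc))
        if not _DIPLOTYPE_RE.match(v.diplotype):
            issues.append(Issue(severity="error", message=f"diplotype {v.diplotype!r} not of form *x/*y", location=loc))
        if v.activity_score is not None and v.activity_score < 0:
            issues.append(Issue(severity="error", message="activity score negative", location=loc))
    for i, rx in enumerate(r.prescriptions):
        if not rx.drug_name.strip():
            issues.append(Issue(severity="error", message="prescription drug name empty", location=f"prescriptions[{i}]"))
        if rx.drug_cas and not validate_cas(rx.drug_cas):
            issues.append(Issue(severity="warning", message=f"CAS number {rx.drug_cas!r} fails check-digit validation", location=f"prescriptions[{i}]"))
    for i, g in enumerate(r.guidelines):
        loc = f"guidelines[{i}]"
        if not g.gene.strip():
            issues.append(Issue(severity="error", message="guideline gene symbol empty", location=loc))
        if not 1 <= g.severity <= 3:
            issues.append(Issue(severity="error", message=f"severity {g.severity} outside 1..3", location=loc))
        if g.metabolizer_status not in METABOLIZER_STATUSES:
            issues.append(Issue(severity="error", message=f"unknown metabolizer status {g.metabolizer_status!r}", location=loc))
        if g.evidence_level not in EVIDENCE_LEVELS:
            issues.append(Issue(severity="error", message=f"unknown evidence level {g.evidence_level!r}", location=loc))
        if not g.drug_name.strip() and not g.drug_cas.strip():
            issues.append(Issue(severity="error", message="guideline missing both drug name and CAS", location=loc))
        if g.drug_cas and not validate_cas(g.drug_cas):
            issues.append(Issue(severity="warning", message=f"CAS number {g.drug_cas!r} fails check-digit validation", location=loc))
        if g.gene and g.gene.upper() not in variant_genes:
            issues.append(Issue(severity="warning", message=f"guideline gene {g.gene} has no variant call in the record", location=loc))
    return issues


def _alias(name: str) -> str:
    return BRAND_ALIASES.get(name.strip().lower(), name.strip().lower())


def match_guidelines(
    r: PatientRecord,
    drug: Prescription,
    aliases: Optional[dict[str, str]] = None,
) -> list[Guideline]:
    """Guidelines from ``r`` applying to one prescription, input order kept.

    CAS equality wins when both sides carry a CAS number; otherwise the
    guideline's drug name is compared case-insensitively against the
    prescription's drug name, brand name, and their brand-alias resolutions.
    """
    table = BRAND_ALIASES if aliases is None else aliases

    def resolve(name: Optional[str]) -> Optional[str]:
        if not name:
            return None
        low = name.strip().lower()
        return table.get(low, low)

    names = {n for n in (resolve(drug.drug_name), resolve(drug.brand_name)) if n}
    out: list[Guideline] = []
    for g in r.guidelines:
        if g.drug_cas and drug.drug_cas:
            if g.drug_cas.strip() == drug.drug_cas.strip():
                out.append(g)
            continue
        if resolve(g.drug_name) in names:
            out.append(g)
    return out
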