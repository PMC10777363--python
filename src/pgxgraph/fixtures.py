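"""Packaged worked example and seeded synthetic case generator.

The worked example is a fictitious 54-year-old male patient ("John Doe")
diagnosed with ADHD and depression, prescribed atomoxetine and clomipramine,
with variant calls CYP2D6*4/*6, CYP2C19*17/*17 and CYP3A4*1A/*1B. His
clomipramine guidelines disagree: the CYP2D6 poor-metabolizer guideline
lowers the dose to 70 percent of standard while the CYP2C19 ultrarapid
guideline recommends avoiding tertiary amines — the canonical contradiction
case. Both inputs ship as data files in the same formats the parsers
consume, so the parsers (not constructors) are exercised.

The synthetic generator emulates CDSS output at configurable scale: a
root-connected random pathway (spanning tree plus extra edges), genes
assigned round-robin so every gene catalyzes at least one reaction, and
guidelines whose recommendation directions are mutually consistent unless a
case is drawn as conflicting, making the contradiction rate of generated
cases equal to ``conflict_rate`` by construction.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from pydantic import BaseModel, field_validator, model_validator

from .pathway_io import Pathway, parse_pathway
from .report import (
    GeneVariantCall,
    Guideline,
    PatientRecord,
    Prescription,
    parse_report,
)

__all__ = ["SyntheticSpec", "make_worked_example", "generate_case", "worked_example_paths"]

_STATUSES = ("PM", "IM", "NM", "UM", "UNKNOWN")


def _data_text(name: str) -> str:
    return (resources.files("pgxgraph") / "data" / name).read_text(encoding="utf-8")


def worked_example_paths() -> dict[str, str]:
    """Names of the packaged worked-example data files."""
    return {
        "pathway": "clomipramine_pathway.tsv",
        "report": "john_doe_report.json",
    }


def make_worked_example() -> tuple[Pathway, PatientRecord]:
    """The packaged clomipramine pathway and John Doe patient record."""
    pathway = parse_pathway(_data_text("clomipramine_pathway.tsv"), "clomipramine")
    record = parse_report(_data_text("john_doe_report.json"))
    return pathway, record


class SyntheticSpec(BaseModel):
    """Parameters of one synthetic CDSS case.

    ``status_probs`` is the (PM, IM, NM, UM, UNKNOWN) phenotype distribution;
    ``branching`` is the mean chemical out-degree (1.0 = pure chain/tree);
    ``conflict_rate`` is the probability that a case carries an
    opposing-category guideline pair.
    """

    seed: int
    n_metabolites: int = 6
    n_genes: int = 3
    branching: float = 1.3
    status_probs: tuple[float, float, float, float, float] = (0.15, 0.15, 0.4, 0.15, 0.15)
    conflict_rate: float = 0.3

    @field_validator("n_metabolites")
    @classmethod
    def _at_least_one_metabolite(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_metabolites must be >= 1")
        return v

    @field_validator("n_genes")
    @classmethod
    def _nonneg_genes(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_genes must be >= 0")
        return v

    @field_validator("branching")
    @classmethod
    def _positive_branching(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("branching must be > 0")
        return v

    @model_validator(mode="after")
    def _probs_sum_to_one(self) -> "SyntheticSpec":
        if any(p < 0 or p > 1 for p in self.status_probs):
            raise ValueError("status_probs entries must be in [0, 1]")
        if abs(sum(self.status_probs) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")
        if not 0 <= self.conflict_rate <= 1:
            raise ValueError("conflict_rate must be in [0, 1]")
        return self


_DIRECTION_TEXT = {
    "decrease_dose": "Reduce the dose and monitor plasma concentrations.",
    "increase_dose": "Increase the dose and monitor therapeutic response.",
    "avoid": "Avoid this drug; select an alternative.",
    "standard": "Use the standard dose.",
}


def generate_case(spec: SyntheticSpec) -> tuple[Pathway, PatientRecord]:
    """Generate a deterministic synthetic (pathway, record) pair.

    The pathway is built as canonical TSV text and run through
    :func:`parse_pathway`, so every generated case satisfies the parser's
    invariants by construction; the same seed yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    drug = "syntharol"
    chems = [drug] + [f"M{i}" for i in range(1, spec.n_metabolites + 1)]
    genes = [f"SYNGENE{i}" for i in range(1, spec.n_genes + 1)]

    # Random spanning tree rooted at the drug: metabolite i attaches to an
    # earlier chemical; gene coverage is round-robin over tree reactions.
    edges: list[tuple[int, int, list[str]]] = []
    edge_set: set[tuple[int, int]] = set()
    for i in range(1, spec.n_metabolites + 1):
        parent = int(rng.integers(0, i))
        catalysts = []
        if genes:
            catalysts.append(genes[(i - 1) % len(genes)])
            if len(genes) > 1 and rng.random() < 0.3:
                extra = genes[int(rng.integers(0, len(genes)))]
                if extra not in catalysts:
                    catalysts.append(extra)
        edges.append((parent, i, catalysts))
        edge_set.add((parent, i))

    # Extra cross edges at rate (branching - 1).
    if spec.branching > 1.0 and spec.n_metabolites >= 2:
        n_extra = int(rng.poisson((spec.branching - 1.0) * spec.n_metabolites))
        for _ in range(n_extra):
            u = int(rng.integers(0, spec.n_metabolites))
            v = int(rng.integers(u + 1, spec.n_metabolites + 1))
            if (u, v) in edge_set:
                continue
            catalysts = [genes[int(rng.integers(0, len(genes)))]] if genes and rng.random() < 0.8 else []
            edges.append((u, v, catalysts))
            edge_set.add((u, v))

    tsv_lines = ["From\tTo\tReaction Type\tController"]
    for u, v, catalysts in edges:
        tsv_lines.append(f"{chems[u]}\t{chems[v]}\tbiochemical\t{', '.join(catalysts)}")
    pathway = parse_pathway("\n".join(tsv_lines) + "\n", drug)

    used_genes = [g for g in genes if g in pathway.catalyst_genes()]

    statuses = {g: _STATUSES[int(rng.choice(5, p=list(spec.status_probs)))] for g in used_genes}
    direction = "decrease_dose" if rng.random() < 0.5 else "increase_dose"
    conflicted = bool(rng.random() < spec.conflict_rate) and len(used_genes) >= 2
    if conflicted:
        statuses[used_genes[0]] = "PM"
        statuses[used_genes[1]] = "UM"

    variants = []
    guidelines = []
    for g in used_genes:
        a, b = int(rng.integers(1, 40)), int(rng.integers(1, 40))
        diplotype = f"*{a}/*{b}"
        variants.append(
            GeneVariantCall(gene=g, diplotype=diplotype, activity_score=round(float(rng.uniform(0, 3)), 2))
        )
        status = statuses[g]
        if status == "UNKNOWN":
            continue  # variant without guideline: circled-variant symbol case
        if conflicted and g == used_genes[0]:
            category = "decrease_dose"
        elif conflicted and g == used_genes[1]:
            category = "avoid"
        elif status == "NM":
            category = "standard"
        else:
            category = direction
        guidelines.append(
            Guideline(
                guideline_id=f"syn-{g.lower()}",
                gene=g,
                diplotype=diplotype,
                metabolizer_status=status,
                drug_name=drug,
                recommendation_category=category,
                recommendation_text=_DIRECTION_TEXT[category],
                severity=int(rng.integers(1, 4)),
                evidence_level="3",
                source_url="https://example.org/synthetic-guideline",
                effect_text=f"Synthetic effect of {g} {diplotype} on {drug} metabolism.",
            )
        )

    record = PatientRecord(
        name=f"Synthetic Patient {spec.seed}",
        age=int(rng.integers(18, 91)),
        sex="female" if rng.random() < 0.5 else "male",
        bmi=round(float(rng.uniform(17, 35)), 1),
        diagnoses=["synthetic indication"],
        prescriptions=[Prescription(drug_name=drug)],
        variants=variants,
        guidelines=guidelines,
    )
    return pathway, record
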