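"""Validation and parse issues shared across the package.

Every parser and validator reports problems as :class:`Issue` records instead
of raising, except for genuinely fatal conditions (unreadable input, missing
pathway root). Severity levels mirror typical CDSS alert tiers.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel

Severity = Literal["info", "warning", "error"]


class Issue(BaseModel):
    """One validation or parse finding.

    Attributes
    ----------
    severity:
        ``info`` (bookkeeping, e.g. a deduplicated row), ``warning``
        (suspicious but usable input) or ``error`` (invariant violation).
    message:
        Human-readable description.
    location:
        Where the problem was found, e.g. ``"row 4"`` or a reaction id.
    """

    severity: Severity
    message: str
    location: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity.upper()}{loc}: {self.message}"


def has_errors(issues: list[Issue]) -> bool:
    """True if any issue is error-severity."""
    return any(i.severity == "error" for i in issues)
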