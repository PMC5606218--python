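"""Exception hierarchy and the row-level validation issue record."""

from __future__ import annotations

from dataclasses import dataclass


class MediSynError(Exception):
    """Base class for all errors raised by this package."""


class DialectError(MediSynError):
    """A source table does not match its dialect (e.g. a required column is absent)."""


class StoreFormatError(MediSynError):
    """A serialized store could not be decoded (corrupt file or schema-version mismatch)."""


class UnsatisfiableSpecError(MediSynError):
    """A fixture specification violates its own cardinality constraints."""


class UnknownTargetError(MediSynError):
    """A requested target does not exist in the store; carries nearest matches."""

    def __init__(self, token: str, suggestions: list[str]):
        self.token = token
        self.suggestions = suggestions
        hint = f" (did you mean: {', '.join(suggestions)}?)" if suggestions else ""
        super().__init__(f"unknown target {token!r}{hint}")


class CellNotFoundError(MediSynError):
    """A (drug, target) cell is absent from the named dataset.

    Distinguishes genuinely missing data from a mistyped lookup.
    """


@dataclass(frozen=True)
class ValidationIssue:
    """One rejected input row: where it failed and why.

    ``row`` is the 1-based data-row number (the header is row 0).
    """

    row: int
    column: str
    message: str

    def as_tsv_row(self) -> str:
        return f"{self.row}\t{self.column}\t{self.message}"
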