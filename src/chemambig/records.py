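"""Core domain types: compound records, database snapshots, field maps.

A *database snapshot* is the in-memory form of one compound collection:
every retained record carries a MOL block (the structure authority) and the
non-structural identifier strings attached to it.  Records without a usable
structure are never retained — they are only counted, so the accounting
``retained + dropped_count == total read`` always balances.
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence


def normalize_identifier(raw: str, *, case_fold: bool = False) -> str:
    """Normalize a raw identifier string for exact-string comparison.

    Unicode is composed to NFC, leading/trailing whitespace is stripped and
    internal whitespace runs collapse to a single space.  Case is preserved
    unless ``case_fold`` is set: distinct research codes such as "AMP" and
    "amp" stay distinct by default.  An empty result marks a discardable
    identifier.
    """
    text = unicodedata.normalize("NFC", raw)
    text = " ".join(text.split())
    if case_fold:
        text = text.casefold()
    return text


def dedupe_identifiers(values: Sequence[str]) -> list[str]:
    """Collapse duplicates while preserving first-seen order."""
    seen: set[str] = set()
    out: list[str] = []
    for v in values:
        if v and v not in seen:
            seen.add(v)
            out.append(v)
    return out


@dataclass
class CompoundRecord:
    """One database entry: record id, MOL block, attached identifiers."""

    record_id: str
    molblock: str
    identifiers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")


@dataclass
class DatabaseSnapshot:
    """A named set of compound records plus ingest provenance.

    ``dropped_count`` counts input entries discarded for a missing or
    unparsable structure, so downstream statistics make their information
    loss visible.
    """

    name: str
    records: list[CompoundRecord] = field(default_factory=list)
    dropped_count: int = 0

    def __post_init__(self) -> None:
        if self.dropped_count < 0:
            raise ValueError("dropped_count must be >= 0")
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in snapshot {self.name!r}")
            seen.add(rec.record_id)
            if not rec.molblock.strip():
                raise ValueError(f"record {rec.record_id!r} has an empty molblock")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def identifier_multiset(self) -> Counter[str]:
        """All identifier instances across records (cross-record duplicates kept)."""
        counts: Counter[str] = Counter()
        for rec in self.records:
            counts.update(rec.identifiers)
        return counts

    def total_identifier_instances(self) -> int:
        return sum(len(rec.identifiers) for rec in self.records)


@dataclass(frozen=True)
class FieldMap:
    """Which SDF data fields hold identifiers and which field names records.

    ``identifier_fields`` may contain the wildcard ``"*"`` meaning every
    public data field; ``excluded_fields`` then subtracts tags (e.g. fields
    explicitly tagged as IUPAC names, SMILES or InChIs, which are handled by
    the systematic-name filter instead of being ingested as identifiers).
    ``id_field`` is an SDF tag, or ``"auto"`` to use the molecule title.
    """

    identifier_fields: tuple[str, ...]
    id_field: str = "auto"
    excluded_fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.identifier_fields:
            raise ValueError("identifier_fields must be non-empty")
        if self.id_field in self.identifier_fields:
            raise ValueError("id_field must not appear in identifier_fields")

    def resolve(self, available: Sequence[str]) -> list[str]:
        """Concrete identifier tags for one record's available data fields."""
        if "*" in self.identifier_fields:
            tags = [t for t in available if not t.startswith("_")]
        else:
            tags = [t for t in self.identifier_fields if t in available]
        drop = set(self.excluded_fields) | {self.id_field}
        return [t for t in tags if t not in drop]
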