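"""Filtering of systematic identifiers from extracted identifier lists.

Synonym fields in compound databases mix genuinely non-systematic names
(brand names, research codes, registry numbers) with systematic ones
(SMILES, InChI, IUPAC nomenclature) that are algorithmically derivable from
the structure.  Only non-systematic identifiers may enter the ambiguity
analysis, so every identifier is consulted against a set of
name-to-structure detectors and classified systematic as soon as *any*
detector recognizes it (union rule).  The detector set is pluggable; the
linear-notation detector is the always-available baseline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from rdkit import Chem, RDLogger

from .records import CompoundRecord, DatabaseSnapshot

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

SYSTEMATIC = "systematic"
NON_SYSTEMATIC = "non_systematic"


@dataclass(frozen=True)
class NameClassification:
    label: str
    triggered_by: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == SYSTEMATIC) != bool(self.triggered_by):
            raise ValueError("label 'systematic' iff triggered_by non-empty")


@dataclass
class FilterReport:
    """Accounting of one filtering pass, on identifier instances."""

    total_in: int
    removed_systematic: int
    retained: int
    per_detector_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.removed_systematic + self.retained != self.total_in:
            raise ValueError("removed_systematic + retained must equal total_in")

    def to_dict(self) -> dict:
        return {
            "total_in": self.total_in,
            "removed_systematic": self.removed_systematic,
            "retained": self.retained,
            "per_detector_counts": dict(self.per_detector_counts),
        }


class Detector(Protocol):
    """A name-to-structure detector: recognizes systematic identifiers."""

    name: str

    def recognizes(self, identifier: str) -> bool: ...


class LinearNotationDetector:
    """Recognize linear notations (SMILES, InChI) via the structure toolkit.

    Bare SMILES parsing of short all-letter strings can spuriously succeed
    (e.g. "CNS" would parse), so a string is only attempted as SMILES when
    it has length >= 3 and contains at least one non-alphabetic
    SMILES-syntax character; research codes such as "AMP" or "AP" are never
    flagged.  InChI strings are recognized by their prefix plus a successful
    parse.
    """

    name = "linear_notation"

    _SYNTAX_CHARS = set("0123456789[]=#()/\\@+-.%")

    def recognizes(self, identifier: str) -> bool:
        if identifier.startswith("InChI="):
            mol = Chem.MolFromInchi(identifier)
            return mol is not None and mol.GetNumAtoms() > 0
        if len(identifier) < 3 or not (set(identifier) & self._SYNTAX_CHARS):
            return False
        if " " in identifier:
            return False
        mol = Chem.MolFromSmiles(identifier)
        return mol is not None and mol.GetNumAtoms() > 0


class IupacNomenclatureDetector:
    """Lexical heuristic for parseable systematic (IUPAC-style) nomenclature.

    Not a nomenclature grammar: it looks for morphology that essentially
    never occurs in brand names or research codes — stereo-descriptor
    locant groups like "(2S,5R,6R)", von Baeyer ring descriptors like
    "azabicyclo[3.2.0]", locant-prefixed multipliers/substituents like
    "3,3-dimethyl" or "7-oxo", and indicated-hydrogen prefixes like "2H-".
    """

    name = "iupac_heuristic"

    _PATTERNS = (
        # stereo-descriptor locants: (2S,5R,6R)- or [(2R)-...]
        re.compile(r"\(\s*\d+\s*[RSEZ]\s*[,)]"),
        # von Baeyer / spiro ring descriptors: bicyclo[3.2.0], spiro[4.5]
        re.compile(r"(?:cyclo|spiro)\[\d+(?:\.\d+)*", re.IGNORECASE),
        # locant + optional multiplier + substituent/replacement morpheme
        re.compile(
            r"\d+(?:,\d+)*-(?:di|tri|tetra|penta|hexa)?"
            r"(?:methyl|ethyl|propyl|butyl|phenyl|benzyl|acetyl|hydroxy|oxo|amino|"
            r"chloro|fluoro|bromo|iodo|nitro|cyano|carboxy|thia|aza|oxa|az[ao]bicyclo)",
            re.IGNORECASE,
        ),
        # indicated hydrogen: 2H-pyran, 1H-indole
        re.compile(r"\b\d+H-"),
    )

    def recognizes(self, identifier: str) -> bool:
        return any(p.search(identifier) for p in self._PATTERNS)


class OpsinDetector:
    """Adapter to the OPSIN IUPAC name-to-structure parser, when installed."""

    name = "opsin"

    def __init__(self) -> None:
        from py2opsin import py2opsin  # noqa: F401 - availability probe

        self._convert = py2opsin

    def recognizes(self, identifier: str) -> bool:
        result = self._convert(identifier)
        return bool(result)


def default_detectors() -> list[Detector]:
    """Baseline detector set; OPSIN joins automatically when importable."""
    detectors: list[Detector] = [LinearNotationDetector(), IupacNomenclatureDetector()]
    try:
        detectors.append(OpsinDetector())
    except ImportError:
        pass
    return detectors


def classify_identifier(name: str, detectors: Sequence[Detector]) -> NameClassification:
    """Consult every detector; systematic as soon as any recognizes the name.

    Consultation is exhaustive (no short-circuit) so ``triggered_by`` is
    complete and per-detector counts are reproducible.  A detector crash is
    treated as "not recognized" for that detector and logged.
    """
    if not detectors:
        raise ValueError("at least one detector must be registered")
    triggered: list[str] = []
    for det in detectors:
        try:
            hit = det.recognizes(name)
        except Exception:  # noqa: BLE001 - detector faults must not kill the audit
            logger.warning("detector %s crashed on %r; treated as not recognized", det.name, name)
            hit = False
        if hit:
            triggered.append(det.name)
    label = SYSTEMATIC if triggered else NON_SYSTEMATIC
    return NameClassification(label=label, triggered_by=tuple(triggered))


def filter_snapshot(
    snapshot: DatabaseSnapshot,
    detectors: Sequence[Detector] | None = None,
) -> tuple[DatabaseSnapshot, FilterReport]:
    """Remove every systematic identifier from every record.

    Returns a new snapshot (records and structures untouched otherwise) and
    a balanced :class:`FilterReport`.  Classification is cached per distinct
    identifier, counts are on identifier instances.
    """
    detectors = list(detectors) if detectors is not None else default_detectors()
    cache: dict[str, NameClassification] = {}

    def classify(name: str) -> NameClassification:
        if name not in cache:
            cache[name] = classify_identifier(name, detectors)
        return cache[name]

    total_in = 0
    removed = 0
    per_detector: dict[str, int] = {d.name: 0 for d in detectors}
    new_records: list[CompoundRecord] = []
    for rec in snapshot.records:
        kept: list[str] = []
        for ident in rec.identifiers:
            total_in += 1
            cls = classify(ident)
            if cls.label == SYSTEMATIC:
                removed += 1
                for det_name in cls.triggered_by:
                    per_detector[det_name] += 1
            else:
                kept.append(ident)
        new_records.append(
            CompoundRecord(record_id=rec.record_id, molblock=rec.molblock, identifiers=kept)
        )
    filtered = DatabaseSnapshot(
        name=snapshot.name, records=new_records, dropped_count=snapshot.dropped_count
    )
    report = FilterReport(
        total_in=total_in,
        removed_systematic=removed,
        retained=total_in - removed,
        per_detector_counts=per_detector,
    )
    return filtered, report


def classify_all(names: Iterable[str], detectors: Sequence[Detector] | None = None) -> dict[str, NameClassification]:
    """Classify a collection of identifiers in one pass (cached)."""
    detectors = list(detectors) if detectors is not None else default_detectors()
    return {name: classify_identifier(name, detectors) for name in set(names)}
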