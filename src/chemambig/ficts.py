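"""FICTS structure standardization and Standard-InChI structure keys.

The FICTS convention names five standardization rules — remove small
Fragments, disregard Isotopes, disregard Charges, generate canonical
Tautomers, ignore Stereochemistry.  A five-character code selects any
combination: position *k* holds either the canonical upper-case letter of
"FICTS" (rule off, i.e. the representation stays sensitive to that
feature) or a lower-case "u" (rule applied, "un-sensitive").  "FICTS" is
the identity standardization; "uuuuu" applies all five rules.

All structure-identity comparisons in the pipeline go through one key:
the Standard InChI of the standardized molecule.  InChI generation
failures yield an explicit ``None`` marker, never an exception, so callers
can exclude those records from comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

_LETTERS = "FICTS"

#: a structure key is a Standard InChI string; ``None`` marks a failure
StructureKey = Optional[str]


@dataclass(frozen=True)
class FictsCode:
    """One of the 32 FICTS standardization settings."""

    apply_fragments: bool = False
    apply_isotopes: bool = False
    apply_charges: bool = False
    apply_tautomers: bool = False
    apply_stereo: bool = False

    @property
    def flags(self) -> tuple[bool, bool, bool, bool, bool]:
        return (
            self.apply_fragments,
            self.apply_isotopes,
            self.apply_charges,
            self.apply_tautomers,
            self.apply_stereo,
        )

    def __str__(self) -> str:
        return "".join("u" if f else letter for f, letter in zip(self.flags, _LETTERS))

    @classmethod
    def identity(cls) -> "FictsCode":
        return cls()

    @classmethod
    def all_codes(cls) -> list["FictsCode"]:
        """All 32 settings, identity first."""
        return [cls(*flags) for flags in product([False, True], repeat=5)]


IDENTITY_CODE = "FICTS"
FULL_CODE = "uuuuu"


def parse_ficts(code: str) -> FictsCode:
    """Parse a five-character FICTS code such as "uICTS" or "FICTu".

    Each position must hold either its canonical letter of "FICTS" or "u";
    anything else raises a :class:`ValueError` naming the offending
    position.
    """
    if not isinstance(code, str) or len(code) != 5:
        raise ValueError(f"FICTS code must be exactly 5 characters, got {code!r}")
    flags = []
    for pos, (char, letter) in enumerate(zip(code, _LETTERS), start=1):
        if char == "u":
            flags.append(True)
        elif char == letter:
            flags.append(False)
        else:
            raise ValueError(
                f"invalid FICTS code {code!r}: position {pos} must be "
                f"{letter!r} or 'u', got {char!r}"
            )
    return FictsCode(*flags)


# module-level standardizer instances; construction is not free
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_CANON = rdMolStandardize.TautomerEnumerator()


def _keep_largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the connected component with the most heavy atoms.

    Ties break on the lexicographically smallest canonical SMILES, so the
    choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def apply_ficts(mol: Chem.Mol, code: FictsCode) -> Optional[Chem.Mol]:
    """Apply the enabled FICTS rules in the fixed order F -> I -> C -> T -> S.

    The kept fragment must be chosen before its properties are edited, and
    stereo erasure last cannot affect the earlier rules.  The charge rule
    neutralizes protonation charges where valence allows and leaves
    non-neutralizable centers (e.g. quaternary nitrogen) untouched; the
    tautomer rule delegates to the toolkit's canonical-tautomer algorithm.
    A transform that produces an unsanitizable molecule returns ``None``
    (logged), which downstream code treats as a key failure.
    """
    try:
        m = Chem.Mol(mol)
        if code.apply_fragments:
            m = Chem.Mol(_keep_largest_fragment(m))
        if code.apply_isotopes:
            for atom in m.GetAtoms():
                atom.SetIsotope(0)
        if code.apply_charges:
            m = _UNCHARGER.uncharge(m)
        if code.apply_tautomers:
            m = _TAUTOMER_CANON.Canonicalize(m)
        if code.apply_stereo:
            Chem.RemoveStereochemistry(m)
        Chem.SanitizeMol(m)
    except Exception:  # noqa: BLE001 - standardization failures become markers
        logger.warning("standardization under %s failed for a record", code)
        return None
    return m


def structure_key(mol: Optional[Chem.Mol]) -> StructureKey:
    """Standard InChI of a (standardized) molecule, or ``None`` on failure."""
    if mol is None:
        return None
    try:
        inchi = Chem.MolToInchi(mol)
    except Exception:  # noqa: BLE001
        return None
    if inchi and inchi.startswith("InChI=1S/"):
        return inchi
    return None


def mol_from_molblock(molblock: str) -> Optional[Chem.Mol]:
    """Parse and sanitize an MDL MOL block; ``None`` if unparsable."""
    mol = Chem.MolFromMolBlock(molblock)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return mol


def molblock_key(molblock: str, code: FictsCode) -> StructureKey:
    """Convenience: parse, standardize under ``code`` and emit the key."""
    mol = mol_from_molblock(molblock)
    if mol is None:
        return None
    return structure_key(apply_ficts(mol, code))
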