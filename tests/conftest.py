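"""Shared fixtures and the independent brute-force ambiguity oracle."""

from __future__ import annotations

import pytest
from hypothesis import settings
from rdkit import Chem, RDLogger

from chemambig.ficts import molblock_key, parse_ficts
from chemambig.records import CompoundRecord, DatabaseSnapshot

RDLogger.DisableLog("rdApp.*")

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def mb(smiles: str) -> str:
    """MOL block for a SMILES (test construction helper)."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"fixture SMILES {smiles!r} must parse"
    return Chem.MolToMolBlock(mol)


def snapshot_of(name: str, *records: tuple[str, str, list[str]]) -> DatabaseSnapshot:
    """Snapshot from (record_id, smiles, identifiers) triples."""
    return DatabaseSnapshot(
        name=name,
        records=[CompoundRecord(rid, mb(smi), list(idents)) for rid, smi, idents in records],
    )


# ---------------------------------------------------------------------------
# brute-force oracle: naive all-pairs recomputation, no IdentifierIndex
# ---------------------------------------------------------------------------


def brute_within_ambiguous(snapshot: DatabaseSnapshot, code: str) -> set[str]:
    """Identifiers with >= 2 distinct keys, by scanning every record per name."""
    ficts = parse_ficts(code)
    idents = sorted({i for rec in snapshot.records for i in rec.identifiers})
    ambiguous: set[str] = set()
    for ident in idents:
        keys: set[str] = set()
        for rec in snapshot.records:
            if ident in rec.identifiers:
                key = molblock_key(rec.molblock, ficts)
                if key is not None:
                    keys.add(key)
        if len(keys) >= 2:
            ambiguous.add(ident)
    return ambiguous


def brute_between_ambiguous(
    snap_a: DatabaseSnapshot, snap_b: DatabaseSnapshot, code: str
) -> tuple[set[str], set[str]]:
    """(shared identifiers, cross-ambiguous identifiers) by direct recomputation."""
    ficts = parse_ficts(code)

    def keys_for(snapshot: DatabaseSnapshot, ident: str) -> set[str]:
        out: set[str] = set()
        for rec in snapshot.records:
            if ident in rec.identifiers:
                key = molblock_key(rec.molblock, ficts)
                if key is not None:
                    out.add(key)
        return out

    idents_a = {i for rec in snap_a.records for i in rec.identifiers}
    idents_b = {i for rec in snap_b.records for i in rec.identifiers}
    shared = {
        i
        for i in idents_a & idents_b
        if keys_for(snap_a, i) and keys_for(snap_b, i)
    }
    ambiguous = set()
    for ident in shared:
        ka, kb = keys_for(snap_a, ident), keys_for(snap_b, ident)
        if len(ka) >= 2 or len(kb) >= 2 or ka != kb:
            ambiguous.add(ident)
    return shared, ambiguous


@pytest.fixture(scope="session")
def detectors():
    from chemambig.namefilter import default_detectors

    return default_detectors()
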