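"""Reading and writing compound collections (SDF, tabular, snapshot tables).

The readers share one contract: every retained record has a parsable MOL
block; entries without a structure are counted in ``dropped_count`` and
logged, never silently lost.  Identifiers are collected from the configured
fields, split on newlines within multi-line field values, normalized and
deduplicated per record (cross-record duplicates are the signal and are
kept).
"""

from __future__ import annotations

import io
import json
import logging
import os
from pathlib import Path
from typing import IO, Union

import pandas as pd
from rdkit import Chem, RDLogger

from .records import (
    CompoundRecord,
    DatabaseSnapshot,
    FieldMap,
    dedupe_identifiers,
    normalize_identifier,
)

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

Source = Union[str, os.PathLike, IO[bytes], IO[str]]

#: separator for multi-valued identifier cells in tabular input
TABULAR_VALUE_SEP = "|"


def _as_bytes(source: Source) -> bytes:
    """Accept a path, a file-like object, or raw text containing newlines."""
    if hasattr(source, "read"):
        data = source.read()  # type: ignore[union-attr]
        return data.encode() if isinstance(data, str) else data
    if isinstance(source, os.PathLike):
        return Path(source).read_bytes()
    if isinstance(source, str):
        if "\n" in source:  # literal SDF/CSV text
            return source.encode()
        return Path(source).read_bytes()
    raise TypeError(f"unreadable source {type(source)!r}")


def _record_identifiers(mol: Chem.Mol, field_map: FieldMap, case_fold: bool) -> list[str]:
    tags = field_map.resolve(list(mol.GetPropNames()))
    values: list[str] = []
    for tag in tags:
        for line in mol.GetProp(tag).splitlines():
            values.append(normalize_identifier(line, case_fold=case_fold))
    return dedupe_identifiers(values)


def _record_id(mol: Chem.Mol, field_map: FieldMap, name: str, index: int) -> str:
    if field_map.id_field == "auto":
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rid = title.strip()
    else:
        rid = mol.GetProp(field_map.id_field).strip() if mol.HasProp(field_map.id_field) else ""
    return rid or f"{name}-{index + 1:06d}"


def read_sdf(
    source: Source,
    field_map: FieldMap,
    *,
    name: str = "snapshot",
    case_fold: bool = False,
) -> DatabaseSnapshot:
    """Read an SDF (V2000 MOL blocks + data fields) into a snapshot.

    Malformed entries and entries whose connection table has no atoms are
    skipped and counted in ``dropped_count``.  An unreadable source raises.
    """
    data = _as_bytes(source)
    supplier = Chem.ForwardSDMolSupplier(io.BytesIO(data), sanitize=True, removeHs=False)
    records: list[CompoundRecord] = []
    dropped = 0
    for i, mol in enumerate(supplier):
        if mol is None or mol.GetNumAtoms() == 0:
            dropped += 1
            logger.warning("%s: SDF entry %d has no usable structure; dropped", name, i)
            continue
        records.append(
            CompoundRecord(
                record_id=_record_id(mol, field_map, name, i),
                molblock=Chem.MolToMolBlock(mol),
                identifiers=_record_identifiers(mol, field_map, case_fold),
            )
        )
    return DatabaseSnapshot(name=name, records=records, dropped_count=dropped)


def read_tabular(
    source: Source,
    *,
    id_col: str,
    structure_col: str,
    identifier_cols: list[str],
    name: str = "snapshot",
    sep: str = ",",
    case_fold: bool = False,
) -> DatabaseSnapshot:
    """Read a delimited table (one row per compound) into a snapshot.

    The structure column holds SMILES, or a full MOL block (recognized by an
    embedded newline).  Identifier cells may hold several values separated
    by ``|``.  A missing schema column is fatal; a row whose structure does
    not parse is dropped and logged.
    """
    frame = pd.read_csv(io.BytesIO(_as_bytes(source)), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in [id_col, structure_col, *identifier_cols] if c not in frame.columns]
    if missing:
        raise ValueError(f"missing schema column(s): {', '.join(missing)}")

    records: list[CompoundRecord] = []
    dropped = 0
    for i, row in frame.iterrows():
        structure = row[structure_col]
        mol = (
            Chem.MolFromMolBlock(structure)
            if "\n" in structure
            else Chem.MolFromSmiles(structure)
        )
        if mol is None or mol.GetNumAtoms() == 0:
            dropped += 1
            logger.warning("%s: row %s structure unparsable; dropped", name, i)
            continue
        values: list[str] = []
        for col in identifier_cols:
            for part in row[col].split(TABULAR_VALUE_SEP):
                values.append(normalize_identifier(part, case_fold=case_fold))
        rid = row[id_col].strip() or f"{name}-{int(i) + 1:06d}"
        records.append(
            CompoundRecord(
                record_id=rid,
                molblock=Chem.MolToMolBlock(mol),
                identifiers=dedupe_identifiers(values),
            )
        )
    return DatabaseSnapshot(name=name, records=records, dropped_count=dropped)


# ---------------------------------------------------------------------------
# snapshot serialization: one long identifiers table + one structures table
# ---------------------------------------------------------------------------


def write_snapshot(snapshot: DatabaseSnapshot, directory: Union[str, os.PathLike]) -> None:
    """Serialize a snapshot as documented tabular files for reproducible re-runs.

    Writes ``<name>.identifiers.csv`` (record_id, identifier — one row per
    record-identifier pair), ``<name>.structures.csv`` (record_id, molblock)
    and ``<name>.meta.json`` (name, dropped_count).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ident_rows = [
        {"record_id": rec.record_id, "identifier": ident}
        for rec in snapshot.records
        for ident in rec.identifiers
    ]
    pd.DataFrame(ident_rows, columns=["record_id", "identifier"]).to_csv(
        directory / f"{snapshot.name}.identifiers.csv", index=False
    )
    struct_rows = [{"record_id": rec.record_id, "molblock": rec.molblock} for rec in snapshot.records]
    pd.DataFrame(struct_rows, columns=["record_id", "molblock"]).to_csv(
        directory / f"{snapshot.name}.structures.csv", index=False
    )
    meta = {"name": snapshot.name, "dropped_count": snapshot.dropped_count}
    (directory / f"{snapshot.name}.meta.json").write_text(json.dumps(meta, indent=2))


def read_snapshot(directory: Union[str, os.PathLike], name: str) -> DatabaseSnapshot:
    """Load a snapshot previously written by :func:`write_snapshot`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.meta.json").read_text())
    structures = pd.read_csv(directory / f"{name}.structures.csv", dtype=str, keep_default_na=False)
    identifiers = pd.read_csv(directory / f"{name}.identifiers.csv", dtype=str, keep_default_na=False)
    by_record: dict[str, list[str]] = {}
    for _, row in identifiers.iterrows():
        by_record.setdefault(row["record_id"], []).append(row["identifier"])
    records = [
        CompoundRecord(
            record_id=row["record_id"],
            molblock=row["molblock"],
            identifiers=by_record.get(row["record_id"], []),
        )
        for _, row in structures.iterrows()
    ]
    return DatabaseSnapshot(name=meta["name"], records=records, dropped_count=meta["dropped_count"])


def list_snapshots(directory: Union[str, os.PathLike]) -> list[str]:
    """Names of all serialized snapshots in a directory."""
    return sorted(p.name[: -len(".meta.json")] for p in Path(directory).glob("*.meta.json"))


def write_sdf(
    snapshot: DatabaseSnapshot,
    path: Union[str, os.PathLike],
    *,
    synonyms_tag: str = "SYNONYMS",
) -> None:
    """Write a snapshot as a standard SDF, identifiers newline-joined in one tag."""
    with open(path, "w") as handle:
        writer = Chem.SDWriter(handle)
        try:
            for rec in snapshot.records:
                mol = Chem.MolFromMolBlock(rec.molblock)
                if mol is None:  # pragma: no cover - retained records are parsable
                    continue
                mol.SetProp("_Name", rec.record_id)
                if rec.identifiers:
                    mol.SetProp(synonyms_tag, "\n".join(rec.identifiers))
                writer.write(mol)
        finally:
            writer.close()
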