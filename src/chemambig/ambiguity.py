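"""Ambiguity statistics for non-systematic identifiers.

An identifier is *ambiguous within* a database when it is associated with
more than one distinct structure, i.e. its set of structure keys under the
active standardization has size >= 2 (two records carrying identical keys
are one structure, not an ambiguity).  An identifier shared by two
databases is *ambiguous across* them when it is ambiguous within either
one, or when its single structure in each database differs between the
two.  All percentages are on the unique-identifier (respectively unique
shared identifier) denominator; identifiers whose every record failed
InChI generation vanish from all denominators, with the excluded-record
count reported so the loss is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean, median
from typing import Optional, Sequence

import pandas as pd

from .ficts import FictsCode, apply_ficts, mol_from_molblock, structure_key
from .records import DatabaseSnapshot


@dataclass
class IdentifierIndex:
    """Map from identifier to the (key, record_id) pairs it occurs with."""

    db_name: str
    ficts: FictsCode
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    excluded_records: int = 0

    def distinct_keys(self, identifier: str) -> set[str]:
        return {key for key, _rid in self.entries[identifier]}

    def identifiers(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class WithinReport:
    """Within-database ambiguity of non-systematic identifiers."""

    db_name: str
    ficts: str
    unique_identifiers: int
    ambiguous_identifiers: int
    ambiguity_pct: float
    #: mean distinct structures per ambiguous identifier; None when none are
    mean_structures_per_ambiguous: Optional[float]
    max_structures_single_identifier: int
    n_identifiers_over_100_structures: int
    excluded_records: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PairReport:
    """Cross-database ambiguity of the identifiers two databases share.

    ``within_attributable_pct`` is the share of shared identifiers that are
    already ambiguous inside at least one of the two databases (and hence
    ambiguous across by definition); ``cross_only_pct`` is the remainder.
    Percentages are ``None`` when the databases share no identifiers.
    """

    db_a: str
    db_b: str
    ficts: str
    shared_unique: int
    ambiguous_pct: Optional[float]
    within_attributable_pct: Optional[float]
    cross_only_pct: Optional[float]
    ambiguous: frozenset[str] = frozenset()
    within_attributable: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ambiguous"] = sorted(self.ambiguous)
        d["within_attributable"] = sorted(self.within_attributable)
        return d


@dataclass
class EffectTable:
    """Ambiguity per FICTS code and scope, with deltas vs the identity code."""

    rows: pd.DataFrame  # columns: scope, kind, ficts, ambiguity_pct, delta_pp
    summary: pd.DataFrame  # per code: median_ambiguity_pct, median_reduction_pp


def build_index(snapshot: DatabaseSnapshot, code: FictsCode) -> IdentifierIndex:
    """Standardize every record under ``code`` and index identifier -> keys.

    Records whose standardization or InChI generation fails are counted in
    ``excluded_records`` and contribute nothing — no comparison is made for
    a structure without a key.
    """
    index = IdentifierIndex(db_name=snapshot.name, ficts=code)
    for rec in snapshot.records:
        mol = mol_from_molblock(rec.molblock)
        key = structure_key(apply_ficts(mol, code)) if mol is not None else None
        if key is None:
            index.excluded_records += 1
            continue
        for ident in rec.identifiers:
            index.entries.setdefault(ident, set()).add((key, rec.record_id))
    return index


def ambiguous_identifiers(index: IdentifierIndex) -> set[str]:
    """Identifiers associated with >= 2 distinct structure keys."""
    return {ident for ident in index.entries if len(index.distinct_keys(ident)) >= 2}


def within_ambiguity(index: IdentifierIndex) -> WithinReport:
    """Within-database ambiguity report (unique-identifier denominator)."""
    if not index.entries:
        raise ValueError(f"index for {index.db_name!r} is empty")
    sizes = {ident: len(index.distinct_keys(ident)) for ident in index.entries}
    ambiguous = [ident for ident, n in sizes.items() if n >= 2]
    unique = len(sizes)
    return WithinReport(
        db_name=index.db_name,
        ficts=str(index.ficts),
        unique_identifiers=unique,
        ambiguous_identifiers=len(ambiguous),
        ambiguity_pct=100.0 * len(ambiguous) / unique,
        mean_structures_per_ambiguous=(
            mean(sizes[i] for i in ambiguous) if ambiguous else None
        ),
        max_structures_single_identifier=max(sizes.values()),
        n_identifiers_over_100_structures=sum(1 for n in sizes.values() if n > 100),
        excluded_records=index.excluded_records,
    )


def between_ambiguity(index_a: IdentifierIndex, index_b: IdentifierIndex) -> PairReport:
    """Cross-database ambiguity of the shared identifiers of two indices.

    Both indices must be built under the same FICTS code.  A shared
    identifier is ambiguous across when it is ambiguous within either
    database, or when both sides are singletons whose keys differ.
    """
    if str(index_a.ficts) != str(index_b.ficts):
        raise ValueError("indices must be built under the same FICTS code")
    if index_a.db_name == index_b.db_name:
        warnings.warn(
            f"comparing two indices both named {index_a.db_name!r}", stacklevel=2
        )
    shared = index_a.identifiers() & index_b.identifiers()
    ambiguous: set[str] = set()
    attributable: set[str] = set()
    for ident in shared:
        keys_a = index_a.distinct_keys(ident)
        keys_b = index_b.distinct_keys(ident)
        if len(keys_a) >= 2 or len(keys_b) >= 2:
            ambiguous.add(ident)
            attributable.add(ident)
        elif keys_a != keys_b:
            ambiguous.add(ident)
    n = len(shared)
    if n == 0:
        amb_pct = attr_pct = cross_pct = None
    else:
        amb_pct = 100.0 * len(ambiguous) / n
        attr_pct = 100.0 * len(attributable) / n
        cross_pct = amb_pct - attr_pct
    return PairReport(
        db_a=index_a.db_name,
        db_b=index_b.db_name,
        ficts=str(index_a.ficts),
        shared_unique=n,
        ambiguous_pct=amb_pct,
        within_attributable_pct=attr_pct,
        cross_only_pct=cross_pct,
        ambiguous=frozenset(ambiguous),
        within_attributable=frozenset(attributable),
    )


def identifiers_per_compound(snapshot: DatabaseSnapshot) -> float:
    """Total retained identifier instances per compound with >= 1 identifier."""
    with_ids = [rec for rec in snapshot.records if rec.identifiers]
    if not with_ids:
        raise ValueError(f"snapshot {snapshot.name!r} has no records with identifiers")
    return sum(len(rec.identifiers) for rec in with_ids) / len(with_ids)


def standardization_effect(
    snapshots: Sequence[DatabaseSnapshot],
    pairs: Sequence[tuple[str, str]],
    codes: Sequence[FictsCode],
) -> EffectTable:
    """Re-index under every code and tabulate the ambiguity per scope.

    ``codes`` must include the identity "FICTS" (the baseline against which
    the per-code deltas and median percentage-point reductions are
    computed).  ``pairs`` names snapshot pairs for the cross-database
    scopes.
    """
    code_strs = [str(c) for c in codes]
    if "FICTS" not in code_strs:
        raise ValueError('codes must include the identity code "FICTS"')
    by_name = {s.name: s for s in snapshots}
    for a, b in pairs:
        if a not in by_name or b not in by_name:
            raise ValueError(f"pair ({a!r}, {b!r}) names an unknown snapshot")

    rows: list[dict] = []
    baseline: dict[str, float] = {}
    for code in codes:
        indices = {s.name: build_index(s, code) for s in snapshots}
        scoped: list[tuple[str, str, Optional[float]]] = []
        for s in snapshots:
            rep = within_ambiguity(indices[s.name])
            scoped.append((f"within:{s.name}", "within", rep.ambiguity_pct))
        for a, b in pairs:
            rep = between_ambiguity(indices[a], indices[b])
            scoped.append((f"between:{a}|{b}", "between", rep.ambiguous_pct))
        for scope, kind, pct in scoped:
            if str(code) == "FICTS" and pct is not None:
                baseline[scope] = pct
            rows.append(
                {"scope": scope, "kind": kind, "ficts": str(code), "ambiguity_pct": pct}
            )
    frame = pd.DataFrame(rows, columns=["scope", "kind", "ficts", "ambiguity_pct"])
    frame["delta_pp"] = frame.apply(
        lambda r: (
            None
            if r["ambiguity_pct"] is None or r["scope"] not in baseline
            else r["ambiguity_pct"] - baseline[r["scope"]]
        ),
        axis=1,
    )
    summary_rows = []
    for code in code_strs:
        sub = frame[(frame["ficts"] == code) & frame["ambiguity_pct"].notna()]
        deltas = sub["delta_pp"].dropna()
        summary_rows.append(
            {
                "ficts": code,
                "median_ambiguity_pct": median(sub["ambiguity_pct"]) if len(sub) else None,
                "median_reduction_pp": -median(deltas) if len(deltas) else None,
            }
        )
    summary = pd.DataFrame(
        summary_rows, columns=["ficts", "median_ambiguity_pct", "median_reduction_pp"]
    )
    return EffectTable(rows=frame, summary=summary)
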