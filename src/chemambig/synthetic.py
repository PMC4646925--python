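"""Synthetic paired compound databases with class-labelled identifier collisions.

Real compound collections cannot be redistributed, so the generator emulates
their statistical structure instead: two databases of records that each
carry a configurable number of research-code-like identifiers, a
controllable fraction of identifiers shared between the databases, and
injected *collisions* — identifiers deliberately attached to two structures
that differ only in one feature class:

``true_structural``   genuinely different scaffolds (never resolvable)
``fragment``          parent vs parent + salt partner        (resolved by uICTS)
``isotope``           unlabelled vs isotope-labelled         (resolved by FuCTS)
``charge``            neutral acid vs deprotonated anion     (resolved by FIuTS)
``tautomer``          keto vs enol form                      (resolved by FICuS)
``stereo``            enantiomer pair                        (resolved by FICTu)

Every injected pair is validated at generation time by
:func:`verify_resolvable`: its keys must differ at baseline, merge under
exactly its own single-u code (and under "uuuuu" unless true-structural),
and stay distinct under every other single-u code.  Recovery of the
manifest by the audit pipeline is therefore exact, not statistical.

Tautomer pairs are keto/enol motifs rather than the textbook mobile-H pairs
(2-pyridone/2-hydroxypyridine, amide/imidic acid): Standard InChI already
normalizes mobile hydrogens, so those textbook pairs share a single InChI
at baseline and cannot act as collisions under an InChI structure key.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Iterator, Mapping, Optional, Union

import numpy as np
from rdkit import Chem

from .ficts import FULL_CODE, FictsCode, apply_ficts, parse_ficts, structure_key
from .records import CompoundRecord, DatabaseSnapshot

COLLISION_CLASSES = (
    "true_structural",
    "fragment",
    "isotope",
    "charge",
    "tautomer",
    "stereo",
)

#: the single-u code that resolves each resolvable collision class
RESOLVING_CODE = {
    "fragment": "uICTS",
    "isotope": "FuCTS",
    "charge": "FIuTS",
    "tautomer": "FICuS",
    "stereo": "FICTu",
}


def rule_applies(code: FictsCode, collision_class: str) -> bool:
    """Whether ``code`` applies the rule that resolves ``collision_class``."""
    return {
        "fragment": code.apply_fragments,
        "isotope": code.apply_isotopes,
        "charge": code.apply_charges,
        "tautomer": code.apply_tautomers,
        "stereo": code.apply_stereo,
    }.get(collision_class, False)


@dataclass
class SyntheticSpec:
    """Study conditions for one generated database pair.

    Defaults emulate a mid-sized public registry: a few hundred compounds
    per database, a skewed synonym count with mean 3.6 identifiers per
    compound, about 2 % within-database ambiguity spread over the six
    collision classes, a fifth of plain identifiers shared between the
    databases, and cross-database collisions dominated by stereochemistry
    (cross ambiguity around 45 % of shared identifiers).
    """

    n_compounds: int = 400
    #: (mean, dispersion) of identifiers per compound; dispersion 0 is a
    #: deterministic allocation, > 0 a gamma-Poisson (negative binomial)
    #: mixture with that excess-variance coefficient
    identifiers_per_compound: tuple[float, float] = (3.6, 0.3)
    shared_identifier_rate: float = 0.20
    collision_plan: Mapping[str, int] = field(
        default_factory=lambda: {
            "true_structural": 10,
            "fragment": 5,
            "isotope": 2,
            "charge": 5,
            "tautomer": 4,
            "stereo": 10,
        }
    )
    cross_collision_plan: Mapping[str, int] = field(
        default_factory=lambda: {
            "true_structural": 10,
            "fragment": 6,
            "isotope": 1,
            "charge": 3,
            "tautomer": 3,
            "stereo": 15,
        }
    )
    #: how many within-database collision identifiers are also copied into
    #: the partner database (the within-attributable share of cross ambiguity)
    shared_within_ambiguous: int = 6
    contamination_rate: float = 0.01
    #: identifiers attached to > 100 distinct structures (heavy-tail option)
    heavy_tail_identifiers: int = 0
    seed: int = 0
    db_names: tuple[str, str] = ("synthA", "synthB")

    def validate(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        mean, dispersion = self.identifiers_per_compound
        if mean < 1 or dispersion < 0:
            raise ValueError("identifiers_per_compound mean must be >= 1, dispersion >= 0")
        if not 0 <= self.shared_identifier_rate <= 1:
            raise ValueError("shared_identifier_rate must be in [0, 1]")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be in [0, 1]")
        for plan in (self.collision_plan, self.cross_collision_plan):
            for cls, count in plan.items():
                if cls not in COLLISION_CLASSES:
                    raise ValueError(f"unknown collision class {cls!r}")
                if count < 0:
                    raise ValueError("collision counts must be >= 0")
        if self.shared_within_ambiguous > sum(self.collision_plan.values()):
            raise ValueError("shared_within_ambiguous exceeds the within-collision plan")
        if self.heavy_tail_identifiers < 0:
            raise ValueError("heavy_tail_identifiers must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticSpec":
        kwargs = dict(data)
        if "identifiers_per_compound" in kwargs:
            kwargs["identifiers_per_compound"] = tuple(kwargs["identifiers_per_compound"])
        if "db_names" in kwargs:
            kwargs["db_names"] = tuple(kwargs["db_names"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Manifest of everything injected: the oracle for recovery tests."""

    db_names: tuple[str, str]
    seed: int
    #: distinct non-contaminant identifiers per database
    n_unique: dict[str, int]
    #: db -> class -> [(identifier, record_id_1, record_id_2), ...]
    within_collisions: dict[str, dict[str, list[tuple[str, str, str]]]]
    #: db -> heavy-tail identifiers (each attached to > 100 structures)
    heavy_tail: dict[str, list[str]]
    #: identifiers shared between the databases with identical structures
    shared_plain: list[str]
    #: class -> [(identifier, record_id_in_a, record_id_in_b), ...]
    cross_collisions: dict[str, list[tuple[str, str, str]]]
    #: class -> within-collision identifiers also present in the partner db
    shared_within: dict[str, list[str]]
    #: db -> injected systematic-style identifier strings
    contaminants: dict[str, list[str]]

    # -- expectations ------------------------------------------------------

    def _code(self, code: Union[str, FictsCode]) -> FictsCode:
        return parse_ficts(code) if isinstance(code, str) else code

    def expected_within_ambiguous(self, db: str, code: Union[str, FictsCode]) -> int:
        c = self._code(code)
        pairs = sum(
            len(entries)
            for cls, entries in self.within_collisions[db].items()
            if not rule_applies(c, cls)
        )
        return pairs + len(self.heavy_tail[db])

    def expected_within_pct(self, db: str, code: Union[str, FictsCode]) -> float:
        return 100.0 * self.expected_within_ambiguous(db, code) / self.n_unique[db]

    @property
    def n_shared(self) -> int:
        return (
            len(self.shared_plain)
            + sum(len(v) for v in self.cross_collisions.values())
            + sum(len(v) for v in self.shared_within.values())
        )

    def expected_cross(self, code: Union[str, FictsCode]) -> Optional[tuple[float, float]]:
        """(ambiguous_pct, within_attributable_pct) on the shared denominator."""
        if self.n_shared == 0:
            return None
        c = self._code(code)
        cross = sum(
            len(entries)
            for cls, entries in self.cross_collisions.items()
            if not rule_applies(c, cls)
        )
        attr = sum(
            len(idents)
            for cls, idents in self.shared_within.items()
            if not rule_applies(c, cls)
        )
        return (100.0 * (cross + attr) / self.n_shared, 100.0 * attr / self.n_shared)

    # -- (de)serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        data["db_names"] = tuple(data["db_names"])
        data["within_collisions"] = {
            db: {c: [tuple(e) for e in lst] for c, lst in per.items()}
            for db, per in data["within_collisions"].items()
        }
        data["cross_collisions"] = {
            c: [tuple(e) for e in lst] for c, lst in data["cross_collisions"].items()
        }
        return cls(**data)


# ---------------------------------------------------------------------------
# structure factories
# ---------------------------------------------------------------------------

# achiral, neutral, unlabelled, single-fragment, tautomer-inert scaffolds
_POOL_HEADS = ("OC", "NC", "FC", "ClC", "BrC", "SC", "COC", "CNC", "CSC", "OCC", "NCC", "C(C)(C)C")
_POOL_TAILS = ("", "O", "N", "F", "Cl", "Br", "S", "CO", "CN", "CS", "C(C)C", "CC(C)C", "CCO", "CCN")


def _plain_smiles() -> Iterator[str]:
    for k in itertools.count():
        if k > 400:  # pragma: no cover - ~75k distinct structures available
            raise RuntimeError("structure pool exhausted")
        chain = "C" * k
        for head in _POOL_HEADS:
            for tail in _POOL_TAILS:
                yield head + chain + tail


class _PoolAllocator:
    """Hands out distinct plain structures as MOL blocks, deterministically."""

    def __init__(self) -> None:
        self._iter = _plain_smiles()
        self._seen: set[str] = set()

    def next_molblock(self) -> str:
        for smi in self._iter:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:  # pragma: no cover - pool grammar is valid
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in self._seen:
                continue
            self._seen.add(canonical)
            return Chem.MolToMolBlock(mol)
        raise RuntimeError("structure pool exhausted")  # pragma: no cover


def _pair_smiles(collision_class: str, variant: int) -> tuple[str, str]:
    """Candidate structure pair for one collision class, diversified by index."""
    c = "C" * (variant % 24)
    if collision_class == "true_structural":
        return f"OC{c}CO", f"NC{c}CN"
    if collision_class == "fragment":
        base = f"OC{c}CC"
        return base, base + ".Cl"
    if collision_class == "isotope":
        return f"C{c}CO", f"[13CH3]{c}CO"
    if collision_class == "charge":
        return f"C{c}CC(=O)O", f"C{c}CC(=O)[O-]"
    if collision_class == "tautomer":
        return f"C{c}CC(C)=O", f"C{c}CC(=C)O"
    if collision_class == "stereo":
        return f"C[C@H](F)CC{c}", f"C[C@@H](F)CC{c}"
    raise ValueError(f"unknown collision class {collision_class!r}")


def _key(mol: Chem.Mol, code: FictsCode) -> Optional[str]:
    return structure_key(apply_ficts(mol, code))


def verify_resolvable(
    struct_a: Union[Chem.Mol, str],
    struct_b: Union[Chem.Mol, str],
    collision_class: str,
) -> bool:
    """Check that a proposed pair realizes exactly its collision class.

    True iff the two keys differ at baseline ("FICTS"), merge under the
    class's own single-u code and under "uuuuu" (for ``true_structural``:
    stay distinct everywhere), and stay distinct under every *other*
    single-u code — i.e. the pair contributes a diagonal entry of the
    per-rule confusion matrix.  Pairs failing any leg are discarded and
    regenerated by the caller.
    """
    if collision_class not in COLLISION_CLASSES:
        raise ValueError(f"unknown collision class {collision_class!r}")
    mol_a = Chem.MolFromMolBlock(struct_a) if isinstance(struct_a, str) else struct_a
    mol_b = Chem.MolFromMolBlock(struct_b) if isinstance(struct_b, str) else struct_b
    if mol_a is None or mol_b is None:
        return False
    if _key(mol_a, FictsCode.identity()) is None:
        return False
    base_a, base_b = _key(mol_a, FictsCode.identity()), _key(mol_b, FictsCode.identity())
    if base_a is None or base_b is None or base_a == base_b:
        return False
    for cls, code_str in RESOLVING_CODE.items():
        code = parse_ficts(code_str)
        ka, kb = _key(mol_a, code), _key(mol_b, code)
        if ka is None or kb is None:
            return False
        if (ka == kb) != (cls == collision_class):
            return False
    full = parse_ficts(FULL_CODE)
    ka, kb = _key(mol_a, full), _key(mol_b, full)
    if ka is None or kb is None:
        return False
    return (ka == kb) == (collision_class != "true_structural")


def _make_verified_pair(collision_class: str, variant: int) -> tuple[str, str]:
    """Molblock pair passing :func:`verify_resolvable`, regenerating on failure."""
    for attempt in range(variant, variant + 50):
        smi_a, smi_b = _pair_smiles(collision_class, attempt)
        mol_a, mol_b = Chem.MolFromSmiles(smi_a), Chem.MolFromSmiles(smi_b)
        if mol_a is None or mol_b is None:
            continue
        if verify_resolvable(mol_a, mol_b, collision_class):
            return Chem.MolToMolBlock(mol_a), Chem.MolToMolBlock(mol_b)
    raise RuntimeError(  # pragma: no cover - factories are pre-validated
        f"could not realize a {collision_class} pair after 50 attempts"
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

# letters that cannot start a SMILES atom token: tokens built from them are
# unparsable as SMILES by construction
_TOKEN_ALPHABET = tuple("ADEGHJLMQRTUVWXYZ")


class _TokenFactory:
    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._counter = 0

    def __call__(self) -> str:
        self._counter += 1
        a, b = self._rng.choice(len(_TOKEN_ALPHABET), size=2)
        return f"{_TOKEN_ALPHABET[a]}{_TOKEN_ALPHABET[b]}-{self._counter:05d}"


def _sample_counts(
    n: int, mean: float, dispersion: float, rng: np.random.Generator
) -> list[int]:
    """Per-record identifier counts (>= 1 each) with the requested mean."""
    if dispersion == 0:
        base = int(mean)
        extra = round((mean - base) * n)
        return [base + 1 if i < extra else base for i in range(n)]
    mu = mean - 1
    if mu == 0:
        return [1] * n
    r = 1.0 / dispersion
    draws = rng.negative_binomial(r, r / (r + mu), size=n)
    return [1 + int(d) for d in draws]


def _allocate_pairs(plan: dict[str, int], budget_records: int) -> dict[str, int]:
    """Distinct structure pairs per class, shrinking fairly when records are
    scarce (several collision identifiers then share one structure pair)."""
    total = sum(plan.values())
    if total == 0:
        return {}
    if 2 * total <= budget_records:
        return dict(plan)
    pairs = {c: max(1, (k * budget_records) // (2 * total)) for c, k in plan.items()}
    while 2 * sum(pairs.values()) > budget_records:
        widest = max(sorted(pairs), key=lambda c: pairs[c])
        if pairs[widest] <= 1:
            raise ValueError(
                f"collision plan infeasible: {total} collisions need more than "
                f"{budget_records} records"
            )
        pairs[widest] -= 1
    return pairs


def _contaminant_strings(n: int, offset: int) -> list[str]:
    """Distinct valid SMILES / InChI strings, all recognizable as systematic."""
    out: list[str] = []
    for i in range(offset, offset + n):
        smi = f"CC({'C' * (1 + i)})CCO"
        if i % 2 == 0:
            out.append(smi)
        else:
            out.append(Chem.MolToInchi(Chem.MolFromSmiles(smi)))
    return out


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[DatabaseSnapshot, DatabaseSnapshot, GroundTruth]:
    """Generate two databases plus the manifest of everything injected.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    snapshots and ground truth.  Raises before generating anything when the
    plan cannot fit into ``n_compounds`` records per database.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tokens = _TokenFactory(rng)
    pool = _PoolAllocator()
    name_a, name_b = spec.db_names
    n = spec.n_compounds
    mean, dispersion = spec.identifiers_per_compound

    k_plan = {c: int(v) for c, v in sorted(spec.collision_plan.items()) if v}
    q_plan = {c: int(v) for c, v in sorted(spec.cross_collision_plan.items()) if v}
    n_cross = sum(q_plan.values())
    if n_cross > n:
        raise ValueError("cross-collision plan exceeds n_compounds")
    pairs_a = _allocate_pairs(k_plan, n - n_cross)

    counts_a = _sample_counts(n, mean, dispersion, rng)
    counts_b = _sample_counts(n, mean, dispersion, rng)

    pair_variant = itertools.count()

    def build_within(
        db_name: str, pairs_alloc: dict[str, int]
    ) -> tuple[list[CompoundRecord], dict[str, list[tuple[str, str]]]]:
        records: list[CompoundRecord] = []
        pair_rids: dict[str, list[tuple[str, str]]] = {}
        for cls in sorted(pairs_alloc):
            pair_rids[cls] = []
            for _ in range(pairs_alloc[cls]):
                mb_1, mb_2 = _make_verified_pair(cls, next(pair_variant))
                rid_1 = f"{db_name}-{len(records) + 1:05d}"
                records.append(CompoundRecord(rid_1, mb_1, []))
                rid_2 = f"{db_name}-{len(records) + 1:05d}"
                records.append(CompoundRecord(rid_2, mb_2, []))
                pair_rids[cls].append((rid_1, rid_2))
        return records, pair_rids

    # ---- database A ------------------------------------------------------
    recs_a, pair_rids_a = build_within(name_a, pairs_a)
    # cross-collision hosts in A, partner structures stashed for B
    cross_stash: list[tuple[str, str, str, str]] = []  # (cls, token, rid_a, molblock_b)
    for cls in sorted(q_plan):
        for _ in range(q_plan[cls]):
            mb_1, mb_2 = _make_verified_pair(cls, next(pair_variant))
            rid = f"{name_a}-{len(recs_a) + 1:05d}"
            recs_a.append(CompoundRecord(rid, mb_1, []))
            cross_stash.append((cls, tokens(), rid, mb_2))
    plain_a_start = len(recs_a)
    if plain_a_start > n:
        raise ValueError("within + cross plans exceed n_compounds for database A")
    while len(recs_a) < n:
        recs_a.append(CompoundRecord(f"{name_a}-{len(recs_a) + 1:05d}", pool.next_molblock(), []))

    for rec, count in zip(recs_a, counts_a):
        rec.identifiers.extend(tokens() for _ in range(count))

    within_a: dict[str, list[tuple[str, str, str]]] = {}
    by_rid_a = {rec.record_id: rec for rec in recs_a}
    for cls in sorted(k_plan):
        within_a[cls] = []
        hosts = pair_rids_a[cls]
        for t in range(k_plan[cls]):
            rid_1, rid_2 = hosts[t % len(hosts)]
            token = tokens()
            by_rid_a[rid_1].identifiers.append(token)
            by_rid_a[rid_2].identifiers.append(token)
            within_a[cls].append((token, rid_1, rid_2))
    for cls, token, rid, _mb in cross_stash:
        by_rid_a[rid].identifiers.append(token)

    heavy_a = _attach_heavy_tail(recs_a[plain_a_start:], spec.heavy_tail_identifiers, tokens)

    # ---- shared selections ----------------------------------------------
    plain_a = recs_a[plain_a_start:]
    n_shared_plain = round(spec.shared_identifier_rate * len(plain_a))
    chosen = (
        sorted(rng.choice(len(plain_a), size=n_shared_plain, replace=False).tolist())
        if n_shared_plain
        else []
    )
    shared_plain: list[tuple[str, str]] = []  # (token, molblock)
    for idx in chosen:
        rec = plain_a[idx]
        shared_plain.append((rec.identifiers[0], rec.molblock))

    all_within = [
        (cls, entry) for cls in sorted(within_a) for entry in within_a[cls]
    ]
    shared_within_sel = all_within[: spec.shared_within_ambiguous]
    shared_within: dict[str, list[str]] = {}
    shared_within_hosts: list[tuple[str, str]] = []  # (token, molblock of first record)
    for cls, (token, rid_1, _rid_2) in shared_within_sel:
        shared_within.setdefault(cls, []).append(token)
        shared_within_hosts.append((token, by_rid_a[rid_1].molblock))

    # ---- database B ------------------------------------------------------
    reserved_b = n_cross + len(shared_plain) + len(shared_within_hosts)
    pairs_b = _allocate_pairs(k_plan, n - reserved_b)
    recs_b, pair_rids_b = build_within(name_b, pairs_b)
    cross_entries: dict[str, list[tuple[str, str, str]]] = {}
    cross_b_recs: list[tuple[str, CompoundRecord]] = []
    for cls, token, rid_a, mb_2 in cross_stash:
        rid_b = f"{name_b}-{len(recs_b) + 1:05d}"
        rec = CompoundRecord(rid_b, mb_2, [])
        recs_b.append(rec)
        cross_b_recs.append((token, rec))
        cross_entries.setdefault(cls, []).append((token, rid_a, rid_b))
    shared_copy_recs: list[tuple[str, CompoundRecord]] = []
    for token, molblock in shared_plain + shared_within_hosts:
        rec = CompoundRecord(f"{name_b}-{len(recs_b) + 1:05d}", molblock, [])
        recs_b.append(rec)
        shared_copy_recs.append((token, rec))
    if len(recs_b) > n:
        raise ValueError("within + cross + sharing plans exceed n_compounds for database B")
    plain_b_start = len(recs_b)
    while len(recs_b) < n:
        recs_b.append(CompoundRecord(f"{name_b}-{len(recs_b) + 1:05d}", pool.next_molblock(), []))

    for rec, count in zip(recs_b, counts_b):
        rec.identifiers.extend(tokens() for _ in range(count))
    for token, rec in cross_b_recs + shared_copy_recs:
        rec.identifiers.append(token)

    within_b: dict[str, list[tuple[str, str, str]]] = {}
    by_rid_b = {rec.record_id: rec for rec in recs_b}
    for cls in sorted(k_plan):
        within_b[cls] = []
        hosts = pair_rids_b[cls]
        for t in range(k_plan[cls]):
            rid_1, rid_2 = hosts[t % len(hosts)]
            token = tokens()
            by_rid_b[rid_1].identifiers.append(token)
            by_rid_b[rid_2].identifiers.append(token)
            within_b[cls].append((token, rid_1, rid_2))

    heavy_b = _attach_heavy_tail(recs_b[plain_b_start:], spec.heavy_tail_identifiers, tokens)

    # ---- uniqueness bookkeeping, then contamination ----------------------
    n_unique = {
        name_a: len({i for r in recs_a for i in r.identifiers}),
        name_b: len({i for r in recs_b for i in r.identifiers}),
    }
    contaminants: dict[str, list[str]] = {}
    offset = 0
    for db_name, recs, counts in ((name_a, recs_a, counts_a), (name_b, recs_b, counts_b)):
        n_cont = round(spec.contamination_rate * sum(counts))
        strings = _contaminant_strings(n_cont, offset)
        offset += n_cont
        for s in strings:
            recs[int(rng.integers(0, n))].identifiers.append(s)
        contaminants[db_name] = strings

    truth = GroundTruth(
        db_names=(name_a, name_b),
        seed=spec.seed,
        n_unique=n_unique,
        within_collisions={name_a: within_a, name_b: within_b},
        heavy_tail={name_a: heavy_a, name_b: heavy_b},
        shared_plain=[t for t, _ in shared_plain],
        cross_collisions=cross_entries,
        shared_within=shared_within,
        contaminants=contaminants,
    )
    snap_a = DatabaseSnapshot(name=name_a, records=recs_a)
    snap_b = DatabaseSnapshot(name=name_b, records=recs_b)
    return snap_a, snap_b, truth


def _attach_heavy_tail(
    plain_records: list[CompoundRecord], n_heavy: int, tokens: _TokenFactory
) -> list[str]:
    """Attach each heavy-tail identifier to 101 distinct plain structures."""
    if n_heavy == 0:
        return []
    if len(plain_records) < 101:
        raise ValueError("heavy-tail identifiers need at least 101 plain records")
    out = []
    for _ in range(n_heavy):
        token = tokens()
        for rec in plain_records[:101]:
            rec.identifiers.append(token)
        out.append(token)
    return out
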