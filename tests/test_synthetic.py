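"""Synthetic-database generator: determinism, ground truth, per-class pairs."""

from __future__ import annotations

import pytest
from rdkit import Chem

from chemambig.ambiguity import build_index, identifiers_per_compound, within_ambiguity
from chemambig.ficts import FictsCode, molblock_key, parse_ficts
from chemambig.namefilter import classify_identifier
from chemambig.synthetic import (
    COLLISION_CLASSES,
    GroundTruth,
    SyntheticSpec,
    _sample_counts,
    generate_pair,
    verify_resolvable,
)

import numpy as np


def small_spec(**overrides) -> SyntheticSpec:
    base = dict(
        n_compounds=40,
        identifiers_per_compound=(2.0, 0.2),
        shared_identifier_rate=0.2,
        collision_plan={"stereo": 2, "fragment": 1},
        cross_collision_plan={"stereo": 1},
        shared_within_ambiguous=1,
        contamination_rate=0.02,
        seed=13,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


class TestDeterminism:
    def test_same_seed_reproduces_byte_identical_output(self):
        runs = []
        for _ in range(2):
            snap_a, snap_b, truth = generate_pair(small_spec())
            serialized = "".join(
                rec.record_id + rec.molblock + "|".join(rec.identifiers)
                for snap in (snap_a, snap_b)
                for rec in snap
            )
            runs.append((serialized, truth.to_json()))
        assert runs[0] == runs[1]

    def test_different_seeds_differ(self):
        _, _, t1 = generate_pair(small_spec(seed=1))
        _, _, t2 = generate_pair(small_spec(seed=2))
        assert t1.to_json() != t2.to_json()


class TestGroundTruth:
    def test_empty_plan_expects_and_measures_zero_ambiguity(self):
        spec = small_spec(
            collision_plan={}, cross_collision_plan={}, shared_within_ambiguous=0,
            contamination_rate=0.0,
        )
        snap_a, _, truth = generate_pair(spec)
        for code in ("FICTS", "uICTS", "uuuuu"):
            assert truth.expected_within_pct("synthA", code) == 0.0
            report = within_ambiguity(build_index(snap_a, parse_ficts(code)))
            assert report.ambiguity_pct == 0.0

    def test_stereo_only_plan_expectations(self):
        spec = small_spec(
            collision_plan={"stereo": 4}, cross_collision_plan={}, shared_within_ambiguous=0,
            contamination_rate=0.0,
        )
        snap_a, _, truth = generate_pair(spec)
        assert truth.expected_within_pct("synthA", "FICTu") == 0.0
        baseline = truth.expected_within_pct("synthA", "FICTS")
        assert baseline > 0
        assert within_ambiguity(build_index(snap_a, FictsCode.identity())).ambiguity_pct == baseline

    def test_full_standardization_counts_only_true_structural(self):
        spec = small_spec(
            collision_plan={"true_structural": 2, "stereo": 2, "charge": 1},
            cross_collision_plan={}, shared_within_ambiguous=0, contamination_rate=0.0,
        )
        _, _, truth = generate_pair(spec)
        assert truth.expected_within_ambiguous("synthA", "uuuuu") == 2
        assert truth.expected_within_ambiguous("synthA", "FICTS") == 5

    def test_json_round_trip(self):
        _, _, truth = generate_pair(small_spec())
        assert GroundTruth.from_json(truth.to_json()) == truth

    def test_shared_identifiers_present_in_both_databases(self):
        snap_a, snap_b, truth = generate_pair(small_spec())
        idents_a = {i for rec in snap_a for i in rec.identifiers}
        idents_b = {i for rec in snap_b for i in rec.identifiers}
        for token in truth.shared_plain:
            assert token in idents_a and token in idents_b
        identity = FictsCode.identity()
        keys = {
            name: {
                i: {molblock_key(rec.molblock, identity) for rec in snap if i in rec.identifiers}
                for i in truth.shared_plain
            }
            for name, snap in (("a", snap_a), ("b", snap_b))
        }
        for token in truth.shared_plain:  # plain sharing copies the structure
            assert keys["a"][token] == keys["b"][token]


class TestVerifyResolvable:
    @pytest.mark.parametrize(
        ("smi_a", "smi_b", "cls"),
        [
            ("C[C@H](F)CC", "C[C@@H](F)CC", "stereo"),
            ("OCCC", "OCCC.Cl", "fragment"),
            ("CCCO", "[13CH3]CCO", "isotope"),
            ("CCC(=O)O", "CCC(=O)[O-]", "charge"),
            ("CCC(C)=O", "CCC(=C)O", "tautomer"),
            ("OCCO", "NCCN", "true_structural"),
        ],
    )
    def test_accepts_each_class_exemplar(self, smi_a, smi_b, cls):
        assert verify_resolvable(Chem.MolFromSmiles(smi_a), Chem.MolFromSmiles(smi_b), cls)

    def test_rejects_identical_structures(self):
        mol = Chem.MolFromSmiles("CCO")
        assert not verify_resolvable(mol, Chem.MolFromSmiles("CCO"), "stereo")

    def test_rejects_pair_labelled_with_wrong_class(self):
        a, b = Chem.MolFromSmiles("C[C@H](F)CC"), Chem.MolFromSmiles("C[C@@H](F)CC")
        assert not verify_resolvable(a, b, "isotope")

    def test_rejects_baseline_indistinguishable_tautomers(self):
        """Mobile-H pairs share one Standard InChI and cannot be collisions."""
        pyridone, hydroxypyridine = Chem.MolFromSmiles("O=c1cccc[nH]1"), Chem.MolFromSmiles("Oc1ccccn1")
        assert not verify_resolvable(pyridone, hydroxypyridine, "tautomer")

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            verify_resolvable(Chem.MolFromSmiles("C"), Chem.MolFromSmiles("CC"), "colour")


class TestSpecValidation:
    def test_infeasible_plan_errors_before_generation(self):
        spec = small_spec(n_compounds=4, collision_plan={c: 10 for c in COLLISION_CLASSES})
        with pytest.raises(ValueError, match="infeasible|exceed"):
            generate_pair(spec)

    def test_unknown_collision_class_rejected(self):
        with pytest.raises(ValueError, match="unknown collision class"):
            generate_pair(small_spec(collision_plan={"flavour": 1}))

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            generate_pair(small_spec(shared_identifier_rate=1.5))


class TestStatisticalShape:
    def test_identifiers_per_compound_converges_to_spec_mean(self):
        """Sample mean within +-0.2 of the configured 8.2 at n=5000."""
        spec = SyntheticSpec(
            n_compounds=5000,
            identifiers_per_compound=(8.2, 0.05),
            shared_identifier_rate=0.0,
            collision_plan={},
            cross_collision_plan={},
            shared_within_ambiguous=0,
            contamination_rate=0.0,
            seed=1234,
        )
        snap_a, _, _ = generate_pair(spec)
        assert identifiers_per_compound(snap_a) == pytest.approx(8.2, abs=0.2)

    def test_deterministic_counts_hit_mean_exactly(self):
        rng = np.random.default_rng(0)
        counts = _sample_counts(1000, 2.4, 0, rng)
        assert sum(counts) == 2400
        assert min(counts) >= 1

    def test_tokens_are_never_systematic(self, detectors):
        snap_a, _, truth = generate_pair(small_spec(contamination_rate=0.0))
        sample = [i for rec in snap_a for i in rec.identifiers][:50]
        assert all(
            classify_identifier(i, detectors).label == "non_systematic" for i in sample
        )
        for contaminant_list in truth.contaminants.values():
            assert contaminant_list == []

    def test_heavy_tail_exercises_over_100_statistic(self):
        spec = small_spec(
            n_compounds=160,
            collision_plan={}, cross_collision_plan={}, shared_within_ambiguous=0,
            contamination_rate=0.0, heavy_tail_identifiers=1,
        )
        snap_a, _, truth = generate_pair(spec)
        report = within_ambiguity(build_index(snap_a, FictsCode.identity()))
        assert report.n_identifiers_over_100_structures == 1
        assert report.max_structures_single_identifier == 101
        assert len(truth.heavy_tail["synthA"]) == 1
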