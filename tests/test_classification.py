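"""Replicate rule and solubility-class assignment."""

import random

import pytest

from cutisol.classification import (
    class_counts,
    classification_table,
    classify,
    group_label,
    replicate_filter,
)
from cutisol.sequence_io import ProteinRecord
from conftest import evidence_from, obs


class TestReplicateFilter:
    def test_two_replicates_accepts(self):
        evidence = evidence_from(
            [obs("AYDK", "P1", "urea2M", 1), obs("AYDK", "P1", "urea2M", 2)]
        )
        assert ("P1", "urea2M") in replicate_filter(evidence)

    def test_single_replicate_rejected(self):
        evidence = evidence_from([obs("AYDK", "P1", "urea2M", 1)])
        assert replicate_filter(evidence) == set()

    def test_protein_level_reading_pools_different_peptides(self):
        evidence = evidence_from(
            [obs("AYDK", "P1", "urea2M", 1), obs("GGGR", "P1", "urea2M", 2)]
        )
        assert ("P1", "urea2M") in replicate_filter(evidence, level="protein")
        # the stricter peptide-level reading rejects the same data
        assert replicate_filter(evidence, level="peptide") == set()

    def test_excluded_fraction_never_passes(self):
        evidence = evidence_from(
            [obs("AYDK", "P1", "KTB", 1), obs("AYDK", "P1", "KTB", 2)]
        )
        assert replicate_filter(evidence) == set()

    def test_brute_force_equivalence_random_evidence(self):
        rng = random.Random(42)
        observations = [
            obs(
                rng.choice(["AYDK", "GGGR", "HHQK"]),
                rng.choice(["P1", "P2"]),
                rng.choice(["urea2M", "urea8M", "FP"]),
                rng.randint(1, 3),
            )
            for _ in range(60)
        ]
        evidence = evidence_from(observations)
        got = replicate_filter(evidence, r_required=2)
        # oracle: count distinct replicates per (protein, fraction) directly
        expected = set()
        for pid in ("P1", "P2"):
            for fraction in ("urea2M", "urea8M", "FP"):
                reps = {
                    o.replicate
                    for o in observations
                    if pid in o.protein_ids and o.fraction == fraction
                }
                if len(reps) >= 2:
                    expected.add((pid, fraction))
        assert got == expected


class TestClassify:
    def test_soluble_only(self):
        evidence = evidence_from(
            [
                obs("AYDK", "P1", "urea2M", 1),
                obs("AYDK", "P1", "urea2M", 2),
                obs("AYDK", "P1", "urea4M", 1),
                obs("AYDK", "P1", "urea4M", 3),
            ]
        )
        call = classify(evidence)["P1"]
        assert call.solubility_class == "SOLUBLE_ONLY"
        assert call.first_solubilizing_fraction == "urea2M"
        assert not call.exception

    def test_both(self):
        evidence = evidence_from(
            [
                obs("AYDK", "P1", "urea8M", 1),
                obs("AYDK", "P1", "urea8M", 2),
                obs("AYDK", "P1", "FP", 1),
                obs("AYDK", "P1", "FP", 2),
            ]
        )
        assert classify(evidence)["P1"].solubility_class == "BOTH"

    def test_fp_only_with_exception_flag(self):
        evidence = evidence_from(
            [
                obs("AYDK", "P1", "FP", 1),
                obs("AYDK", "P1", "FP", 2),
                obs("GGGR", "P1", "urea4M", 1),  # single-replicate minority
            ]
        )
        call = classify(evidence)["P1"]
        assert call.solubility_class == "FP_ONLY"
        assert call.exception

    def test_soluble_with_fp_exception(self):
        evidence = evidence_from(
            [
                obs("AYDK", "P1", "urea2M", 1),
                obs("AYDK", "P1", "urea2M", 2),
                obs("AYDK", "P1", "FP", 3),
            ]
        )
        call = classify(evidence)["P1"]
        assert call.solubility_class == "SOLUBLE_ONLY"
        assert call.exception

    def test_insufficient(self):
        evidence = evidence_from([obs("AYDK", "P1", "urea2M", 1)])
        call = classify(evidence)["P1"]
        assert call.solubility_class == "INSUFFICIENT"
        assert call.accepted_fractions == frozenset()

    def test_strength_threshold(self):
        base = [
            obs("AYDK", "P1", "FP", 1),
            obs("AYDK", "P1", "FP", 2),
            obs("GGGR", "P1", "FP", 1),
        ]
        assert classify(evidence_from(base))["P1"].strength == "single"
        more = base + [obs("HHQK", "P1", "FP", 2)]
        assert classify(evidence_from(more))["P1"].strength == "multi"

    def test_partition_every_observed_protein_classified(self, clean_bundle):
        calls = classify(clean_bundle.evidence)
        observed = clean_bundle.evidence.protein_ids()
        assert set(calls) == observed
        for call in calls.values():
            assert call.solubility_class in (
                "SOLUBLE_ONLY", "BOTH", "FP_ONLY", "INSUFFICIENT"
            )

    def test_invariant_to_observation_order_and_slices(self):
        rng = random.Random(7)
        observations = [
            obs("AYDK", "P1", "urea2M", 1, gel_slice="A"),
            obs("AYDK", "P1", "urea2M", 2, gel_slice="B"),
            obs("GGGR", "P1", "FP", 1),
            obs("GGGR", "P1", "FP", 3),
            obs("HHQK", "P2", "FP", 1),
            obs("HHQK", "P2", "FP", 2),
        ]
        reference = classify(evidence_from(observations))
        for _ in range(5):
            shuffled = observations[:]
            rng.shuffle(shuffled)
            relabeled = [
                obs(o.peptide, set(o.protein_ids), o.fraction, o.replicate,
                    gel_slice="whole")
                for o in shuffled
            ]
            assert classify(evidence_from(relabeled)) == reference


class TestClassCounts:
    def _proteins(self):
        return [
            ProteinRecord(id="A", sequence="AYDKGGGR", family="CPR",
                          cpr_group="RR1"),
            ProteinRecord(id="B", sequence="AYDKGGGR", family="CPR",
                          cpr_group="RR2", cluster_id="2RB"),
            ProteinRecord(id="C", sequence="AYDKGGGR", family="CPR",
                          cpr_group="RR2", cluster_id="2RB"),
            ProteinRecord(id="D", sequence="HHQKGGGR", family="TWDL"),
        ]

    def test_cluster_with_only_shared_peptides_counted_once(self):
        proteins = self._proteins()
        evidence = evidence_from(
            [
                obs("AYDK", "A", "urea2M", 1),
                obs("AYDK", "A", "urea2M", 2),
                obs("AYDK", {"B", "C"}, "FP", 1),
                obs("AYDK", {"B", "C"}, "FP", 2),
                obs("HHQK", "D", "FP", 1),
                obs("HHQK", "D", "FP", 2),
            ]
        )
        counts = class_counts(classify(evidence), proteins)
        assert counts.per_protein.loc["FP_ONLY", "RR2"] == 2
        assert counts.table.loc["FP_ONLY", "RR2"] == 1
        assert counts.collapsed_clusters == ["2RB"]
        assert counts.table.loc["SOLUBLE_ONLY", "RR1"] == 1
        assert counts.table.loc["FP_ONLY", "other"] == 1

    def test_planted_counts_recovered_exactly(self, clean_bundle):
        calls = classify(clean_bundle.evidence)
        counts = class_counts(calls, clean_bundle.proteins)
        assert counts.per_protein.sum(axis=1).to_dict() == {
            "SOLUBLE_ONLY": 13,
            "BOTH": 11,
            "FP_ONLY": 48,
        }


def test_group_label_pooling():
    assert group_label(
        ProteinRecord(id="A", sequence="M", family="CPR", cpr_group="RR1")
    ) == "RR1"
    assert group_label(
        ProteinRecord(id="A", sequence="M", family="CPR",
                      cpr_group="unassigned")
    ) == "other"
    assert group_label(ProteinRecord(id="A", sequence="M", family="TWDL")) == "other"


def test_classification_table_marks(toy_proteins):
    evidence = evidence_from(
        [
            obs("AYDK", "P1", "urea2M", 1),
            obs("AYDK", "P1", "urea2M", 2),
            obs("AYDK", "P1", "FP", 1),
        ]
    )
    calls = classify(evidence)
    table = classification_table(calls, toy_proteins, evidence)
    row = table[table["protein"] == "P1"].iloc[0]
    assert row["urea2M"] == "+"
    assert row["FP"] == "(+)"
    assert row["class"] == "SOLUBLE_ONLY"
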