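"""Variant parsing, augmentation, deduplication, fold splitting and IO."""

import numpy as np
import pytest

from ddgfuse import (PointMutation, ProteinSequence, ValidationError,
                     VariantRecord, apply_mutation, augment_with_reverse,
                     deduplicate_average, homology_fold_split, parse_mutation,
                     read_fasta, read_variant_csv, reverse_variant,
                     write_fasta, write_variant_csv)
from ddgfuse.simulate import gen_sequence_clusters
from ddgfuse.variants import pairwise_identity


class TestParseMutation:
    def test_direct_readoff(self):
        seq = ProteinSequence("p", "MAV")
        mut = parse_mutation("A2G", seq)
        assert (mut.wt_residue, mut.position, mut.mut_residue) == ("A", 2, "G")

    @pytest.mark.parametrize("code", [
        "M1M",      # wild type equals mutant
        "G2A",      # sequence has A at position 2, not G
        "A9G",      # out of range
        "A0G",      # positions are 1-based
        "AxG",      # malformed
        "A2B",      # not an amino acid
        "",
    ])
    def test_invalid_codes_rejected(self, code):
        with pytest.raises(ValidationError):
            parse_mutation(code, ProteinSequence("p", "MAV"))


class TestApplyMutation:
    def test_single_substitution(self):
        seq = ProteinSequence("p", "MAV")
        assert apply_mutation(seq, PointMutation("A", 2, "G")).residues == "MGV"

    def test_involution_and_length(self, toy_sequence):
        mut = PointMutation("V", 3, "W")
        mutated = apply_mutation(toy_sequence, mut)
        assert len(mutated) == len(toy_sequence)
        assert sum(a != b for a, b in
                   zip(mutated.residues, toy_sequence.residues)) == 1
        back = apply_mutation(mutated, mut.inverse())
        assert back.residues == toy_sequence.residues


class TestReverseVariant:
    def _record(self, ddg=1.2):
        seq = ProteinSequence("p", "MAV")
        return VariantRecord("p", seq, PointMutation("A", 2, "G"), ddg=ddg)

    def test_antisymmetry_by_definition(self):
        rev = reverse_variant(self._record(1.2))
        assert rev.ddg == -1.2
        assert rev.direction == "reverse"
        assert rev.wildtype.residues == "MGV"
        assert rev.mutation.code == "G2A"
        assert rev.mutant.residues == "MAV"

    def test_involution(self):
        rec = self._record(0.7)
        assert reverse_variant(reverse_variant(rec)) == rec

    def test_zero_ddg(self):
        assert reverse_variant(self._record(0.0)).ddg == 0.0

    def test_fold_label_inherited(self):
        rec = VariantRecord("p", ProteinSequence("p", "MAV"),
                            PointMutation("A", 2, "G"), ddg=1.0, fold_label=3)
        assert reverse_variant(rec).fold_label == 3

    def test_augment_doubles_labelled_records(self):
        recs = [self._record(1.0)]
        out = augment_with_reverse(recs)
        assert len(out) == 2
        assert out[1].ddg == -1.0


class TestDeduplicateAverage:
    def _rec(self, code, ddg):
        seq = ProteinSequence("p", "MAVKLAGDES")
        return VariantRecord("p", seq, parse_mutation(code, seq), ddg=ddg)

    def test_mean_of_duplicates(self):
        out = deduplicate_average(
            [self._rec("A2G", 1.0), self._rec("A2G", 2.0),
             self._rec("L5V", 0.5)])
        assert len(out) == 2
        by_code = {r.mutation.code: r.ddg for r in out}
        assert by_code == {"A2G": 1.5, "L5V": 0.5}

    def test_identity_without_duplicates(self):
        recs = [self._rec("A2G", 1.0), self._rec("L5V", 0.5)]
        assert sorted(r.key for r in deduplicate_average(recs)) == \
            sorted(r.key for r in recs)

    def test_symmetric_cancellation(self):
        out = deduplicate_average([self._rec("A2G", 1.0),
                                   self._rec("A2G", -1.0)])
        assert len(out) == 1 and out[0].ddg == 0.0

    def test_idempotent(self):
        recs = [self._rec("A2G", 1.0), self._rec("A2G", 3.0)]
        once = deduplicate_average(recs)
        assert deduplicate_average(once) == once

    def test_empty(self):
        assert deduplicate_average([]) == []


class TestHomologyFoldSplit:
    def test_identical_sequences_share_a_fold(self):
        seqs = [ProteinSequence(f"s{i}", "MAVKLFGDES" * 3) for i in range(10)]
        folds = homology_fold_split(seqs, k=5)
        assert len(set(folds.values())) == 1

    def test_dissimilar_sequences_spread_one_per_fold(self):
        # brute-force check: all pairwise identities below threshold
        seqs = [ProteinSequence("a", "AAAAAAAAAAAAAAAAAAAA"),
                ProteinSequence("b", "CCCCCCCCCCCCCCCCCCCC"),
                ProteinSequence("c", "DDDDDDDDDDDDDDDDDDDD"),
                ProteinSequence("d", "EEEEEEEEEEEEEEEEEEEE"),
                ProteinSequence("e", "FFFFFFFFFFFFFFFFFFFF")]
        for i in range(5):
            for j in range(i + 1, 5):
                assert pairwise_identity(seqs[i].residues,
                                         seqs[j].residues) < 0.25
        folds = homology_fold_split(seqs, k=5)
        assert sorted(folds.values()) == [1, 2, 3, 4, 5]

    def test_partition_and_cluster_purity(self):
        seqs = gen_sequence_clusters(seed=5, n_clusters=6, cluster_size=4,
                                     length=60)
        folds = homology_fold_split(seqs, k=3, identity_threshold=0.25)
        assert set(folds) == {s.id for s in seqs}
        by_id = {s.id: s for s in seqs}
        for a in seqs:
            for b in seqs:
                if a.id < b.id and pairwise_identity(
                        a.residues, b.residues) >= 0.25:
                    assert folds[a.id] == folds[b.id]
        # greedy balancing keeps folds within one cluster of each other
        sizes = np.bincount(list(folds.values()))[1:]
        assert sizes.max() - sizes.min() <= 4

    def test_invalid_parameters(self):
        seqs = [ProteinSequence("a", "MAV"), ProteinSequence("b", "MGV")]
        with pytest.raises(ValidationError):
            homology_fold_split(seqs, k=1)
        with pytest.raises(ValidationError):
            homology_fold_split(seqs, k=2, identity_threshold=1.5)


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        seqs = [ProteinSequence("p1", "MAVKL"), ProteinSequence("p2", "WYC")]
        path = tmp_path / "x.fasta"
        write_fasta(seqs, path)
        back = read_fasta(path)
        assert {k: v.residues for k, v in back.items()} == \
            {"p1": "MAVKL", "p2": "WYC"}

    def test_variant_csv_roundtrip(self, tmp_path):
        seq = ProteinSequence("p1", "MAVKL")
        direct = VariantRecord("p1", seq, PointMutation("A", 2, "G"),
                               ddg=1.234567891, fold_label=2)
        recs = [direct, reverse_variant(direct),
                VariantRecord("p1", seq, PointMutation("K", 4, "R"))]
        path = tmp_path / "v.csv"
        write_variant_csv(recs, path)
        back = read_variant_csv(path, {"p1": seq})
        assert [r.mutation.code for r in back] == ["A2G", "G2A", "K4R"]
        assert [r.direction for r in back] == ["direct", "reverse", "direct"]
        assert back[0].ddg == pytest.approx(direct.ddg, abs=1e-6)
        assert back[1].ddg == pytest.approx(-direct.ddg, abs=1e-6)
        assert back[1].wildtype.residues == "MGVKL"
        assert back[2].ddg is None
        assert back[0].fold_label == 2

    def test_flip_sign(self, tmp_path):
        seq = ProteinSequence("p1", "MAVKL")
        rec = VariantRecord("p1", seq, PointMutation("A", 2, "G"), ddg=1.0)
        path = tmp_path / "v.csv"
        write_variant_csv([rec], path)
        assert read_variant_csv(path, {"p1": seq},
                                flip_sign=True)[0].ddg == -1.0

    def test_unknown_protein_rejected(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text("protein_id,mutation,ddg\nnope,A2G,1.0\n")
        with pytest.raises(ValidationError):
            read_variant_csv(path, {})
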