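import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressmir as sm
from stressmir.sequence_io import pairwise_identity


def _rec(i, seq, **kw):
    return sm.SequenceRecord(id=f"s{i}", seq=seq, **kw)


class TestReadWriteFasta:
    def test_normalization_case_and_t_to_u(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">a\nacgt\n")
        records = sm.read_fasta(path)
        assert records[0].seq == "ACGU"

    def test_roundtrip_identity(self, tmp_path):
        records = [_rec(0, "AUGC"), _rec(1, "GGCCAU"), _rec(2, "UUUA")]
        path = tmp_path / "out.fasta"
        sm.write_fasta(records, path)
        back = sm.read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">z\nAAA\n>a\nCCC\n>m\nGGG\n")
        assert [r.id for r in sm.read_fasta(path)] == ["z", "a", "m"]

    def test_not_fasta_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("ACGU\nACGU\n")
        with pytest.raises(sm.ValidationError, match="line 1"):
            sm.read_fasta(path)

    def test_duplicate_ids_listed(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nAAA\n>a\nCCC\n")
        with pytest.raises(sm.ValidationError, match="a"):
            sm.read_fasta(path)


class TestLabels:
    def test_read_and_attach(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("x\tpositive\ny\tnegative\n")
        labels = sm.read_labels(path)
        records = [
            sm.SequenceRecord(id="x", seq="AUGC"),
            sm.SequenceRecord(id="y", seq="GGCC"),
        ]
        labeled = sm.sequence_io.attach_labels(records, labels)
        assert [r.label for r in labeled] == ["positive", "negative"]

    def test_bad_label_value_rejected(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("x\tmaybe\n")
        with pytest.raises(sm.ValidationError):
            sm.read_labels(path)


class TestCleanDataset:
    def test_duplicates_and_nonstandard_removed(self):
        records = [
            _rec(0, "AUGC"),
            _rec(1, "AUGC"),   # duplicate of 0
            _rec(2, "AUNC"),   # non-standard residue
            _rec(3, "GGCC"),
            _rec(4, "UUAA"),
        ]
        retained, report = sm.clean_dataset(records)
        assert [r.id for r in retained] == ["s0", "s3", "s4"]
        assert "non-standard residues): 1" in report
        assert "identical sequences): 1" in report

    def test_identity_on_clean_input(self):
        records = [_rec(0, "AUGC"), _rec(1, "GGCC")]
        retained, _ = sm.clean_dataset(records)
        assert retained == records

    def test_idempotent(self):
        records = [_rec(i, s) for i, s in enumerate(["AUGC", "AUGC", "GGNC", "UUAA"])]
        once, _ = sm.clean_dataset(records)
        twice, _ = sm.clean_dataset(once)
        assert once == twice

    def test_empty_output_raises(self):
        with pytest.raises(sm.DataError, match="no sequences survive"):
            sm.clean_dataset([_rec(0, "NNN")])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGUN", min_size=1, max_size=8), min_size=1, max_size=12
        )
    )
    def test_filter_dedup_order_independence(self, seqs):
        records = [_rec(i, s) for i, s in enumerate(seqs)]
        # order A: drop non-standard first, then dedup (the implementation)
        try:
            retained_a, _ = sm.clean_dataset(records)
        except sm.DataError:
            retained_a = []
        # order B: dedup first, then drop non-standard (independent reimpl.)
        seen, dedup = set(), []
        for r in records:
            if r.seq not in seen:
                seen.add(r.seq)
                dedup.append(r)
        retained_b = [r for r in dedup if r.is_standard()]
        assert {r.seq for r in retained_a} == {r.seq for r in retained_b}


def _lcs_len(a: str, b: str) -> int:
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i, j] = (
                dp[i - 1, j - 1] + 1
                if a[i - 1] == b[j - 1]
                else max(dp[i - 1, j], dp[i, j - 1])
            )
    return int(dp[-1, -1])


def oracle_identity(a: str, b: str) -> float:
    m = _lcs_len(a, b)
    return m / (len(a) + len(b) - m)


class TestReduceRedundancy:
    def test_identical_sequences_collapse(self):
        records = [_rec(0, "AUGCAUGC"), _rec(1, "AUGCAUGC")]
        assert len(sm.reduce_redundancy(records, 0.8)) == 1

    def test_disjoint_alphabets_retained(self):
        records = [_rec(0, "AAAA"), _rec(1, "CCCC")]
        assert len(sm.reduce_redundancy(records, 0.8)) == 2

    def test_matches_brute_force_greedy_oracle(self, rng):
        from tests.conftest import random_rna

        records = [_rec(i, random_rna(rng, 24)) for i in range(10)]
        got = sm.reduce_redundancy(records, 0.8)
        kept: list = []
        for rec in records:
            if all(oracle_identity(rec.seq, k.seq) < 0.8 for k in kept):
                kept.append(rec)
        assert [r.id for r in got] == [r.id for r in kept]

    def test_output_size_non_increasing_in_threshold(self, rng):
        from tests.conftest import random_rna

        records = [_rec(i, random_rna(rng, 20)) for i in range(12)]
        sizes = [
            len(sm.reduce_redundancy(records, t)) for t in (0.5, 0.7, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_threshold_out_of_range(self):
        with pytest.raises(sm.ValidationError):
            sm.reduce_redundancy([_rec(0, "AUGC")], 0.0)


class TestPairCombined:
    def _manifests(self, mat_ids, pre_ids, label="positive"):
        mat = sm.DatasetManifest(
            records=[
                sm.SequenceRecord(id=i, seq="AUGCAUGCAUGC", role="mature", label=label)
                for i in mat_ids
            ],
            mode="miRNA",
        )
        pre = sm.DatasetManifest(
            records=[
                sm.SequenceRecord(id=i, seq="GGCCAUGCAUGCAUGC", role="precursor", label=label)
                for i in pre_ids
            ],
            mode="premiRNA",
        )
        return mat, pre

    def test_matched_ids_pair(self):
        mat, pre = self._manifests(["a", "b", "c"], ["a", "b", "c"])
        combined = sm.pair_combined(mat, pre)
        assert len(combined) == 3
        assert combined.pairing == {"a": "a", "b": "b", "c": "c"}

    def test_unmatched_dropped_with_warning(self):
        mat, pre = self._manifests(["a", "x"], ["a"])
        combined = sm.pair_combined(mat, pre)
        assert len(combined) == 1
        assert any("x" in line for line in combined.provenance)

    def test_strict_mode_raises_on_unmatched(self):
        mat, pre = self._manifests(["a", "x"], ["a"])
        with pytest.raises(sm.DataError, match="x"):
            sm.pair_combined(mat, pre, strict=True)

    def test_label_disagreement_raises(self):
        mat, _ = self._manifests(["a"], [], label="positive")
        _, pre = self._manifests([], ["a"], label="negative")
        with pytest.raises(sm.DataError, match="disagreement"):
            sm.pair_combined(mat, pre)

    def test_seventy_pairs(self):
        ids = [f"m{i}" for i in range(70)]
        mat, pre = self._manifests(ids, ids)
        combined = sm.pair_combined(mat, pre)
        assert len(combined) == 70
        # pairing is a bijection between retained mature and precursor ids
        assert set(combined.pairing) == set(combined.pairing.values()) == set(ids)
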