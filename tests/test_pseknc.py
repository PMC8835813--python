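"""Encoder correctness against an independent brute-force oracle.

The oracle below recomputes every quantity with naive double loops straight
from the defining formulas, deliberately sharing no code with the
vectorized encoder.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressmir as sm
from stressmir.properties import all_tuples, default_table
from tests.conftest import random_rna

# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_frequencies(seq: str, k: int) -> dict[str, float]:
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return {t: windows.count(t) / len(windows) for t in all_tuples(k)}


def oracle_delta(seq: str, k: int, j: int, table) -> float:
    length = len(seq)
    total = 0.0
    n_terms = length - k - j + 1
    for i in range(n_terms):
        a = table.values(seq[i : i + k])
        b = table.values(seq[i + j : i + j + k])
        phi = sum((a[r] - b[r]) ** 2 for r in range(table.r)) / table.r
        total += phi
    return total / n_terms


def oracle_block(seq: str, k: int, config: sm.PseKNCConfig) -> np.ndarray:
    table = config.property_tables[k]
    g = oracle_frequencies(seq, k)
    deltas = [oracle_delta(seq, k, j, table) for j in range(1, config.lam + 1)]
    denom = sum(g.values()) + config.omega * sum(deltas)
    freq_part = [g[t] / denom for t in all_tuples(k)]
    corr_part = [config.omega * d / denom for d in deltas]
    return np.array(freq_part + corr_part)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestKtupleFrequencies:
    def test_homopolymer_is_one_hot(self):
        freqs = sm.ktuple_frequencies("AAAA", 2)
        assert freqs[0] == 1.0 and freqs[1:].sum() == 0.0

    def test_three_overlapping_windows(self):
        freqs = sm.ktuple_frequencies("AUGC", 2)
        idx = {t: i for i, t in enumerate(all_tuples(2))}
        assert freqs[idx["AU"]] == pytest.approx(1 / 3)
        assert freqs[idx["UG"]] == pytest.approx(1 / 3)
        assert freqs[idx["GC"]] == pytest.approx(1 / 3)
        assert freqs.sum() == pytest.approx(1.0)

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(20):
            seq = random_rna(rng, 24)
            got = sm.ktuple_frequencies(seq, 5)
            want = oracle_frequencies(seq, 5)
            np.testing.assert_allclose(got, [want[t] for t in all_tuples(5)], atol=1e-15)

    def test_too_short_raises(self):
        with pytest.raises(sm.ValidationError):
            sm.ktuple_frequencies("AU", 3)


class TestTierCorrelation:
    def test_homopolymer_gives_zero(self):
        table = default_table(2)
        for j in (1, 2, 3):
            assert sm.tier_correlation("AAAAAA", 2, j, table) == 0.0

    def test_constant_property_table_gives_zero(self):
        table = sm.PropertyTable(
            k=2, property_names=("p",), matrix=np.zeros((16, 1)), name="const"
        )
        assert sm.tier_correlation("AUGCAUGC", 2, 1, table) == 0.0

    def test_matches_double_loop_oracle(self):
        table = sm.PropertyTable.from_values(
            2,
            ("x", "y"),
            {t: (float(i), float(i % 3)) for i, t in enumerate(all_tuples(2))},
            standardize=False,
        )
        got = sm.tier_correlation("AUAU", 2, 1, table)
        assert got == pytest.approx(oracle_delta("AUAU", 2, 1, table), abs=1e-15)

    def test_property_scaling_is_quadratic(self, rng):
        base = default_table(2)
        scaled = sm.PropertyTable(
            k=2, property_names=base.property_names, matrix=3.0 * base.matrix, name="x3"
        )
        seq = random_rna(rng, 24)
        assert sm.tier_correlation(seq, 2, 2, scaled) == pytest.approx(
            9.0 * sm.tier_correlation(seq, 2, 2, base), rel=1e-12
        )

    def test_too_short_names_minimum_length(self):
        with pytest.raises(sm.ValidationError, match="length >= 8"):
            sm.tier_correlation("AUGCA", 5, 3, default_table(5))


class TestEncodeBlockAndSequence:
    @pytest.mark.parametrize("k,expected", [(2, 19), (3, 67), (4, 259), (5, 1027)])
    def test_block_dimensions(self, rng, k, expected):
        seq = random_rna(rng, 24)
        assert len(sm.encode_block(seq, k, sm.PseKNCConfig())) == expected

    def test_full_vector_is_1372(self, rng):
        assert len(sm.encode_sequence(random_rna(rng, 24))) == 1372

    def test_homopolymer_block_is_one_hot(self):
        block = sm.encode_block("A" * 24, 2, sm.PseKNCConfig())
        assert block[0] == 1.0 and np.all(block[1:] == 0.0)

    def test_vectorized_equals_oracle_on_random_sequences(self, rng):
        config = sm.PseKNCConfig()
        for _ in range(100):
            seq = random_rna(rng, int(rng.integers(20, 25)))
            for k in config.k_values:
                np.testing.assert_allclose(
                    sm.encode_block(seq, k, config),
                    oracle_block(seq, k, config),
                    atol=1e-12,
                )

    def test_blocks_sum_to_one(self, rng):
        config = sm.PseKNCConfig()
        vec = sm.encode_sequence(random_rna(rng, 24), config)
        start = 0
        for k in config.k_values:
            size = 4**k + config.lam
            assert vec[start : start + size].sum() == pytest.approx(1.0, abs=1e-9)
            start += size
        assert vec.sum() == pytest.approx(len(config.k_values), abs=1e-8)

    def test_non_negative_and_deterministic(self, rng):
        seq = random_rna(rng, 24)
        v1, v2 = sm.encode_sequence(seq), sm.encode_sequence(seq)
        assert np.all(v1 >= 0.0)
        np.testing.assert_array_equal(v1, v2)

    def test_t_to_u_invariance(self):
        v_dna = sm.encode_sequence("ATGCATGCATGCATGCATGCATGC")
        v_rna = sm.encode_sequence("AUGCAUGCAUGCAUGCAUGCAUGC")
        np.testing.assert_array_equal(v_dna, v_rna)

    def test_too_short_sequence_names_minimum(self):
        with pytest.raises(sm.ValidationError, match="minimum length is 8"):
            sm.encode_sequence("AUGCAUG")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=8, max_size=40))
    def test_block_normalization_property(self, seq):
        config = sm.PseKNCConfig(k_values=(2, 3), lam=3)
        for k in config.k_values:
            block = sm.encode_block(seq, k, config)
            assert block.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(block >= 0.0)


class TestPropertyTables:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_standardized_mean_zero_var_one(self, k):
        table = default_table(k)
        np.testing.assert_allclose(table.matrix.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(table.matrix.var(axis=0), 1.0, atol=1e-9)

    def test_roundtrip_via_file(self, tmp_path):
        table = default_table(2)
        path = tmp_path / "dinuc.tsv"
        table.to_file(path)
        loaded = sm.PropertyTable.from_file(path)
        np.testing.assert_allclose(loaded.matrix, table.matrix, atol=1e-9)

    def test_missing_tuple_rejected(self):
        values = {t: (1.0,) for t in all_tuples(2) if t != "GC"}
        with pytest.raises(sm.ValidationError, match="missing"):
            sm.PropertyTable.from_values(2, ("p",), values)


class TestEncodeDataset:
    def test_matrix_shape_mature(self):
        result = sm.simulate(sm.SimSpec(n_per_class=5, seed=3))
        matrix = sm.encode_dataset(result.mature_manifest())
        assert matrix.X.shape == (10, 1372)

    def test_combined_mode_is_2744(self):
        result = sm.simulate(sm.SimSpec(n_per_class=5, seed=3, paired=True))
        matrix = sm.encode_dataset(result.combined_manifest())
        assert matrix.X.shape == (10, 2744)
        assert matrix.feature_names[0].startswith("mat_")
        assert matrix.feature_names[-1].startswith("pre_")

    def test_row_permutation_preserves_values(self):
        result = sm.simulate(sm.SimSpec(n_per_class=4, seed=3))
        manifest = result.mature_manifest()
        config = sm.PseKNCConfig(k_values=(2,))
        m1 = sm.encode_dataset(manifest, config)
        shuffled = sm.DatasetManifest(records=list(reversed(manifest.records)), mode="miRNA")
        m2 = sm.encode_dataset(shuffled, config)
        by_id1 = dict(zip(m1.ids, m1.X))
        by_id2 = dict(zip(m2.ids, m2.X))
        for rid in m1.ids:
            np.testing.assert_array_equal(by_id1[rid], by_id2[rid])

    def test_unencodable_ids_listed(self):
        records = [
            sm.SequenceRecord(id="ok", seq="AUGCAUGCAUGC", label="positive"),
            sm.SequenceRecord(id="short", seq="AUG", label="negative"),
        ]
        manifest = sm.DatasetManifest(records=records, mode="miRNA")
        with pytest.raises(sm.DataError, match="short"):
            sm.encode_dataset(manifest)
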