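"""Feature construction: embeddings, omics aggregation, scaling, integration."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from targetrank import (
    FeatureBlock,
    HashSeededEmbedder,
    PrecomputedEmbeddings,
    aggregate_expression,
    build_omics_block,
    count_mutations,
    embed_sequences,
    integrate_features,
    minmax_normalize,
)


class TestEmbedSequences:
    def test_reference_dimension(self):
        backend = HashSeededEmbedder()
        block = embed_sequences(
            [("A", "MKV"), ("B", "MACW"), ("C", "MW")], backend
        )
        assert block.matrix.shape == (3, 1024)
        assert block.name == "embedding"

    def test_identical_sequences_identical_rows(self):
        backend = HashSeededEmbedder(dimension=16)
        block = embed_sequences([("A", "MKVW"), ("B", "MKVW")], backend)
        np.testing.assert_array_equal(block.matrix[0], block.matrix[1])

    def test_hash_seeded_vector_matches_independent_recomputation(self):
        """The deterministic backend equals a by-hand rebuild of its generator."""
        backend = HashSeededEmbedder(dimension=64)
        got = backend.embed("ACDEFG")
        digest = hashlib.blake2b(b"ACDEFG", digest_size=8).digest()
        expected = np.random.default_rng(
            int.from_bytes(digest, "big")
        ).standard_normal(64)
        np.testing.assert_array_equal(got, expected)

    def test_invalid_character_names_position(self):
        backend = HashSeededEmbedder(dimension=8)
        with pytest.raises(ValueError, match="position 2"):
            embed_sequences([("A", "MK1V")], backend)

    def test_long_sequence_truncated_with_warning(self, caplog):
        backend = HashSeededEmbedder(dimension=8, max_tokens=10)
        long_seq = "M" * 25
        with caplog.at_level("WARNING"):
            block = embed_sequences([("A", long_seq)], backend)
        assert "truncated" in caplog.text
        np.testing.assert_array_equal(block.matrix[0], backend.embed("M" * 10))

    def test_no_collisions_among_random_sequences(self):
        """Distinct sequences map to distinct vectors (hash-seeded backend)."""
        rng = np.random.default_rng(0)
        backend = HashSeededEmbedder(dimension=8)
        seqs = set()
        while len(seqs) < 10_000:
            seqs.add("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12)))
        first_coords = {tuple(backend.embed(s)[:2]) for s in seqs}
        assert len(first_coords) == len(seqs)

    def test_precomputed_backend_serves_cached_vectors(self):
        table = {"A": np.arange(4.0), "B": np.arange(4.0) + 1}
        backend = PrecomputedEmbeddings(table=table)
        backend.register("A", "MKV")
        np.testing.assert_array_equal(backend.embed("MKV"), np.arange(4.0))


class TestAggregateExpression:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 3, 5], (5, 3, 3, 1)),
            ([7], (7, 7, 7, 7)),
            ([2, 2, 8, 8], (8, 5, 5, 2)),  # even-length median = midpoint
        ],
    )
    def test_worked_examples(self, values, expected):
        assert aggregate_expression(values) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no expression samples"):
            aggregate_expression([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50))
    def test_order_statistics_are_ordered(self, values):
        mx, mean, med, mn = aggregate_expression(values)
        assert mn <= med <= mx and mn <= mean <= mx


class TestCountMutations:
    def _maf(self):
        return pd.DataFrame(
            {
                "gene_symbol": ["TP53", "TP53", "TP53", "KRAS", "KRAS", "EGFR"],
                "sample_id": [f"S{i}" for i in range(6)],
                "mutated_flag": ["TRUE", "FALSE", "TRUE", "TRUE", "TRUE", "FALSE"],
            }
        )

    def test_counts_true_flags_only(self):
        assert count_mutations(self._maf(), "TP53") == 2
        assert count_mutations(self._maf(), "KRAS") == 2
        assert count_mutations(self._maf(), "EGFR") == 0

    def test_absent_gene_is_zero(self):
        assert count_mutations(self._maf(), "BRCA1") == 0

    def test_all_true_records(self):
        maf = pd.DataFrame(
            {"gene_symbol": ["A"] * 3, "sample_id": list("xyz"), "mutated_flag": [True] * 3}
        )
        assert count_mutations(maf, "A") == 3


class TestMinMaxNormalize:
    def _block(self, matrix):
        m = np.asarray(matrix, dtype=float)
        return FeatureBlock("test", [f"g{i}" for i in range(m.shape[0])], m)

    def test_full_fit_maps_to_unit_interval(self):
        out, _ = minmax_normalize(self._block([[2], [4], [6]]))
        np.testing.assert_allclose(out.matrix.ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        out, _ = minmax_normalize(self._block([[5], [5], [5]]))
        np.testing.assert_array_equal(out.matrix, 0.0)

    def test_out_of_fit_rows_clip(self):
        out, _ = minmax_normalize(self._block([[2], [4], [8]]), fit_rows=[0, 1])
        # (8-2)/(4-2)=3 before clipping
        assert out.matrix[2, 0] == 1.0

    def test_inverse_transform_recovers_fit_rows(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(size=(20, 6))
        block = self._block(matrix)
        out, scaler = minmax_normalize(block)
        np.testing.assert_allclose(scaler.inverse_transform(out.matrix), matrix, atol=1e-9)

    def test_fit_rows_in_unit_interval(self):
        rng = np.random.default_rng(2)
        block = self._block(rng.normal(size=(30, 4)))
        fit = list(range(0, 30, 2))
        out, _ = minmax_normalize(block, fit_rows=fit)
        assert out.matrix[fit].min() >= 0.0 and out.matrix[fit].max() <= 1.0

    def test_nonfinite_input_names_column(self):
        matrix = np.ones((3, 2))
        matrix[1, 1] = np.nan
        with pytest.raises(ValueError, match=r"column\(s\) \[1\]"):
            minmax_normalize(self._block(matrix))


class TestIntegrateFeatures:
    def test_reference_dimensions(self):
        genes = ["A", "B"]
        emb = FeatureBlock("embedding", genes, np.zeros((2, 1024)))
        om = FeatureBlock("omics", genes, np.ones((2, 5)))
        integrated = integrate_features(emb, om)
        assert integrated.matrix.shape == (2, 1029)
        assert integrated.name == "integrated"

    def test_zero_genes(self):
        emb = FeatureBlock("embedding", [], np.zeros((0, 1024)))
        om = FeatureBlock("omics", [], np.zeros((0, 5)))
        assert integrate_features(emb, om).matrix.shape == (0, 1029)

    def test_gene_order_mismatch_raises(self):
        emb = FeatureBlock("embedding", ["A", "B"], np.zeros((2, 1024)))
        om = FeatureBlock("omics", ["B", "A"], np.zeros((2, 5)))
        with pytest.raises(ValueError, match="gene order"):
            integrate_features(emb, om)

    def test_slices_recover_sources_bitwise(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(7)]
        emb = FeatureBlock("embedding_custom", genes, rng.normal(size=(7, 12)))
        om = FeatureBlock("omics", genes, rng.normal(size=(7, 5)))
        integrated = integrate_features(emb, om)
        assert np.array_equal(integrated.matrix[:, :12], emb.matrix)
        assert np.array_equal(integrated.matrix[:, 12:], om.matrix)


def test_omics_block_from_tables():
    expression = pd.DataFrame(
        {"S1": [1.0, 4.0], "S2": [3.0, 4.0], "S3": [5.0, 4.0]},
        index=["GENEA", "GENEB"],
    )
    maf = pd.DataFrame(
        {
            "gene_symbol": ["GENEA", "GENEA", "GENEB"],
            "sample_id": ["S1", "S2", "S1"],
            "mutated_flag": ["TRUE", "TRUE", "FALSE"],
        }
    )
    block = build_omics_block(["GENEA", "GENEB", "GENEC"], expression, maf)
    np.testing.assert_allclose(block.matrix[0], [5, 3, 3, 1, 2])
    np.testing.assert_allclose(block.matrix[1], [4, 4, 4, 4, 0])
    np.testing.assert_allclose(block.matrix[2], [0, 0, 0, 0, 0])  # missing gene


def test_named_block_dimension_enforced():
    with pytest.raises(ValueError, match="1024"):
        FeatureBlock("embedding", ["A"], np.zeros((1, 10)))
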