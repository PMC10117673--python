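"""Dataset assembly: positive-set union, negative sampling, balance invariants."""

import numpy as np
import pandas as pd
import pytest

from targetrank import (
    CancerDataset,
    GeneRecord,
    assemble_all,
    assemble_dataset,
    attach_sequences,
    build_negative_pool,
    build_positive_set,
    dataset_counts,
    sample_negatives,
)
from targetrank.assembly import read_dataset, write_dataset


def _dti(symbols, drugs=None):
    drugs = drugs or [f"DB{i:05d}" for i in range(len(symbols))]
    return pd.DataFrame({"drug_id": drugs, "gene_symbol": symbols})


def _reviewed(symbols, flag=True):
    return {s: flag for s in symbols}


class TestBuildPositiveSet:
    def test_union_of_disjoint_targets_and_biomarkers(self):
        """24 unique approved targets + 91 disjoint biomarkers, all curated -> 115."""
        targets = [f"TGT{i:03d}" for i in range(24)]
        # several drugs share targets: 28 interactions over 24 unique genes
        dti = _dti(targets + targets[:4])
        biomarkers = [f"BMK{i:03d}" for i in range(91)]
        flags = _reviewed(targets + biomarkers)
        positives = build_positive_set(dti, biomarkers, flags)
        assert len(positives) == 115
        assert all(r.label == 1 for r in positives)

    def test_union_with_empty_biomarkers(self):
        positives = build_positive_set(_dti(["A", "B", "C"]), [], _reviewed("ABC"))
        assert {r.symbol for r in positives} == {"A", "B", "C"}

    def test_overlapping_sources_deduplicate(self):
        positives = build_positive_set(
            _dti(["A", "B"]), ["B", "C"], _reviewed("ABC")
        )
        assert {r.symbol for r in positives} == {"A", "B", "C"}

    def test_unreviewed_genes_are_dropped(self):
        flags = {"A": True, "B": False, "C": True}
        positives = build_positive_set(_dti(["A", "B"]), ["C"], flags)
        assert {r.symbol for r in positives} == {"A", "C"}

    def test_empty_after_filter_raises(self):
        with pytest.raises(ValueError, match="no positive genes"):
            build_positive_set(_dti(["A"]), [], {"A": False})

    def test_case_and_whitespace_normalized(self):
        positives = build_positive_set(
            _dti([" tp53 ", "TP53"]), ["tp53"], {"TP53": True}
        )
        assert {r.symbol for r in positives} == {"TP53"}

    def test_union_matches_bruteforce_oracle(self):
        """Random toy tables against a direct set-union computation."""
        rng = np.random.default_rng(42)
        universe = [f"G{i:03d}" for i in range(60)]
        for _ in range(25):
            targets = list(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            markers = list(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            reviewed = {g: bool(rng.random() < 0.8) for g in universe}
            expected = {g for g in set(targets) | set(markers) if reviewed[g]}
            if not expected:
                continue
            got = build_positive_set(_dti(targets), markers, reviewed)
            assert {r.symbol for r in got} == expected


class TestNegativePool:
    def test_removes_positives(self):
        table = pd.DataFrame(
            {"gene_symbol": [f"G{i}" for i in range(10)], "protein_name": ["p"] * 10}
        )
        pool = build_negative_pool(table, ["G0", "G1", "G2"])
        assert len(pool) == 7 and not pool & {"G0", "G1", "G2"}

    def test_no_overlap_leaves_pool_unchanged(self):
        table = pd.DataFrame({"gene_symbol": ["A", "B"], "protein_name": ["p", "q"]})
        assert build_negative_pool(table, ["X", "Y"]) == {"A", "B"}

    def test_pool_subset_of_positives_raises(self):
        table = pd.DataFrame({"gene_symbol": ["A", "B"], "protein_name": ["p", "q"]})
        with pytest.raises(ValueError, match="insufficient negative pool"):
            build_negative_pool(table, ["A", "B"])


class TestSampleNegatives:
    def test_draws_exactly_k(self):
        pool = {f"G{i:04d}" for i in range(300)}
        negatives = sample_negatives(pool, 215, seed=3)
        assert len(negatives) == 215
        assert all(r.label == 0 for r in negatives)

    def test_same_seed_same_sample(self):
        pool = {f"G{i:04d}" for i in range(100)}
        a = sample_negatives(pool, 30, seed=5)
        b = sample_negatives(pool, 30, seed=5)
        assert {r.symbol for r in a} == {r.symbol for r in b}

    def test_accumulated_draws_are_disjoint(self):
        pool = {f"G{i:04d}" for i in range(500)}
        rng = np.random.default_rng(0)
        for _ in range(100):
            used: set[str] = set()
            k1, k2 = rng.integers(1, 100, size=2)
            first = sample_negatives(pool, int(k1), seed=int(rng.integers(2**31)), already_used=used)
            used |= {r.symbol for r in first}
            second = sample_negatives(pool, int(k2), seed=int(rng.integers(2**31)), already_used=used)
            assert not {r.symbol for r in first} & {r.symbol for r in second}

    def test_shortfall_raises_with_count(self):
        with pytest.raises(ValueError, match="short by 3"):
            sample_negatives({"A", "B"}, 5, seed=0)


class TestAssembleDataset:
    def test_balanced_sizes(self):
        pos = [GeneRecord(f"P{i}", 1) for i in range(215)]
        neg = [GeneRecord(f"N{i}", 0) for i in range(215)]
        ds = assemble_dataset("leukemia", pos, neg)
        assert len(ds) == 430

    def test_minimal_dataset(self):
        ds = assemble_dataset("bladder", [GeneRecord("A", 1)], [GeneRecord("B", 0)])
        assert len(ds) == 2

    def test_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            assemble_dataset("colon", [GeneRecord("A", 1)], [GeneRecord("A", 0)])

    def test_imbalance_raises(self):
        with pytest.raises(ValueError, match="unbalanced"):
            assemble_dataset(
                "colon",
                [GeneRecord("A", 1), GeneRecord("B", 1)],
                [GeneRecord("C", 0)],
            )


class TestMultiCancerAssembly:
    def _inputs(self, n_cancers=3, n_pos=8):
        per_cancer = {}
        for c in range(n_cancers):
            symbols = [f"C{c}P{i}" for i in range(n_pos)]
            per_cancer[f"cancer_{c}"] = {
                "dti_table": _dti(symbols[: n_pos // 2]),
                "biomarker_genes": symbols[n_pos // 2 :],
                "reviewed_flags": _reviewed(symbols),
            }
        pool_symbols = [f"C{c}P{i}" for c in range(n_cancers) for i in range(n_pos)]
        pool_symbols += [f"NEG{i:04d}" for i in range(n_cancers * n_pos * 3)]
        pool = pd.DataFrame(
            {"gene_symbol": pool_symbols, "protein_name": ["x"] * len(pool_symbols)}
        )
        return per_cancer, pool

    def test_negative_sets_pairwise_disjoint(self):
        per_cancer, pool = self._inputs()
        datasets = assemble_all(per_cancer, pool, master_seed=1)
        all_negs = [s for d in datasets.values() for s in (r.symbol for r in d.negatives)]
        assert len(all_negs) == len(set(all_negs))
        for d in datasets.values():
            assert len(d.positives) == len(d.negatives)

    def test_rerun_is_identical(self, tmp_path):
        per_cancer, pool = self._inputs()
        files = []
        for run in range(2):
            datasets = assemble_all(per_cancer, pool, master_seed=9)
            path = tmp_path / f"run{run}.tsv"
            write_dataset(datasets["cancer_1"], path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_counts_report_global_unique(self):
        per_cancer, pool = self._inputs(n_cancers=2, n_pos=4)
        datasets = assemble_all(per_cancer, pool, master_seed=0)
        counts = dataset_counts(datasets)
        assert counts["sum_over_cancers"] == sum(
            c["all"] for c in counts["per_cancer"].values()
        )
        assert counts["global_unique"] <= counts["sum_over_cancers"]

    def test_sequence_join_preserves_balance(self):
        per_cancer, pool = self._inputs(n_cancers=1, n_pos=6)
        symbols = pool["gene_symbol"].tolist()
        sequences = {s: "MKT" for s in symbols if not s.endswith("P0")}  # drop one positive
        datasets = assemble_all(per_cancer, pool, sequences=sequences, master_seed=2)
        d = next(iter(datasets.values()))
        assert len(d.positives) == len(d.negatives) == 5
        assert all(r.sequence for r in d.records)


def test_attach_sequences_drops_missing():
    records = [GeneRecord("A", 1), GeneRecord("B", 1)]
    kept, dropped = attach_sequences(records, {"A": "MKV"})
    assert [r.symbol for r in kept] == ["A"] and dropped == ["B"]
    assert kept[0].sequence == "MKV"


def test_dataset_roundtrip(tmp_path):
    ds = assemble_dataset(
        "lung",
        [GeneRecord("A", 1, sequence="MKV"), GeneRecord("B", 1, sequence="MAC")],
        [GeneRecord("C", 0, sequence="MW"), GeneRecord("D", 0, sequence="MY")],
    )
    path = tmp_path / "lung.tsv"
    write_dataset(ds, path)
    loaded = read_dataset(path, "lung")
    assert loaded.symbols == ds.symbols and loaded.labels == ds.labels


def test_gene_record_validation():
    with pytest.raises(ValueError):
        GeneRecord("", 1)
    with pytest.raises(ValueError):
        GeneRecord("A", 2)
    with pytest.raises(ValueError, match="invalid residues"):
        GeneRecord("A", 1, sequence="MK9")
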