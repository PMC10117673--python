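"""Assembly of balanced target/non-target gene datasets per cancer type.

The positive class for a cancer is the union of (a) genes targeted by an
approved drug for that cancer and (b) genes called as significantly
overexpressed biomarkers, restricted to genes with reviewed (curated)
protein records.  The negative class is sampled uniformly, without
replacement, from the pool of human protein-coding genes after removing
every positive gene of every cancer type; negative sets of different
cancers never share a gene.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import CancerDataset, GeneRecord, normalize_symbol

logger = logging.getLogger(__name__)


def build_positive_set(
    dti_table: pd.DataFrame,
    biomarker_genes: Iterable[str],
    reviewed_flags: Mapping[str, bool],
) -> set[GeneRecord]:
    """Union approved drug-target genes with overexpressed biomarker genes.

    Parameters
    ----------
    dti_table
        Approved drug-target interactions with columns ``drug_id`` and
        ``gene_symbol``.  Multiple drugs hitting the same gene collapse to
        one positive record.
    biomarker_genes
        Gene symbols of significantly overexpressed biomarkers.
    reviewed_flags
        Map from gene symbol to whether the gene has a reviewed (curated)
        protein record; unreviewed genes are excluded.

    Returns
    -------
    set of GeneRecord, all with label 1.
    """
    if dti_table is None or biomarker_genes is None:
        raise ValueError("dti_table and biomarker_genes must be non-null")
    if "gene_symbol" not in dti_table.columns:
        raise ValueError("dti_table must have a gene_symbol column")

    targets = [normalize_symbol(s) for s in dti_table["gene_symbol"].astype(str)]
    markers = [normalize_symbol(s) for s in biomarker_genes]
    flags = {normalize_symbol(k): bool(v) for k, v in reviewed_flags.items()}

    n_dup_targets = len(targets) - len(set(targets))
    if n_dup_targets:
        logger.info("de-duplicated %d repeated drug-target symbols", n_dup_targets)
    n_dup_markers = len(markers) - len(set(markers))
    if n_dup_markers:
        logger.info("de-duplicated %d repeated biomarker symbols", n_dup_markers)

    union = set(targets) | set(markers)
    kept = {s for s in union if flags.get(s, False)}
    dropped = union - kept
    if dropped:
        logger.info("dropped %d genes without reviewed records", len(dropped))
    if not kept:
        raise ValueError("no positive genes after the reviewed-record filter")
    return {GeneRecord(symbol=s, label=1, reviewed=True) for s in kept}


def build_negative_pool(
    human_gene_table: pd.DataFrame,
    all_positives: Iterable[str],
    min_size: int = 1,
) -> set[str]:
    """Human gene pool minus the positives of *all* cancer types.

    Removing positives across every cancer type (not just the one being
    assembled) guarantees that no sampled non-target is a known target
    anywhere in the study.
    """
    if human_gene_table is None or len(human_gene_table) == 0:
        raise ValueError("human_gene_table must be non-empty")
    if "gene_symbol" not in human_gene_table.columns:
        raise ValueError("human_gene_table must have a gene_symbol column")
    pool = {normalize_symbol(s) for s in human_gene_table["gene_symbol"].astype(str)}
    positives = {normalize_symbol(s) for s in all_positives}
    remaining = pool - positives
    if len(remaining) < min_size:
        raise ValueError(
            f"insufficient negative pool: {len(remaining)} genes remain, "
            f"need at least {min_size}"
        )
    return remaining


def sample_negatives(
    pool: Iterable[str],
    k: int,
    seed: int,
    already_used: Optional[Iterable[str]] = None,
) -> set[GeneRecord]:
    """Draw ``k`` non-target genes uniformly without replacement.

    ``already_used`` accumulates the negatives of previously assembled
    cancer types so that negative sets stay pairwise disjoint across
    cancers.  Sampling is deterministic given (pool, k, seed, already_used):
    the candidate list is sorted before drawing.
    """
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    used = {normalize_symbol(s) for s in (already_used or ())}
    candidates = sorted({normalize_symbol(s) for s in pool} - used)
    if len(candidates) < k:
        raise ValueError(
            f"cannot sample {k} negatives: only {len(candidates)} unused genes "
            f"remain in the pool (short by {k - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return {GeneRecord(symbol=candidates[i], label=0) for i in chosen}


def assemble_dataset(
    cancer_type: str,
    positives: Iterable[GeneRecord],
    negatives: Iterable[GeneRecord],
) -> CancerDataset:
    """Combine one cancer's positive and negative records into a dataset.

    Balance, disjointness and per-class uniqueness are enforced by the
    ``CancerDataset`` constructor.
    """
    return CancerDataset(
        cancer_type=cancer_type,
        positives=sorted(positives, key=lambda r: r.symbol),
        negatives=sorted(negatives, key=lambda r: r.symbol),
    )


def attach_sequences(
    records: Iterable[GeneRecord],
    sequences: Mapping[str, str],
    protein_ids: Optional[Mapping[str, str]] = None,
) -> tuple[list[GeneRecord], list[str]]:
    """Join records with their amino-acid sequences; report drops.

    Genes with no sequence in the FASTA are dropped (with a logged
    warning) rather than carried forward with an empty feature source.
    Returns (kept records, dropped symbols).
    """
    seqs = {normalize_symbol(k): v for k, v in sequences.items()}
    pids = {normalize_symbol(k): v for k, v in (protein_ids or {}).items()}
    kept: list[GeneRecord] = []
    dropped: list[str] = []
    for rec in records:
        seq = seqs.get(rec.symbol)
        if seq is None:
            dropped.append(rec.symbol)
            continue
        kept.append(
            GeneRecord(
                symbol=rec.symbol,
                label=rec.label,
                protein_id=pids.get(rec.symbol, rec.protein_id),
                sequence=seq,
                reviewed=rec.reviewed,
            )
        )
    if dropped:
        logger.warning(
            "dropped %d genes with no sequence in the FASTA: %s%s",
            len(dropped),
            ", ".join(sorted(dropped)[:5]),
            "..." if len(dropped) > 5 else "",
        )
    return kept, dropped


def derive_cancer_seed(master_seed: int, cancer_type: str) -> int:
    """Per-cancer seed: master seed offset by a stable hash of the name.

    crc32 is stable across processes and platforms (unlike ``hash``), so
    re-running assembly with the same master seed reproduces every draw.
    """
    return int((master_seed + zlib.crc32(cancer_type.encode())) % (2**31))


def assemble_all(
    per_cancer_inputs: Mapping[str, Mapping],
    human_gene_table: pd.DataFrame,
    sequences: Optional[Mapping[str, str]] = None,
    master_seed: int = 0,
) -> dict[str, CancerDataset]:
    """Assemble balanced datasets for several cancer types at once.

    ``per_cancer_inputs`` maps cancer type to a dict with keys
    ``dti_table`` (DataFrame), ``biomarker_genes`` (list of symbols) and
    ``reviewed_flags`` (symbol -> bool).  Cancers are processed in
    alphabetical order and an accumulator of used negatives is threaded
    through so negative sets are pairwise disjoint.  When ``sequences``
    is given, genes without a sequence are dropped before negatives are
    sampled and the pool is restricted to genes with sequences, so the
    class balance survives the join.
    """
    positive_sets: dict[str, set[GeneRecord]] = {}
    for cancer in sorted(per_cancer_inputs):
        inputs = per_cancer_inputs[cancer]
        positive_sets[cancer] = build_positive_set(
            inputs["dti_table"], inputs["biomarker_genes"], inputs["reviewed_flags"]
        )

    all_positive_symbols = {
        r.symbol for recs in positive_sets.values() for r in recs
    }
    largest = max(len(s) for s in positive_sets.values())
    pool = build_negative_pool(human_gene_table, all_positive_symbols, min_size=largest)

    seq_map = (
        {normalize_symbol(k): v for k, v in sequences.items()}
        if sequences is not None
        else None
    )
    if seq_map is not None:
        pool = {s for s in pool if s in seq_map}

    datasets: dict[str, CancerDataset] = {}
    already_used: set[str] = set()
    for cancer in sorted(positive_sets):
        positives = positive_sets[cancer]
        if seq_map is not None:
            kept, _ = attach_sequences(positives, seq_map)
            positives = set(kept)
            if not positives:
                raise ValueError(f"no positive genes with sequences for {cancer}")
        seed = derive_cancer_seed(master_seed, cancer)
        negatives = sample_negatives(pool, len(positives), seed, already_used)
        if seq_map is not None:
            negatives = set(attach_sequences(negatives, seq_map)[0])
        already_used |= {r.symbol for r in negatives}
        datasets[cancer] = assemble_dataset(cancer, positives, negatives)
    return datasets


def dataset_counts(datasets: Mapping[str, CancerDataset]) -> dict:
    """Per-cancer and global-unique gene counts for a multi-cancer assembly."""
    per_cancer = {
        c: {"positives": len(d.positives), "negatives": len(d.negatives), "all": len(d)}
        for c, d in datasets.items()
    }
    all_symbols = {s for d in datasets.values() for s in d.symbols}
    return {
        "per_cancer": per_cancer,
        "sum_over_cancers": sum(len(d) for d in datasets.values()),
        "global_unique": len(all_symbols),
    }


def write_dataset(dataset: CancerDataset, path: Path | str) -> None:
    """Write one dataset as a TSV (symbol, protein_id, label, sequence)."""
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in dataset.records],
            "protein_id": [r.protein_id or "" for r in dataset.records],
            "label": [r.label for r in dataset.records],
            "sequence": [r.sequence or "" for r in dataset.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: Path | str, cancer_type: str) -> CancerDataset:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = [
        GeneRecord(
            symbol=row["symbol"],
            label=int(row["label"]),
            protein_id=row["protein_id"] or None,
            sequence=row["sequence"] or None,
        )
        for _, row in df.iterrows()
    ]
    return CancerDataset(
        cancer_type=cancer_type,
        positives=[r for r in records if r.label == 1],
        negatives=[r for r in records if r.label == 0],
    )


def write_manifest(
    datasets: Mapping[str, CancerDataset], master_seed: int, path: Path | str
) -> None:
    manifest = {
        "master_seed": master_seed,
        "per_cancer_seeds": {
            c: derive_cancer_seed(master_seed, c) for c in sorted(datasets)
        },
        "counts": dataset_counts(datasets),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
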