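"""Per-gene feature construction: sequence embeddings, omics summaries, integration.

Three feature blocks are produced for each gene:

* ``embedding`` — a 1024-dimensional vector summarizing the protein's
  amino-acid sequence (from a protein language model backend, or the
  deterministic hash-seeded backend for offline work);
* ``omics`` — five features: the maximum, mean, median and minimum of the
  gene's expression across patient samples, plus the count of patient
  samples in which the gene is mutated;
* ``integrated`` — the row-wise concatenation, embeddings first,
  1024 + 5 = 1029 columns.

All features are min-max scaled to [0, 1] per column; the scaler is fit on
training rows only and re-applied (with clipping) to held-out rows to avoid
information leaking from test to train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .embedding import EmbeddingBackend
from .records import EXTENDED_AMINO_ACIDS

logger = logging.getLogger(__name__)

# Declared width of each named block; custom names may use any width.
BLOCK_DIMENSIONS = {"embedding": 1024, "omics": 5, "integrated": 1029}

OMICS_FEATURE_NAMES = (
    "expr_max",
    "expr_mean",
    "expr_median",
    "expr_min",
    "mutation_count",
)


@dataclass
class FeatureBlock:
    """A named genes × features matrix with row order tied to ``genes``."""

    name: str
    genes: Sequence[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got {self.matrix.ndim}-D")
        if self.matrix.shape[0] != len(self.genes):
            raise ValueError(
                f"{self.matrix.shape[0]} rows but {len(self.genes)} genes"
            )
        expected = BLOCK_DIMENSIONS.get(self.name)
        if expected is not None and self.matrix.shape[1] != expected:
            raise ValueError(
                f"block {self.name!r} must have {expected} columns, "
                f"got {self.matrix.shape[1]}"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]


def embed_sequences(
    sequences: Sequence[tuple[str, str]],
    backend: EmbeddingBackend,
) -> FeatureBlock:
    """Embed (symbol, sequence) pairs into a genes × dimension block.

    Sequences longer than the backend's token budget are truncated with a
    warning; a residue outside the accepted amino-acid alphabet raises with
    the offending position.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to embed")
    rows = []
    genes = []
    for symbol, seq in sequences:
        seq = seq.upper()
        for pos, ch in enumerate(seq):
            if ch not in EXTENDED_AMINO_ACIDS:
                raise ValueError(
                    f"invalid character {ch!r} at position {pos} in sequence of {symbol}"
                )
        if len(seq) > backend.max_tokens:
            logger.warning(
                "sequence of %s has %d residues; truncated to %d",
                symbol,
                len(seq),
                backend.max_tokens,
            )
            seq = seq[: backend.max_tokens]
        vec = np.asarray(backend.embed(seq), dtype=np.float64)
        if vec.shape != (backend.dimension,):
            raise ValueError(
                f"backend {backend.name} returned shape {vec.shape}, "
                f"expected ({backend.dimension},)"
            )
        rows.append(vec)
        genes.append(symbol)
    name = "embedding" if backend.dimension == BLOCK_DIMENSIONS["embedding"] else "embedding_custom"
    return FeatureBlock(name=name, genes=genes, matrix=np.vstack(rows))


def aggregate_expression(values: Iterable[float]) -> tuple[float, float, float, float]:
    """Summarize one gene's expression across patient samples.

    Returns ``(max, mean, median, min)``.  The median of an even-length
    list is the midpoint of the two central order statistics.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no expression samples for gene")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite expression value")
    return (
        float(np.max(arr)),
        float(np.mean(arr)),
        float(np.median(arr)),
        float(np.min(arr)),
    )


def count_mutations(maf_records: pd.DataFrame, gene: str) -> int:
    """Number of patient samples in which ``gene`` carries a mutation.

    ``maf_records`` is a MAF-like table with columns ``gene_symbol``,
    ``sample_id`` and ``mutated_flag``; a gene absent from the table has
    count 0.
    """
    if len(maf_records) == 0:
        return 0
    sub = maf_records[maf_records["gene_symbol"].astype(str).str.upper() == gene.upper()]
    if len(sub) == 0:
        return 0
    flags = sub["mutated_flag"]
    if flags.dtype == bool:
        return int(flags.sum())
    return int(
        flags.astype(str).str.strip().str.upper().isin({"TRUE", "T", "1"}).sum()
    )


def build_omics_block(
    genes: Sequence[str],
    expression: pd.DataFrame,
    maf_records: pd.DataFrame,
) -> FeatureBlock:
    """Assemble the 5-column omics block for ``genes``.

    ``expression`` is a gene × sample matrix (index = gene symbols, one
    column per patient sample).  A gene with no expression row gets zeros
    for the four expression summaries (logged); a gene absent from the MAF
    gets mutation count 0.
    """
    expr_index = {str(g).upper(): i for i, g in enumerate(expression.index)}
    rows = np.zeros((len(genes), 5), dtype=np.float64)
    missing = []
    for i, gene in enumerate(genes):
        key = gene.upper()
        if key in expr_index:
            vals = expression.iloc[expr_index[key]].to_numpy(dtype=np.float64)
            rows[i, :4] = aggregate_expression(vals)
        else:
            missing.append(gene)
        rows[i, 4] = count_mutations(maf_records, gene)
    if missing:
        logger.warning(
            "%d genes have no expression rows; their expression features are 0: %s%s",
            len(missing),
            ", ".join(missing[:5]),
            "..." if len(missing) > 5 else "",
        )
    return FeatureBlock(name="omics", genes=list(genes), matrix=rows)


@dataclass
class FittedMinMaxScaler:
    """Per-column min-max transform fitted on a chosen subset of rows."""

    data_min: np.ndarray
    data_range: np.ndarray  # zero range replaced by 1 so constants map to 0

    def transform(self, matrix: np.ndarray, clip: bool = True) -> np.ndarray:
        out = (np.asarray(matrix, dtype=np.float64) - self.data_min) / self.data_range
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=np.float64) * self.data_range + self.data_min


def minmax_normalize(
    block: FeatureBlock,
    fit_rows: Optional[Sequence[int]] = None,
) -> tuple[FeatureBlock, FittedMinMaxScaler]:
    """Scale each column to [0, 1] using min/max computed over ``fit_rows``.

    Rows outside ``fit_rows`` may fall outside [0, 1] after the affine map
    and are clipped.  Constant columns map to 0.  Default ``fit_rows`` is
    all rows.
    """
    if fit_rows is None:
        fit_rows = range(block.n_genes)
    fit_rows = list(fit_rows)
    if len(fit_rows) == 0:
        raise ValueError("fit_rows must be non-empty")
    if not np.all(np.isfinite(block.matrix)):
        bad = np.where(~np.isfinite(block.matrix).all(axis=0))[0]
        raise ValueError(f"non-finite input in feature column(s) {bad.tolist()}")
    sk = MinMaxScaler(clip=False)
    sk.fit(block.matrix[fit_rows])
    rng_ = sk.data_max_ - sk.data_min_
    scaler = FittedMinMaxScaler(
        data_min=sk.data_min_.copy(),
        data_range=np.where(rng_ == 0, 1.0, rng_),
    )
    normalized = FeatureBlock(
        name=block.name, genes=list(block.genes), matrix=scaler.transform(block.matrix)
    )
    return normalized, scaler


def integrate_features(
    embedding_block: FeatureBlock, omics_block: FeatureBlock
) -> FeatureBlock:
    """Concatenate embedding and omics blocks row-wise, embeddings first.

    Gene order must match exactly; a mismatch raises instead of silently
    reordering.
    """
    if list(embedding_block.genes) != list(omics_block.genes):
        raise ValueError("gene order differs between embedding and omics blocks")
    matrix = np.hstack([embedding_block.matrix, omics_block.matrix])
    name = (
        "integrated"
        if matrix.shape[1] == BLOCK_DIMENSIONS["integrated"]
        else "integrated_custom"
    )
    return FeatureBlock(name=name, genes=list(embedding_block.genes), matrix=matrix)


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene × sample expression matrix: first column gene symbol, rest samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_maf_tsv(path) -> pd.DataFrame:
    """MAF-like table: gene_symbol, sample_id, mutated_flag (TRUE/FALSE)."""
    return pd.read_csv(path, sep="\t", dtype={"gene_symbol": str, "sample_id": str})


def write_feature_block(block: FeatureBlock, path) -> None:
    df = pd.DataFrame(block.matrix, index=pd.Index(block.genes, name="gene"))
    df.to_csv(path, sep="\t")


def read_feature_block(path, name: str) -> FeatureBlock:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureBlock(name=name, genes=[str(g) for g in df.index], matrix=df.to_numpy())
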