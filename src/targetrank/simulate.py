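"""Synthetic data with controllable class structure.

Every stage of the pipeline is testable offline against data whose ground
truth is known.  The generator emulates:

* protein sequences — uniform random strings over the 20-letter amino-acid
  alphabet (no homology or motif structure);
* sequence embeddings — class-conditional spherical Gaussians in embedding
  space whose means are ``embedding_separation`` apart (identity
  covariance, so that distance is also the Mahalanobis distance);
* expression — log-normal draws per patient sample, with a multiplicative
  upward shift for target genes, keeping values non-negative as in real
  expression data;
* mutations — per-sample mutation events at a class-dependent rate, so a
  gene's mutation count is Poisson with mean rate × n_patient_samples.

For the Gaussian embedding model the optimal linear score w = μ₁ − μ₀ has
a closed-form AUC of Φ(δ/√2): the score difference between an independent
positive and negative is N(δ², 2δ²).  This gives an end-to-end check of
the feature → AUC path against a formula.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import norm

from .features import FeatureBlock, integrate_features
from .records import AMINO_ACIDS

_ALPHABET = sorted(AMINO_ACIDS)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``embedding_separation`` is the Euclidean (= Mahalanobis, identity
    covariance) distance δ between the class means in embedding space;
    ``omics_effect`` is the additive shift of the log-expression location
    for target genes (a multiplicative shift on the expression scale);
    ``mutation_rates`` are per-sample mutation probabilities for targets
    and non-targets.
    """

    n_pos: int = 100
    n_neg: int = 100
    seq_length_range: tuple[int, int] = (80, 300)
    embedding_separation: float = 6.0
    omics_effect: float = 1.0
    mutation_rates: tuple[float, float] = (0.3, 0.1)
    n_patient_samples: int = 20
    embedding_dim: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be >= 1")
        if self.seq_length_range[1] < self.seq_length_range[0]:
            raise ValueError(
                f"max sequence length {self.seq_length_range[1]} < min "
                f"{self.seq_length_range[0]}"
            )
        if self.embedding_separation < 0:
            raise ValueError("embedding_separation must be >= 0")
        if self.n_patient_samples < 1:
            raise ValueError("n_patient_samples must be >= 1")


def optimal_linear_auc(delta: float) -> float:
    """Closed-form AUC of the optimal linear score at class separation δ."""
    return float(norm.cdf(delta / np.sqrt(2.0)))


def simulate_sequences(config: SimConfig) -> list[SeqRecord]:
    """Random amino-acid sequences, one per gene, ids SYN0001, SYN0002, ...

    Positives come first (matching ``simulate_labeled_features`` order).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_length_range
    records = []
    for i in range(config.n_pos + config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_ALPHABET, size=length))
        records.append(
            SeqRecord(Seq(seq), id=f"SYN{i + 1:04d}", description="synthetic protein")
        )
    return records


def write_fasta(records, path: Path | str) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path: Path | str) -> dict[str, str]:
    """Gene symbol -> amino-acid string (record id is the symbol)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def embedding_class_means(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """True class means of the embedding cloud for a given configuration.

    The separation direction is drawn from a dedicated child stream of the
    config seed, so the same config always yields the same class geometry
    across `simulate_labeled_features` and `simulate_pu_pool`.
    """
    rng = np.random.default_rng([config.seed, 17])
    direction = rng.standard_normal(config.embedding_dim)
    direction /= np.linalg.norm(direction)
    delta = config.embedding_separation
    return (delta / 2.0) * direction, (-delta / 2.0) * direction


def _embedding_cloud(config: SimConfig, rng: np.random.Generator):
    mu_pos, mu_neg = embedding_class_means(config)
    pos = rng.standard_normal((config.n_pos, config.embedding_dim)) + mu_pos
    neg = rng.standard_normal((config.n_neg, config.embedding_dim)) + mu_neg
    return pos, neg


def _omics_rows(
    rng: np.random.Generator, n: int, config: SimConfig, positive: bool
) -> np.ndarray:
    """Expression aggregates (max, mean, median, min) + mutation count."""
    shift = config.omics_effect if positive else 0.0
    rate = config.mutation_rates[0] if positive else config.mutation_rates[1]
    expr = np.exp(
        rng.normal(1.0 + shift, 0.5, size=(n, config.n_patient_samples))
    )
    rows = np.column_stack(
        [
            expr.max(axis=1),
            expr.mean(axis=1),
            np.median(expr, axis=1),
            expr.min(axis=1),
            rng.poisson(rate * config.n_patient_samples, size=n).astype(float),
        ]
    )
    return rows


def simulate_labeled_features(config: SimConfig) -> tuple[FeatureBlock, np.ndarray]:
    """Integrated feature block (embeddings ‖ omics) with known labels.

    Positives occupy the first ``n_pos`` rows (label 1), negatives the
    rest (label 0).  Gene symbols follow the SYNxxxx convention of
    :func:`simulate_sequences`.
    """
    rng = np.random.default_rng(config.seed)
    pos_emb, neg_emb = _embedding_cloud(config, rng)
    pos_om = _omics_rows(rng, config.n_pos, config, positive=True)
    neg_om = _omics_rows(rng, config.n_neg, config, positive=False)
    n = config.n_pos + config.n_neg
    genes = [f"SYN{i + 1:04d}" for i in range(n)]
    emb_name = "embedding" if config.embedding_dim == 1024 else "embedding_custom"
    embedding = FeatureBlock(
        name=emb_name, genes=genes, matrix=np.vstack([pos_emb, neg_emb])
    )
    omics = FeatureBlock(name="omics", genes=genes, matrix=np.vstack([pos_om, neg_om]))
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    return integrate_features(embedding, omics), labels


def simulate_pu_pool(
    config: SimConfig, n_unlabeled: int, n_planted: int
) -> tuple[FeatureBlock, set[int]]:
    """An unlabeled gene pool with ``n_planted`` hidden positives.

    Rows are negative-class draws except for a seeded random subset of
    ``n_planted`` rows replaced by positive-class draws; the planted row
    indices are returned for evaluation only.
    """
    if n_planted > n_unlabeled:
        raise ValueError(
            f"n_planted ({n_planted}) exceeds n_unlabeled ({n_unlabeled})"
        )
    if n_unlabeled < 1:
        raise ValueError("n_unlabeled must be >= 1")
    rng = np.random.default_rng(config.seed)
    mu_pos, mu_neg = embedding_class_means(config)
    emb = rng.standard_normal((n_unlabeled, config.embedding_dim)) + mu_neg
    om = _omics_rows(rng, n_unlabeled, config, positive=False)
    planted = set(
        rng.choice(n_unlabeled, size=n_planted, replace=False).tolist()
    ) if n_planted else set()
    if planted:
        idx = sorted(planted)
        emb[idx] = rng.standard_normal((len(idx), config.embedding_dim)) + mu_pos
        om[idx] = _omics_rows(rng, len(idx), config, positive=True)
    genes = [f"UNL{i + 1:04d}" for i in range(n_unlabeled)]
    emb_name = "embedding" if config.embedding_dim == 1024 else "embedding_custom"
    block = integrate_features(
        FeatureBlock(name=emb_name, genes=genes, matrix=emb),
        FeatureBlock(name="omics", genes=genes, matrix=om),
    )
    return block, planted


def write_fixture_tree(config: SimConfig, out_dir: Path | str) -> dict[str, Path]:
    """Emit the full curated-input file set the pipeline consumes.

    Produces a drug-target interaction CSV, a biomarker gene list, a human
    gene pool table, a FASTA of protein sequences, a gene × sample
    expression TSV and a MAF-like mutation TSV — the exact formats the
    assembly and feature readers parse — so the whole chain runs
    end-to-end with no external data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_extra = 3 * config.n_neg  # pool margin beyond the labeled genes
    n_total = config.n_pos + config.n_neg + n_extra
    symbols = [f"SYN{i + 1:04d}" for i in range(n_total)]
    positives = symbols[: config.n_pos]

    # sequences for every pool gene
    lo, hi = config.seq_length_range
    fasta_path = out_dir / "sequences.fasta"
    records = []
    for s in symbols:
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SeqRecord(
                Seq("".join(rng.choice(_ALPHABET, size=length))),
                id=s,
                description="synthetic protein",
            )
        )
    write_fasta(records, fasta_path)

    # approved drug-target interactions over roughly half the positives
    n_dti = max(1, config.n_pos // 2)
    dti_path = out_dir / "dti.csv"
    with open(dti_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_id", "gene_symbol"])
        for i, s in enumerate(positives[:n_dti]):
            writer.writerow([f"DB{i % 7:05d}", s])

    # overexpressed biomarkers cover the rest, with some overlap
    biomarkers = positives[max(0, n_dti - 2):]
    (out_dir / "biomarkers.csv").write_text(
        "gene_symbol\n" + "\n".join(biomarkers) + "\n"
    )

    pool_path = out_dir / "gene_pool.csv"
    with open(pool_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_symbol", "protein_name", "reviewed"])
        for s in symbols:
            writer.writerow([s, f"{s} protein", "TRUE"])

    # expression matrix with the class shift applied to positive genes
    sample_ids = [f"PT{j + 1:03d}" for j in range(config.n_patient_samples)]
    expr_path = out_dir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene\t" + "\t".join(sample_ids) + "\n")
        for s in symbols:
            shift = config.omics_effect if s in set(positives) else 0.0
            vals = np.exp(rng.normal(1.0 + shift, 0.5, size=config.n_patient_samples))
            fh.write(s + "\t" + "\t".join(f"{v:.6g}" for v in vals) + "\n")

    # MAF-like mutation records, one row per (gene, sample)
    maf_path = out_dir / "mutations.tsv"
    with open(maf_path, "w") as fh:
        fh.write("gene_symbol\tsample_id\tmutated_flag\n")
        for s in symbols:
            rate = (
                config.mutation_rates[0]
                if s in set(positives)
                else config.mutation_rates[1]
            )
            for pt in sample_ids:
                flag = "TRUE" if rng.random() < rate else "FALSE"
                fh.write(f"{s}\t{pt}\t{flag}\n")

    return {
        "dti": dti_path,
        "biomarkers": out_dir / "biomarkers.csv",
        "gene_pool": pool_path,
        "fasta": fasta_path,
        "expression": expr_path,
        "maf": maf_path,
    }
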