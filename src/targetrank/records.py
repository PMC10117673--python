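"""Domain records: genes with labels, and balanced per-cancer datasets.

Target identification is cast as binary classification over genes: a gene
is a *target* (label 1) if an approved drug interacts with its protein or
it is an overexpressed cancer biomarker, and a *non-target* (label 0)
otherwise.  Each cancer type gets its own balanced dataset so that the two
classes carry equal weight during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

# 20 canonical amino acids plus the ambiguity/rare codes accepted in
# curated protein sequences.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_AMINO_ACIDS = AMINO_ACIDS | set("XUBZ")

CANCER_TYPES = (
    "bladder",
    "breast",
    "colon",
    "kidney",
    "leukemia",
    "liver",
    "lung",
    "non_hodgkin_lymphoma",
    "rectal",
    "thyroid",
)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: uppercase, surrounding whitespace stripped.

    Gene symbols arrive in mixed case across curated sources; every set
    operation in this package works on the canonical form.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One gene: symbol, optional protein accession and sequence, binary label."""

    symbol: str
    label: int
    protein_id: Optional[str] = None
    sequence: Optional[str] = None
    reviewed: bool = True

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("gene symbol must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.sequence is not None:
            if len(self.sequence) < 1:
                raise ValueError(f"empty sequence for gene {self.symbol}")
            bad = set(self.sequence.upper()) - EXTENDED_AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"invalid residues {sorted(bad)} in sequence of {self.symbol}"
                )


@dataclass
class CancerDataset:
    """A balanced labeled gene collection for one cancer type.

    Invariants enforced on construction: equal class sizes, disjoint
    symbol sets, and unique symbols within each class.
    """

    cancer_type: str
    positives: Sequence[GeneRecord] = field(default_factory=tuple)
    negatives: Sequence[GeneRecord] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.positives = tuple(self.positives)
        self.negatives = tuple(self.negatives)
        pos_symbols = [r.symbol for r in self.positives]
        neg_symbols = [r.symbol for r in self.negatives]
        if len(set(pos_symbols)) != len(pos_symbols):
            raise ValueError("duplicate symbols in positive set")
        if len(set(neg_symbols)) != len(neg_symbols):
            raise ValueError("duplicate symbols in negative set")
        if any(r.label != 1 for r in self.positives):
            raise ValueError("positive set contains a record with label != 1")
        if any(r.label != 0 for r in self.negatives):
            raise ValueError("negative set contains a record with label != 0")
        overlap = set(pos_symbols) & set(neg_symbols)
        if overlap:
            raise ValueError(
                f"positive/negative overlap for {self.cancer_type}: {sorted(overlap)[:5]}"
            )
        if len(self.positives) != len(self.negatives):
            raise ValueError(
                f"unbalanced dataset for {self.cancer_type}: "
                f"{len(self.positives)} positives vs {len(self.negatives)} negatives"
            )

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return self.positives + self.negatives

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.records)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(r.label for r in self.records)
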