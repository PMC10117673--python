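"""Protein-sequence embedding backends.

A backend turns one amino-acid sequence into a fixed-length vector.  The
reference representation is the mean over token positions of the last
hidden state of a pretrained protein language model (1024 dimensions for
the ProtTrans-family BERT models); any backend honoring the small protocol
below can stand in.  Two offline backends ship with the package:

* :class:`HashSeededEmbedder` — a deterministic pseudo-embedding whose
  vector is drawn from a generator seeded by a stable hash of the sequence
  itself.  It carries no biology but is reproducible, collision-free in
  practice, and lets every downstream stage run with no model weights.
* :class:`PrecomputedEmbeddings` — serves vectors from a gene × dimension
  matrix computed once by an external model and cached as TSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

DEFAULT_DIMENSION = 1024
# Token budget mirroring the longer of the two training lengths used by the
# reference protein language model.
DEFAULT_MAX_TOKENS = 2000


@runtime_checkable
class EmbeddingBackend(Protocol):
    name: str
    dimension: int
    max_tokens: int

    def embed(self, sequence: str) -> np.ndarray:
        """Deterministically map one sequence to a (dimension,) vector."""
        ...


def sequence_hash_seed(sequence: str) -> int:
    """Stable 64-bit seed derived from the sequence content.

    blake2b is used rather than ``hash()`` so the seed survives across
    processes and Python versions.
    """
    digest = hashlib.blake2b(sequence.encode("ascii"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


@dataclass
class HashSeededEmbedder:
    """Deterministic hash-seeded Gaussian pseudo-embeddings.

    ``embed(s)`` seeds a fresh generator with a 64-bit hash of ``s`` and
    draws ``dimension`` standard-normal values, so identical sequences give
    identical vectors and distinct sequences give (almost surely) distinct
    ones.
    """

    name: str = "hash-seeded"
    dimension: int = DEFAULT_DIMENSION
    max_tokens: int = DEFAULT_MAX_TOKENS

    def embed(self, sequence: str) -> np.ndarray:
        rng = np.random.default_rng(sequence_hash_seed(sequence))
        return rng.standard_normal(self.dimension)


@dataclass
class PrecomputedEmbeddings:
    """Embedding vectors computed externally and cached per gene symbol.

    The table maps gene symbol -> vector; ``embed`` is keyed on the symbol
    recorded at construction time for each sequence, so the same cache
    serves any sequence set whose symbols it covers.
    """

    table: Mapping[str, np.ndarray]
    name: str = "precomputed"
    max_tokens: int = DEFAULT_MAX_TOKENS
    dimension: int = field(init=False)
    _by_sequence: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError("empty embedding cache")
        dims = {np.asarray(v).shape for v in self.table.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent cached vector shapes: {dims}")
        self.dimension = next(iter(dims))[0]

    def register(self, symbol: str, sequence: str) -> None:
        if symbol not in self.table:
            raise KeyError(f"no cached embedding for gene {symbol}")
        self._by_sequence[sequence[: self.max_tokens]] = symbol

    def embed(self, sequence: str) -> np.ndarray:
        symbol = self._by_sequence.get(sequence)
        if symbol is None:
            raise KeyError("sequence was not registered with a gene symbol")
        return np.asarray(self.table[symbol], dtype=np.float64)
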