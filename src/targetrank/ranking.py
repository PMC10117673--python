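"""Nominating novel targets: rank unlabeled genes by prediction probability.

After retraining the best configuration on the full labeled dataset
(100 epochs), the model scores a pool of unlabeled genes.  Genes predicted
positive (score >= 0.5) are sorted by descending probability; score ties
break alphabetically by gene symbol so repeated runs agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .features import FeatureBlock
from .models import TrainedModel

POSITIVE_THRESHOLD = 0.5
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class RankedCandidate:
    symbol: str
    score: float
    rank: int


def rank_candidates(
    model: TrainedModel,
    unlabeled_features: FeatureBlock,
    top_k: int = DEFAULT_TOP_K,
    threshold: float = POSITIVE_THRESHOLD,
) -> list[RankedCandidate]:
    """Top-k unlabeled genes predicted positive, by descending score.

    Only genes with score >= ``threshold`` qualify; fewer than ``top_k``
    may therefore be returned.  Ranks are consecutive from 1.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    scores = model.predict_scores(unlabeled_features)
    qualifying = [
        (symbol, float(score))
        for symbol, score in zip(unlabeled_features.genes, scores)
        if score >= threshold
    ]
    qualifying.sort(key=lambda item: (-item[1], item[0]))
    return [
        RankedCandidate(symbol=s, score=sc, rank=i + 1)
        for i, (s, sc) in enumerate(qualifying[:top_k])
    ]


def write_candidates(candidates: Sequence[RankedCandidate], path: Path | str) -> None:
    """TSV output: gene, score at 4 decimals, rank."""
    lines = ["gene\tscore\trank"]
    lines += [f"{c.symbol}\t{c.score:.4f}\t{c.rank}" for c in candidates]
    Path(path).write_text("\n".join(lines) + "\n")
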