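"""Evaluation protocols: ROC/AUC, stratified k-fold CV, the disjoint-negative
comparison protocol, and Y-randomization.

AUC is computed in its Mann-Whitney form — the probability that a random
positive outscores a random negative, ties counted half — via midranks.
This is identical to the trapezoidal area under the ROC curve swept over
all thresholds, and O(n log n) instead of O(n²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureBlock, minmax_normalize
from .models import ClassifierConfig, TrainedModel, train

ArrayLike = Union[np.ndarray, Sequence[float]]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def fpr(self) -> float:
        """False positive rate FP / (TN + FP)."""
        denom = self.TN + self.FP
        return self.FP / denom if denom else float("nan")

    @property
    def tpr(self) -> float:
        """True positive rate (recall) TP / (TP + FN)."""
        denom = self.TP + self.FN
        return self.TP / denom if denom else float("nan")


@dataclass
class EvalResult:
    per_unit_auc: list[float]
    protocol: str  # "kfold" or "disjoint_negative"
    seeds: list[int]
    confusions: list[ConfusionCounts] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_unit_auc))


@dataclass
class YRandResult:
    original_r2: float
    permuted_r2: list[float]

    @property
    def p_value(self) -> float:
        """Empirical permutation p-value, (1 + #{perm >= original}) / (1 + N)."""
        exceed = sum(1 for r in self.permuted_r2 if r >= self.original_r2)
        return (1 + exceed) / (1 + len(self.permuted_r2))


def confusion_counts(labels: ArrayLike, scores: ArrayLike, threshold: float = 0.5) -> ConfusionCounts:
    """Hard-threshold confusion counts; score >= threshold predicts 1."""
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} labels vs {s.shape[0]} scores")
    pred = (s >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def roc_auc(labels: ArrayLike, scores: ArrayLike) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    Equals the probability that a uniformly chosen positive outscores a
    uniformly chosen negative, with tied scores counted 1/2 — and therefore
    the trapezoidal area under the (FPR, TPR) curve over all thresholds.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("labels and scores have different lengths")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # midranks for ties
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def r_squared(y_true: ArrayLike, y_pred: ArrayLike) -> float:
    """Coefficient of determination; negative when worse than the mean."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.asarray(y_pred, dtype=np.float64).ravel()
    ss_res = float(np.sum((y - p) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: constant true labels")
    return 1.0 - ss_res / ss_tot


def _fold_seed(base_seed: int, index: int) -> int:
    # independent, reproducible per-fold streams, kept below 2**31
    return int((base_seed * 1_000_003 + index) % (2**31))


def _as_matrix(features: Union[FeatureBlock, np.ndarray]) -> np.ndarray:
    return features.matrix if isinstance(features, FeatureBlock) else np.asarray(features, dtype=np.float64)


def _fit_eval_split(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ClassifierConfig,
    normalize: bool,
) -> tuple[np.ndarray, TrainedModel]:
    """Normalize on the training rows only, train, and score the test rows."""
    if normalize:
        block = FeatureBlock(name="working", genes=[str(i) for i in range(len(X))], matrix=X)
        normalized, _ = minmax_normalize(block, fit_rows=list(train_idx))
        Xn = normalized.matrix
    else:
        Xn = X
    fitted = train(Xn[train_idx], y[train_idx], config)
    return fitted.predict_scores(Xn[test_idx]), fitted


def stratified_kfold_cv(
    features: Union[FeatureBlock, np.ndarray],
    labels: ArrayLike,
    config: Optional[ClassifierConfig] = None,
    k: int = 10,
    seed: int = 0,
    normalize: bool = False,
    threshold: float = 0.5,
) -> EvalResult:
    """Stratified k-fold cross-validation reporting per-fold and mean AUC.

    Each fold preserves the class proportions (within one sample); every
    sample is tested exactly once.  The feature scaler and the classifier
    are re-fit inside every fold on the training rows only, with a
    fold-index-derived seed so folds are reproducible yet independent.
    """
    config = config or ClassifierConfig()
    X = _as_matrix(features)
    y = np.asarray(labels).ravel().astype(int)
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold stratified CV; "
            f"class sizes are {class_sizes.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs: list[float] = []
    seeds: list[int] = []
    confusions: list[ConfusionCounts] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_seed = _fold_seed(seed, fold)
        scores, _ = _fit_eval_split(
            X, y, train_idx, test_idx, config.with_seed(fold_seed), normalize
        )
        aucs.append(roc_auc(y[test_idx], scores))
        confusions.append(confusion_counts(y[test_idx], scores, threshold))
        seeds.append(fold_seed)
    return EvalResult(per_unit_auc=aucs, protocol="kfold", seeds=seeds, confusions=confusions)


def disjoint_negative_protocol(
    positive_features: FeatureBlock,
    negative_sets: Sequence[FeatureBlock],
    config: Optional[ClassifierConfig] = None,
    split: float = 0.7,
    seed: int = 0,
    normalize: bool = False,
) -> EvalResult:
    """Ten-repetition protocol with one positive set and disjoint negative sets.

    Each repetition combines the positives with one negative set of equal
    size, shuffles, splits 70/30 stratified, trains on the 70% and reports
    the test AUC; the mean over repetitions summarizes the run.
    """
    config = config or ClassifierConfig()
    n_pos = positive_features.n_genes
    seen: set[str] = set()
    for i, block in enumerate(negative_sets):
        if block.n_genes != n_pos:
            raise ValueError(
                f"negative set {i} has {block.n_genes} genes; expected {n_pos}"
            )
        overlap = seen & set(block.genes)
        if overlap:
            raise ValueError(
                f"negative sets are not disjoint: {sorted(overlap)[:5]} reused"
            )
        seen |= set(block.genes)
    aucs: list[float] = []
    seeds: list[int] = []
    confusions: list[ConfusionCounts] = []
    for i, block in enumerate(negative_sets):
        rep_seed = _fold_seed(seed, i)
        X = np.vstack([positive_features.matrix, block.matrix])
        y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, train_size=split, stratify=y, random_state=rep_seed, shuffle=True
        )
        scores, _ = _fit_eval_split(
            X, y, train_idx, test_idx, config.with_seed(rep_seed), normalize
        )
        aucs.append(roc_auc(y[test_idx], scores))
        confusions.append(confusion_counts(y[test_idx], scores))
        seeds.append(rep_seed)
    return EvalResult(
        per_unit_auc=aucs, protocol="disjoint_negative", seeds=seeds, confusions=confusions
    )


def y_randomization(
    features: Union[FeatureBlock, np.ndarray],
    labels: ArrayLike,
    config: Optional[ClassifierConfig] = None,
    n_perm: int = 100,
    seed: int = 0,
    split: float = 0.7,
    normalize: bool = False,
) -> YRandResult:
    """Label-scrambling validation of a fitted model.

    The original R² scores the model trained on true labels against the
    true labels of a stratified 70/30 held-out set.  Each of the ``n_perm``
    permutations scrambles the full label vector (features fixed) and runs
    the *identical* procedure — stratified split on the scrambled labels,
    train, R² on the scrambled held-out labels — so that under a true null
    the original statistic is exchangeable with the permuted ones and the
    p-value is exact.  A model that learned real structure beats (almost)
    every permutation; permuted fits typically give low or negative R².
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or ClassifierConfig()
    X = _as_matrix(features)
    y = np.asarray(labels).ravel().astype(int)

    def _evaluate(y_vec: np.ndarray, model_seed: int) -> float:
        idx = np.arange(len(y_vec))
        train_idx, test_idx = train_test_split(
            idx, train_size=split, stratify=y_vec, random_state=seed, shuffle=True
        )
        if y_vec[train_idx].min() == y_vec[train_idx].max():
            return float("-inf")  # degenerate shuffle on tiny data
        scores, _ = _fit_eval_split(
            X, y_vec, train_idx, test_idx, config.with_seed(model_seed), normalize
        )
        try:
            return r_squared(y_vec[test_idx], scores)
        except ValueError:  # constant held-out labels after an extreme shuffle
            return float("-inf")

    original_r2 = _evaluate(y, config.seed)
    rng = np.random.default_rng(seed)
    permuted = [
        _evaluate(y[rng.permutation(len(y))], _fold_seed(seed, i + 1))
        for i in range(n_perm)
    ]
    return YRandResult(original_r2=original_r2, permuted_r2=permuted)
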