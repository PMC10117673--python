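# targetrank

Cancer-specific therapeutic-target prioritization from protein-sequence
embeddings and aggregated omics features.

Late-stage oncology drug failures are frequently failures of target
selection. `targetrank` is for computational biologists who want to
triage candidate targets before committing experimental effort: it casts
target identification as balanced binary classification over genes —
label 1 for genes with an approved drug interaction or overexpressed
biomarker status, label 0 for genes sampled from the remaining human
protein-coding pool — and then ranks unlabeled genes by predicted target
probability (a positive–unlabeled setup, since "negatives" may hide true
targets).

Each gene *i* is a feature vector **x**ᵢ ∈ ℝ¹⁰²⁹: a 1024-dimensional
protein language-model embedding of its amino-acid sequence concatenated
with five omics summaries (max/mean/median/min expression over patient
samples, plus a mutation count), min-max scaled to [0, 1]. The classifier
is a compact dense network

    x → dense(64, tanh) → dense(32, tanh) → dense(1, sigmoid)

trained with binary cross-entropy + L2 on the hidden layers, Nadam at
learning rate 0.01, batch size 16, 30 epochs (100 for the full-data
retraining that precedes ranking), with random-forest, gradient-boosting
and SVM baselines behind the same contract. Evaluation uses the
Mann–Whitney (midrank) AUC — P(score of a random target > score of a
random non-target) — under stratified 10-fold cross-validation, a
ten-repetition disjoint-negative-set protocol with 70/30 stratified
splits, and a Y-randomization (label-scrambling) permutation test.
Everything is seeded and bit-reproducible; a synthetic-data module
generates all input formats with controllable class separation so the
entire pipeline runs offline.

## Worked example

Cross-validate the dense network on synthetic integrated features whose
classes are separated by δ = 6 in embedding space
(`examples/03_crossvalidate.py`):

```python
from targetrank import (ClassifierConfig, SimConfig,
                        simulate_labeled_features, stratified_kfold_cv)

config = SimConfig(n_pos=100, n_neg=100, embedding_dim=64,
                   embedding_separation=6.0, seed=3)
block, labels = simulate_labeled_features(config)
result = stratified_kfold_cv(block, labels, ClassifierConfig(seed=3), k=10, seed=3)
print(result.mean_auc)
```

Running the full script (which also fits the random-forest baseline)
prints

```
dnn            mean AUC = 1.000   folds: 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00
random_forest  mean AUC = 1.000   folds: 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00 1.00
```

— at this separation the classes are essentially perfectly separable
(the optimal linear score alone attains AUC Φ(6/√2) ≈ 1), so a mean fold
AUC of 1.000 means the model recovered the planted signal; 0.5 would be
chance. The label-scrambling check (`examples/04_y_randomization.py`)
confirms the association is real rather than capacity artifact:

```
original R^2: 0.962
permuted R^2: max 0.235, median -0.479, 97% negative
empirical p-value: 0.0099  (< 0.05 -> association is real)
```

and ranking a 100-gene unlabeled pool with 10 hidden positives
(`examples/05_rank_novel_targets.py`) recovers 9 of them in the top 10
(random expectation 1). The other examples walk through dataset assembly
from curated tables and feature-block construction.

A thin CLI mirrors the same flow
(`targetrank simulate|assemble|featurize|train|evaluate|yrand|rank`);
run any subcommand with `--help`.

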