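# Methods

## Problem and model

`targetrank` frames cancer-specific therapeutic-target identification as
balanced binary classification over genes. For one cancer type, the
positive class contains genes with an approved drug interaction or
significantly overexpressed biomarker status; the negative class is an
equal-size random sample of other human protein-coding genes. A classifier
trained on per-gene feature vectors then scores unlabeled genes, and the
highest-scoring ones are nominated as candidate targets. Because the
"negatives" are merely unlabeled (they may hide true targets), the ranking
step is a positive–unlabeled (PU) problem: the model is trained as if
unlabeled meant negative, and its top-ranked "negatives" are the
candidates of interest.

## Dataset assembly

Positives are the union of the unique approved drug–target genes and the
biomarker genes, restricted to genes with reviewed (curated) protein
records. Symbols are uppercased and stripped before any set operation so
mixed-case inputs cannot create phantom duplicates. The negative pool is
the human gene table minus the positives of *all* cancer types, so no
sampled non-target is a known target anywhere in the study. Negatives are
drawn uniformly without replacement; an `already_used` accumulator is
threaded through the cancer types in alphabetical order so negative sets
are pairwise disjoint across cancers. Per-cancer seeds are
`master_seed + crc32(cancer_name) mod 2^31`, giving independent,
platform-stable streams.

Genes with no sequence in the FASTA are unusable downstream. Positives are
filtered for sequence availability *before* negatives are sampled, and the
pool is restricted to genes with sequences, so the balance invariant
|positives| = |negatives| survives the join (re-sampling after a failed
join would couple the draw to the FASTA contents).

## Features

Each gene gets three blocks:

* **embedding** (1024 columns) — a fixed-length summary of the protein's
  amino-acid sequence. The reference representation is the mean over token
  positions of the last hidden state of a large pretrained protein
  language model; mean pooling is the conventional per-protein reduction
  for that model family, which publishes per-residue states only.
  Backends are pluggable behind a three-field protocol (name, dimension,
  max_tokens). Two offline backends ship: `PrecomputedEmbeddings` serves a
  cached gene × 1024 matrix computed once by an external model, and
  `HashSeededEmbedder` draws a standard-normal vector from a generator
  seeded by a 64-bit blake2b hash of the sequence. The hash-seeded vectors
  are deterministic and collision-free in practice but carry **no
  biology**: two homologous sequences are as far apart as two unrelated
  ones. Sequences longer than 2000 residues (the longer of the two
  training lengths of the reference model) are truncated with a warning.
* **omics** (5 columns) — maximum, mean, median and minimum expression of
  the gene across patient samples, plus the count of samples in which the
  gene is mutated. The median of an even-length sample is the midpoint of
  the two central order statistics. A gene absent from the expression
  matrix gets zeros for the four summaries (logged); a gene absent from
  the mutation table has count 0.
* **integrated** (1029 columns) — row-wise concatenation, embeddings
  first. Gene order must match exactly between blocks; a mismatch raises
  rather than silently reordering.

Min-max scaling maps each column to [0, 1] using the minimum and maximum
of a caller-chosen subset of rows. The pipeline fits the scaler on
training rows only and transforms held-out rows with clipping to [0, 1],
so no information flows from test to train; constant columns map to 0.
The evaluation protocols themselves take features as given and rescale
only when asked (`normalize=True`), keeping the fold/train/AUC logic
independent of the feature pipeline.

## Classifier

The primary model is a compact dense network implemented directly on
NumPy: input → dense(64, tanh) → dense(32, tanh) → dense(1, sigmoid),
binary cross-entropy loss with L2 penalties (default 1e-3) on the hidden
layers' weights and biases, weights initialized from N(0, 0.05²), biases
zero, trained with Nadam (Adam with Nesterov lookahead) at learning rate
0.01, batch size 16, 30 epochs. All stochastic pieces — initialization and
the per-epoch shuffle — come from one seeded generator, so training is
bit-reproducible and saved models reload to identical scores. For the
full-data retraining that precedes candidate ranking, 100 epochs are used.
Random-forest, gradient-boosting and SVM baselines (library defaults,
seeded) expose the same `fit`/`predict_scores` contract so every
evaluation protocol is classifier-agnostic. Where a hard label is needed
(confusion counts, the candidate cut) the threshold is 0.5.

## Evaluation

**AUC** is computed in its Mann–Whitney form via midranks: the probability
that a random positive outscores a random negative, ties counted half.
This equals the trapezoidal area under the ROC curve swept over all
thresholds and costs O(n log n); tests verify equality with an O(n²)
pairwise oracle (and an independent library implementation) to 1e-12,
including heavily tied scores.

**Stratified 10-fold CV** preserves class proportions within one sample
per fold; each sample is tested exactly once; models are re-initialized
per fold with fold-index-derived seeds so folds are reproducible yet
independent. The mean of the per-fold AUCs is the summary statistic.

**Disjoint-negative protocol**: ten repetitions, each combining the fixed
positive set with one of ten pairwise-disjoint equal-size negative sets,
shuffled, split 70/30 stratified, trained on the 70% and scored on the
30%; the per-repetition test AUCs are averaged.

**Y-randomization** validates that performance is not a capacity artifact:
the model is trained on true labels and scored by R² on a stratified 70/30
held-out set, then the full label vector is scrambled n_perm times (100 by
default) with features fixed and the *identical* procedure re-run —
including a fresh stratified split on the scrambled labels. Re-splitting
per permutation matters: with a split fixed on the true labels, permuted
test sets are unbalanced, their label variance (the R² denominator)
shrinks, and the permutation p-value becomes anticonservative under the
null. With re-splitting the original statistic is exchangeable with the
permuted ones, and the reported p-value,
(1 + #{permuted R² ≥ original R²}) / (1 + n_perm), is exact under that
exchangeability. Scrambled-label fits typically produce low or negative
R² (worse than predicting the class mean).

## Candidate ranking

After full-data retraining, unlabeled genes with score ≥ 0.5 are sorted by
descending probability, ties broken alphabetically by symbol, and the top
k (default 10) reported with ranks 1..k. The output is a pure function of
(model, features, k); repeated runs agree exactly.

## Synthetic generator

The generator produces every input format the pipeline consumes, with
known ground truth:

* sequences — uniform random strings over the 20-letter amino-acid
  alphabet, lengths uniform in a configurable range;
* embeddings — class-conditional spherical Gaussians in embedding space
  with identity covariance and means `embedding_separation` (δ) apart, the
  direction drawn from a dedicated child stream of the seed so one config
  defines one geometry;
* expression — log-normal per patient sample
  (exp N(1 + omics_effect·label, 0.5)), keeping values non-negative as in
  real expression data; the four aggregates are computed from these draws;
* mutations — per-sample events at class-dependent rates, so a gene's
  count is Poisson with mean rate × n_patient_samples.

Defaults (100 genes/class, δ = 6, omics_effect = 1, mutation rates
0.3/0.1 per sample, 20 patient samples) describe a clearly separable
study condition. For the Gaussian embedding model the optimal linear
score w = μ₁ − μ₀ has closed-form AUC Φ(δ/√2) — the score difference
between an independent positive and negative is N(δ², 2δ²) — which the
suite uses as an end-to-end limit check of the feature → AUC path
(δ = 2, 2000 draws per class, tolerance 0.01 ≈ 2 Monte-Carlo standard
errors).

The generator deliberately omits sequence homology, motif structure,
expression batch effects and realistic mutation spectra, and its
embeddings carry no biology. Passing tests therefore demonstrate that the
machinery — assembly invariants, feature plumbing, optimization,
protocol arithmetic, ranking — is correct and calibrated, not that the
feature sources are informative for real cancer genes.

## Numerical choices and test scales

Sigmoid evaluation is split by sign to avoid overflow; predicted
probabilities are clipped to [1e-12, 1 − 1e-12] inside the loss. Fold and
permutation seeds are derived as `base·1_000_003 + index mod 2^31`.
Protocol tests run at reduced scale chosen for sub-minute feedback:
32-dimensional embedding blocks, 60 genes per class, and 5–10 training
epochs for the permutation suites; the signal-recovery check runs the full
1029-column geometry at 200 genes per class.

## Known limitations

* With inputs min-max scaled to [0, 1], every input coordinate is
  non-negative, so the per-batch gradients of all weights in one
  first-layer column share a sign. Nadam's per-parameter normalized steps
  then move whole columns coherently at ~lr per step; at learning rate
  0.01 this drift can saturate the tanh hidden layers within an epoch on
  high-dimensional, weakly-informative inputs, freezing the network at
  near-constant output. On such data, train on the unscaled features, or
  lower the learning rate (0.001 is in the supported grid). The raw
  Gaussian benchmark geometry, being zero-centered, is unaffected.
* The hash-seeded embedding backend is a determinism and plumbing tool;
  conclusions about real sequence information require the external
  language-model backend via the embedding cache.
* The candidate cut at 0.5 is a convention; calibrated probabilities are
  not guaranteed, so ranks are more meaningful than absolute scores.
* The Y-randomization R² is computed on scores against binary labels; it
  is a goodness-of-fit heuristic in that setting, which is why the
  decision quantity is the exact permutation p-value rather than R²
  itself.
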