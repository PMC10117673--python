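"""Nominate novel therapeutic targets from an unlabeled gene pool.

Retrains the dense network on the full labeled dataset at 100 epochs, then
scores an unlabeled pool in which 10 of 100 genes are hidden positives.
Genes predicted positive (score >= 0.5) are ranked by probability; the
printed table mirrors the (gene, score, rank) candidate report.
"""

from targetrank import (
    ClassifierConfig,
    SimConfig,
    rank_candidates,
    simulate_labeled_features,
    simulate_pu_pool,
    train,
)

config = SimConfig(n_pos=60, n_neg=60, embedding_dim=32, seed=13)
block, labels = simulate_labeled_features(config)
model = train(block, labels, ClassifierConfig(epochs=100, seed=13))

pool, planted = simulate_pu_pool(config, n_unlabeled=100, n_planted=10)
candidates = rank_candidates(model, pool, top_k=10)

index_of = {g: i for i, g in enumerate(pool.genes)}
print("rank  gene      score   hidden positive?")
for c in candidates:
    hit = "yes" if index_of[c.symbol] in planted else ""
    print(f"{c.rank:>4}  {c.symbol:8s}  {c.score:.4f}  {hit}")
hits = sum(1 for c in candidates if index_of[c.symbol] in planted)
print(f"precision@{len(candidates)}: {hits}/{len(candidates)} "
      f"(random expectation {10/100:.2f})")
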