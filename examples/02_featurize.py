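"""Build the three per-gene feature blocks: embeddings, omics, integrated.

Each gene gets a 1024-dimensional sequence embedding (here from the
deterministic hash-seeded backend), five omics summaries (max/mean/median/
min expression over patient samples plus a mutation count), and their
1029-column concatenation, min-max scaled to [0, 1].
"""

import tempfile
from pathlib import Path

from targetrank import (
    HashSeededEmbedder,
    SimConfig,
    build_omics_block,
    embed_sequences,
    integrate_features,
    minmax_normalize,
    simulate_sequences,
    write_fixture_tree,
)
from targetrank.features import read_expression_tsv, read_maf_tsv
from targetrank.simulate import read_fasta_sequences

workdir = Path(tempfile.mkdtemp())
paths = write_fixture_tree(SimConfig(n_pos=8, n_neg=8, seed=2), workdir)

sequences = read_fasta_sequences(paths["fasta"])
genes = sorted(sequences)[:10]

embedding = embed_sequences([(g, sequences[g]) for g in genes], HashSeededEmbedder())
omics = build_omics_block(genes, read_expression_tsv(paths["expression"]),
                          read_maf_tsv(paths["maf"]))
integrated = integrate_features(embedding, omics)
scaled, scaler = minmax_normalize(integrated)

print(f"embedding block: {embedding.matrix.shape}")   # genes x 1024
print(f"omics block:     {omics.matrix.shape}")       # genes x 5
print(f"integrated:      {integrated.matrix.shape}")  # genes x 1029
print(f"scaled range:    [{scaled.matrix.min():.1f}, {scaled.matrix.max():.1f}]")
print("omics row (max, mean, median, min, mutations):",
      [round(float(v), 2) for v in omics.matrix[0]])
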