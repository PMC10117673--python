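"""Assemble a balanced target/non-target gene dataset from curated tables.

Generates a synthetic input tree (drug-target interactions, overexpressed
biomarkers, a human gene pool, protein FASTA), then builds the positive set
(union of approved-drug targets and biomarkers, reviewed genes only) and
samples an equal number of non-targets from the pool.
"""

import tempfile
from pathlib import Path

import pandas as pd

from targetrank import SimConfig, assemble_all, dataset_counts, write_fixture_tree
from targetrank.simulate import read_fasta_sequences

workdir = Path(tempfile.mkdtemp())
paths = write_fixture_tree(SimConfig(n_pos=20, n_neg=20, seed=1), workdir)

pool = pd.read_csv(paths["gene_pool"])
per_cancer = {
    "lung": {
        "dti_table": pd.read_csv(paths["dti"]),
        "biomarker_genes": pd.read_csv(paths["biomarkers"])["gene_symbol"].tolist(),
        "reviewed_flags": {s: True for s in pool["gene_symbol"]},
    }
}
datasets = assemble_all(
    per_cancer, pool, sequences=read_fasta_sequences(paths["fasta"]), master_seed=1
)

lung = datasets["lung"]
print(f"lung dataset: {len(lung.positives)} targets + {len(lung.negatives)} non-targets "
      f"= {len(lung)} genes")
print("counts:", dataset_counts(datasets))
# The positive and negative sets are equal in size (balanced classes) and
# share no gene symbol; every record carries a protein sequence.
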