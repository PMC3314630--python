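"""Bipartition-consensus species tree with BioNJ.

Simulates gene trees perturbed from a known species tree, extracts the
>=70%-support bipartitions, encodes them as a 0/1 matrix, computes
p-distances and builds the consensus tree with BioNJ; the result is scored
by Robinson-Foulds distance against the generating species tree.
"""

from gobiseq.phylo_consensus import (
    consensus_pipeline,
    parse_newick_support,
    robinson_foulds,
)
from gobiseq.synthetic_data import SimConfig, simulate_gene_trees

cfg = SimConfig(seed=23, n_taxa=10, n_gene_trees=20, split_noise=0.1)
newicks, species, _ = simulate_gene_trees(cfg)

consensus = consensus_pipeline(newicks, min_support=70)
rf_consensus = robinson_foulds(consensus, species)
rf_inputs = sorted(
    robinson_foulds(parse_newick_support(t), species) for t in newicks
)

print("consensus tree:", consensus.as_string(schema="newick",
                                             suppress_rooting=True).strip())
print(f"RF(consensus, species tree) = {rf_consensus}")
print(f"gene-tree RF distances: min {rf_inputs[0]}, "
      f"median {rf_inputs[len(rf_inputs) // 2]}, max {rf_inputs[-1]}")
print()
print(
    "Low-support (perturbed) splits fall below the 70% threshold, so the\n"
    "consensus is at least as close to the species tree as the median\n"
    "noisy gene tree; with 10% split noise it typically recovers it exactly."
)
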