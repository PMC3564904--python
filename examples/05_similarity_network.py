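"""Permutation-calibrated similarity network, compared across individuals.

Edges join clone pairs whose distance is significantly smaller than the
per-locus genotype-shuffling null (pooled across pairs, BH-corrected).
Two simulated littermates with the same commitment schedule are compared
for conserved tissue-level relationships.
"""

import fatemap as fm
from fatemap.network import tissue_level_edges

nets = []
for label, seed in [("mouse A", 1), ("mouse B", 2)]:
    matrix = fm.simulate_lineage(fm.SimulationConfig(seed=seed)).matrix
    net = fm.build_similarity_network(matrix, alpha=0.05, n_permutations=200, seed=seed)
    nets.append(net)
    print(f"{label}: {net.number_of_edges()} significant clone-pair edges, "
          f"{len(tissue_level_edges(net))} tissue-level relationships")

conserved = fm.compare_networks(nets[0], nets[1])
print(f"conserved tissue-level relationships: {len(conserved)}")
for e in sorted(conserved, key=str):
    print("  ", " <-> ".join("/".join(k) for k in sorted(e)))
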