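"""Genetic distance, tissue summaries and the molecular clock.

Computes the per-locus-normalised minimal-pairing distance among simulated
clones, summarises it by tissue (intra-/inter-tissue, to-zygote, left-right
means), and converts distances into mitotic separations with the clock
D = mu x divisions.
"""

import fatemap as fm

sim = fm.simulate_lineage(fm.SimulationConfig(seed=1))
matrix = sim.matrix

dm = fm.distance_matrix(matrix)
zygote = fm.consensus_genotype(matrix)
zd = fm.distance_to_reference(matrix, zygote)

summary = fm.tissue_distance_summary(dm, matrix.meta, zd)
cols = ["tissue", "side", "intra_mean", "inter_mean", "zygote_mean", "left_right_mean"]
print(summary.table[cols].round(3).to_string(index=False))

clock = fm.ClockModel(mu=0.011)
print(f"\nglobal mean distance {summary.global_mean:.3f} "
      f"~ {fm.divisions_from_distance(summary.global_mean, clock):.1f} divisions")
print(f"15 divisions at rate 0.013 -> distance "
      f"{fm.distance_from_divisions(15, fm.ClockModel(0.013)):.3f}")
print(f"lineage histories for 8 cells: {fm.count_lineage_histories(8):,}")

# Distances to the zygote are roughly half the clone-to-clone distances:
# two clones accumulate mutations along both branches from their common
# ancestor, while the zygote comparison spans a single branch.
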