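"""Simulate a developing individual and inspect its mutation profile.

Builds a branching lineage of ~100 single-cell clones from six tissue/side
pools (110 polyG loci, mutation rate 0.011 per locus per division, 40
divisions from the zygote), then summarises how mutated the sampled cells
are relative to the inferred zygote genotype.
"""

import fatemap as fm

sim = fm.simulate_lineage(fm.SimulationConfig(seed=1))
matrix = sim.matrix

zygote = fm.consensus_genotype(matrix)
summary = fm.identify_somatic_mutations(matrix, zygote)

print(f"clones: {matrix.n_clones}, loci: {matrix.n_loci}")
print(f"mean mutant alleles / locus / cell: "
      f"{summary.mean_mutant_alleles_per_locus_per_cell:.3f}")
print(f"mean fraction of mutated markers per cell: "
      f"{summary.mean_fraction_mutated:.3f}")
print(f"analytic event-level expectation 1-(1-mu)^40 = "
      f"{1 - (1 - 0.011) ** 40:.3f}")

# The simulated fraction sits a little below the event-level expectation:
# +1/-1 slippage events on the same allele can cancel, and missing calls
# hide some mutations, exactly as in real fragment-analysis data.
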