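# fatemap

Phylogenetic fate mapping from polyguanine somatic-mutation genotypes.

During development, every cell division leaves a faint genetic record:
mutation-prone polyguanine (polyG) microsatellites slip by one repeat unit
at a roughly constant per-division rate. Genotyping ~110 such loci in
single-cell clones expanded from dissected tissues makes it possible to
reconstruct, retrospectively, how a body was built — which tissues share
progenitor pools, how many mitoses separate a cell from the zygote, when
left/right compartments formed, and how symmetric the underlying lineage
tree is. `fatemap` implements that analysis chain for researchers working
with fragment-analysis genotypes of clonally expanded single cells (or with
simulated data): genotype calling, diploid genetic distance, clonal-complex
clustering, similarity networks, molecular-clock conversion and
tree-imbalance statistics, plus a branching lineage simulator that provides
ground truth for every stage.

## The model

Cells divide from the zygote; at each division each polyG locus mutates
with probability μ (per locus per division, both alleles combined),
changing one allele's length by ±1 bp. Genotypes are diploid allele-length
pairs, e.g. `106/103`, with `X` for an ambiguous call.

* **Genotype calling** — with I₁H ≥ I₂H ≥ I₃H the top peak intensities of a
  replicate: homozygote when |I₂H − I₃H| ≤ 10⁴ U, heterozygote when the gap
  is exceeded and I₂H > 0.8·I₁H, otherwise — or on any disagreement among
  the three PCR replicates — ambiguous.
* **Genetic distance** — per locus, the smaller of the two ways of pairing
  the four alleles (summed |Δlength|); loci with more than one missing
  allele in the pair are excluded; the total is divided by the number of
  usable loci. Under the molecular clock, D = μ · (divisions separating
  the pair).
* **Clonal complexes (modified eBURST)** — connected components of the
  graph linking pairs with D ≤ 0.2 (≈15 divisions at μ = 0.013); the
  founder is the member linked to the most others.
* **Similarity network** — edges join pairs whose distance is significantly
  smaller than a per-locus genotype-shuffling null (pooled across pairs,
  Benjamini–Hochberg corrected).
* **Tree shape** — N̄ (mean internal nodes from tip to root, root counted;
  4.0 for the balanced 16-tip tree, (n−1)(n+2)/2n for caterpillars) and the
  Colless index Σ|L−R|, compared between observed-genotype trees and trees
  rebuilt from randomized genotypes.
* **Combinatorics** — n cells admit (2n−3)!/(2ⁿ⁻²(n−2)!) rooted lineage
  histories: 15 for n=4, 135,135 for n=8, >10¹⁵ for n=16.

## Worked example

```python
import fatemap as fm

sim = fm.simulate_lineage(fm.SimulationConfig(seed=1))   # ~100 clones, 110 loci
zygote = fm.consensus_genotype(sim.matrix)
summary = fm.identify_somatic_mutations(sim.matrix, zygote)
print(summary.mean_fraction_mutated)                     # 0.317
dm = fm.distance_matrix(sim.matrix)
result = fm.build_clonal_complexes(dm, fm.EburstConfig(0.2, fm.ClockModel(0.013)))
print(len(result.complexes), len(result.singletons))     # 4 92
```

Running `python examples/01_simulate_lineage.py` prints:

```
clones: 100, loci: 110
mean mutant alleles / locus / cell: 0.339
mean fraction of mutated markers per cell: 0.317
analytic event-level expectation 1-(1-mu)^40 = 0.358
```

About a third of a clone's markers carry a visible mutation after 40
divisions at μ = 0.011 — slightly below the event-level expectation because
opposite ±1 slippage events on the same allele cancel and missing calls
hide some mutations. `examples/` contains one short script per capability
(simulation, genotype calling, distance + clock, eBURST complexes,
similarity networks, tree imbalance); each prints the numbers it computes
and a line on what they mean. The same stages are available from the shell
via the `fatemap` CLI (`fatemap simulate`, `fatemap distance`,
`fatemap eburst`, `fatemap network`, `fatemap treeshape`,
`fatemap run-all`).

## Layout

```
src/fatemap/     genotypes, simulate, calling, distance, eburst,
                 network, treeshape, pipeline, cli
examples/        one narrative script per capability
tests/           pytest suite (unit, property and end-to-end checks)
docs/methods.md  model, parameter and design notes
```
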