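# Methods notes

This note records the models, conventions and numerical choices behind
`fatemap`, in the order data flows through the package.

## Mutation model and simulator

Cells divide synchronously from the zygote for `n_generations` (default
40, the rough number of mitoses between fertilisation and birth in mouse).
Each polyG locus mutates with probability `mu` per division (default
0.011, inside the experimentally reported 0.010–0.013 range), the event
hits one of the two alleles uniformly and shifts its length by a step
drawn from `step_probabilities` (default ±1 bp with equal probability —
the single-repeat-unit slippage that dominates mononucleotide tracts; the
real step spectrum is not characterised, so multi-step models remain a
configuration choice rather than a default).

Tissue commitment follows a pool model: at a commitment generation, a set
of cells alive at that generation is marked as the progenitor pool of one
tissue/side, and all descendants inherit the label. Default schedule: six
pools emulating the study design — muscle fibroblasts and fat
preadipocytes (left and right) from pools of 25 committed at generation 7,
brain vascular endothelium (left and right) from pools of 5 committed at
generation 13. This mirrors the biological picture of an early large mixed
mesodermal pool versus a later, smaller endothelial source. Sixteen cells
per pool are sampled at the final generation (~96 clones), plus
`split_clone_pairs` (default 4) duplicated terminal cells that model
split-clone culture controls; duplicates are genotypically identical
before missing-data masking. Each allele call is masked to `X`
independently with `missing_rate` (default 0.05 — the order of magnitude
seen in fragment-analysis panels; not a reported quantity).

Because only ~100 of 2⁴⁰ cells are observed, the simulator materialises
just the genealogy of the sample: each sampled cell is a leaf of the
synchronous binary pedigree addressed by a 40-bit path, shared ancestry is
the shared bit-prefix, and mutations are drawn per branch as
Binomial(divisions, mu) per locus. This is exact for the model and O(sample
size), not O(population).

**What the simulator does not model:** cell death and asynchronous
division (all divergences therefore sit at the depth implied by a complete
synchronous pedigree, which makes simulated clone pairs coalesce deeper —
and distances larger — than the published tissue means), ex-vivo culture
mutations beyond what `missing_rate`/split pairs capture, locus-specific
rates, and spatial structure. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under the stated model,
not the biological realism of any particular distance value.

## Genotype calling

The caller reproduces the published decision rule per replicate
(intensities I₁H ≥ I₂H ≥ I₃H, thresholds `intensity_gap` = 10⁴ U and
`het_ratio` = 0.8) and requires all three replicates to agree; profiles
with fewer than three peaks are padded with zero-intensity sentinels. The
original description leaves open whether an additional dominance condition
on I₁H applied; none is imposed here. On disagreement the call is
ambiguous; if the top-intensity allele itself is consistent it is retained
(`106/X`), otherwise the call is `X/X`.

Parental assignment takes the two most frequent allele lengths per locus
as founders (the minimisation objective is stated in the source method but
not its algorithm; the modal choice is the natural frequency heuristic)
and orients each diploid call to minimise total absolute deviation from
the founders. Consensus (zygote/tissue) genotypes are per-slot modal
alleles; all modal ties break to the smaller length for determinism.

## Genetic distance

Per locus, the contribution is the smaller of the two allele pairings
(summed |Δlength| in bp). Loci with more than one missing allele in the
pair are excluded; with exactly one missing allele the known allele is
compared against the closer of the counterpart's two alleles (uses the
available information, consistent with the "minimal difference" principle;
exposed as the package's dialect since the original sub-rule is not
public). The sum is divided by the per-pair count of usable loci, so
distances remain comparable under missing data. The result is a symmetric
premetric: d(a,a)=0 and d≥0 hold, but the per-pair normalisation can
violate the triangle inequality. Pairs with no usable loci are undefined
(NaN) and treated as unlinked downstream. Zygote distances are computed
against the all-clone consensus genotype.

Tissue summaries average pair-level distances (intra-tissue, inter-tissue,
to-zygote, left-to-right), with SEMs over the contributing pair values —
the pair, not the clone, is the unit, since the underlying quantity is a
pair property. The accompanying Student t-test against the global mean
reproduces the published table convention, but note that pair distances
sharing clones are dependent, so those p-values are descriptive. For
actual inference the package provides
`intra_vs_inter_permutation_test`, which refers the Welch t statistic to
its distribution under random relabelling of clones into groups; under
exchangeability this p-value is uniform by construction (verified in the
tests over 200 randomized replicates).

## Molecular clock and the cancellation deficit

`D = mu × divisions` converts per-locus distances into mitotic
separations. Two caveats, both consequences of ±1 stepwise slippage:

1. **Same-allele cancellation.** The visible length change of one allele
   after d divisions is |random walk| with Binomial(d, mu/2) steps, which
   is below mu·d once multiple hits become likely. The expectation is
   computable in closed form (`_expected_visible_changes`), and the
   mutation-rate estimator uses its method-of-moments inversion by default:
   the raw ratio of visible changes to locus-divisions (`rate_raw`, the
   simple published-style estimator) underestimates mu by about one
   standard error already at 20 doublings, while the corrected estimator
   recovers the simulated rate within 3 SE in ≈99% of replicates.
2. **Cross-genotype cancellation.** Between two mutated genotypes the
   minimal allele pairing can additionally cancel changes at loci where
   the zygote was homozygous (slots are interchangeable), so mean distance
   falls increasingly below mu×separation as separation grows (measured
   ≈5% at s≈40, ≈20%+ at s≈80). Distances are therefore a lower bound on
   mu×s; division estimates of deeply separated pairs are conservative.

## Clonal complexes and networks

Grouping is single linkage (connected components of the thresholded
graph), matching classical eBURST semantics; the founder is the member
with the most within-threshold links, ties broken by smallest mean
distance to members and then clone id, for determinism. The default
threshold 0.2 equals the published cut-off (≈15 divisions at mu=0.013).
Undefined distances never link.

Network edges require the pair distance to be significantly small under
the randomization null that shuffles each locus's genotype calls across
clones (preserving every locus's allele multiset). Null distances are
pooled across pairs — exchangeable once every locus is shuffled — because
per-pair permutation p-values are bounded below by 1/(n_permutations+1)
and could never pass Benjamini–Hochberg across thousands of pairs.
Defaults: alpha 0.05, 200 permutations. Cross-individual comparison
intersects edges at the (tissue, side) level, the resolution at which two
individuals share vocabulary.

## Tree shape

N̄ counts internal nodes from tip to root, root included
(Kirkpatrick–Slatkin convention), validated against both printed reference
values (4.0 on the balanced 16-tip tree, 7.43 on the 14-tip caterpillar)
and the closed forms k on 2^k tips and (n−1)(n+2)/2n on caterpillars. N̄
handles multifurcations directly; Colless requires a binary tree and
either rejects polytomies or resolves them randomly with a seed.
Normalised Colless divides by the caterpillar maximum (n−1)(n−2)/2.

External Bayesian inference is delegated: `recode_for_phylogenetics` maps
alleles to 0–9 digits per locus per parental slot (frequency-ranked, modal
allele = 0, rarest merged into 9, missing = `?` — one character per slot
keeps the diploid information) and writes a standard-datatype NEXUS with
the analysis settings recorded in a command block; tree samples are read
back with dendropy. For self-contained runs `build_distance_tree` provides
a deterministic UPGMA tree, and `shape_null_comparison` contrasts observed
trees with trees rebuilt from randomized genotypes (shift in mean plus a
one-sided rank p that the observed tree is the more symmetric). A
structured lineage yields a negative N̄ shift; randomized input shows none.

## Problem sizes and determinism

Every stochastic operation takes a seed (NumPy `default_rng`); the
pipeline derives per-stage seeds from one master seed via `SeedSequence`
and records seed, configuration and a configuration hash in its manifest,
so outputs are bit-reproducible. Tests run the full-size study design
(110 loci, ~100 clones) where a single realisation suffices and scale down
to 40–60 loci and 30–50 clones for replicated calibration checks (200
null replicates, 100 recovery replicates), keeping the suite in the
minutes range while leaving expectations unchanged.

## Known limitations

- The distance premetric is not a metric; tree building on it is
  heuristic (UPGMA assumes ultrametricity that real data only approximate).
- The clock inverts distances linearly and thus inherits the cancellation
  deficit described above.
- The in-vitro rate correction assumes single-unit steps; for configured
  multi-step spectra only `rate_raw` is meaningful.
- Consensus genotypes approximate the zygote only while the modal allele
  is ancestral — very high mutation rates or strong shared drift would
  break this.
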