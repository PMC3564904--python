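"""Branching cell-lineage simulator with polyG mutation accumulation.

Cells divide synchronously from the zygote.  At a configurable generation
each tissue commits: a pool of cells alive at that generation is marked as
the tissue's progenitors (with a body side), and all of its descendants
inherit the label.  At the final generation a fixed number of cells per
tissue is sampled and genotyped, optionally with split-clone duplicates
(internal reproducibility controls) and missing calls.

Mutations follow a per-locus per-division Bernoulli clock: with
probability ``mu`` the locus mutates in a given division, one of the two
alleles is picked uniformly, and the allele length changes by a step drawn
from ``step_probabilities`` (default +/-1 bp).  Because the simulator only
needs genotypes of sampled cells, it materialises the genealogy of the
sample (shared ancestry via binary division paths) rather than all 2^40
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TissueCommitment:
    """One tissue/side pool committed at a given generation."""

    tissue: str
    side: str
    generation: int
    pool_size: int


def default_commitment_schedule() -> list[TissueCommitment]:
    """Six pools: muscle fibroblasts and preadipocytes from a large mixed
    mesodermal pool committed early, brain vascular endothelium from a small
    pool committed later; each with left and right compartments."""
    sched = []
    for tissue, gen, pool in [
        ("fibroblast", 7, 25),
        ("preadipocyte", 7, 25),
        ("endothelial", 13, 5),
    ]:
        for side in ("L", "R"):
            sched.append(TissueCommitment(tissue, side, gen, pool))
    return sched


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated individual.

    Defaults emulate the source study's conditions: ~110 polyG loci,
    mutation rate ~0.011 per locus per division, ~40 divisions from the
    zygote, ~16 clones sampled from each of six tissue/side pools.
    """

    n_loci: int = 110
    mu: float = 0.011
    step_probabilities: dict[int, float] = field(
        default_factory=lambda: {-1: 0.5, 1: 0.5}
    )
    n_generations: int = 40
    commitment_schedule: list[TissueCommitment] = field(
        default_factory=default_commitment_schedule
    )
    cells_per_tissue: int = 16
    missing_rate: float = 0.05
    split_clone_pairs: int = 4
    zygote_het_fraction: float = 0.5
    allele_length_range: tuple[int, int] = (90, 140)
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if self.n_loci < 1 or self.n_generations < 1 or self.cells_per_tissue < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        total = sum(self.step_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("step probabilities must sum to 1")
        if 0 in self.step_probabilities:
            raise ValueError("step of 0 bp is not a mutation")
        for c in self.commitment_schedule:
            if c.pool_size < 1:
                raise ValueError("pool sizes must be >= 1")
            if not (0 < c.generation < self.n_generations):
                raise ValueError("commitment generation must lie in (0, n_generations)")


@dataclass
class SubcloneExperimentConfig:
    """In-vitro mutation-rate assay: single cells passaged for a defined
    number of doublings, then genotyped against the parental line."""

    n_subclones: int = 12
    doublings: int = 20
    n_loci: int = 110
    mu: float = 0.012
    zygote_het_fraction: float = 0.5
    allele_length_range: tuple[int, int] = (90, 140)
    step_probabilities: dict[int, float] = field(
        default_factory=lambda: {-1: 0.5, 1: 0.5}
    )
    seed: int | None = None

    def validate(self) -> None:
        if min(self.n_subclones, self.doublings, self.n_loci) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")


# ---------------------------------------------------------------------------
# lineage tree of the sample


@dataclass
class LineageNode:
    """A node of the sampled genealogy.

    ``path`` encodes the cell's position in the synchronous binary pedigree:
    the cell at generation g with path p has parent p >> 1 at g-1.
    ``mutations`` lists (locus, slot, step) events on the branch from the
    parent to this node.
    """

    path: int
    generation: int
    parent: "LineageNode | None" = None
    children: list["LineageNode"] = field(default_factory=list)
    mutations: list[tuple[int, int, int]] = field(default_factory=list)
    clone_id: str | None = None
    tissue: str = ""
    side: str = ""

    @property
    def is_tip(self) -> bool:
        return not self.children


class LineageTree:
    """Rooted genealogy of the sampled cells, generation 0 at the zygote."""

    def __init__(self, root: LineageNode, zygote_genotype: np.ndarray):
        self.root = root
        self.zygote_genotype = np.asarray(zygote_genotype, dtype=np.int32)

    def tips(self) -> list[LineageNode]:
        out: list[LineageNode] = []

        def walk(node: LineageNode) -> None:
            if node.is_tip:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def genotype_at(self, node: LineageNode) -> np.ndarray:
        """Zygote genotype plus all mutation events on the root path."""
        events: list[tuple[int, int, int]] = []
        cur: LineageNode | None = node
        while cur is not None:
            events.extend(cur.mutations)
            cur = cur.parent
        g = self.zygote_genotype.copy()
        for locus, slot, step in events:
            g[locus, slot] += step
        return g

    def to_newick(self) -> str:
        def render(node: LineageNode) -> str:
            blen = node.generation - (node.parent.generation if node.parent else 0)
            if node.is_tip:
                return f"{node.clone_id}:{blen}"
            inner = ",".join(render(ch) for ch in node.children)
            return f"({inner}):{blen}"

        return render(self.root) + ";"


@dataclass
class LineageSimulation:
    """Bundle returned by :func:`simulate_lineage`."""

    tree: LineageTree
    matrix: GenotypeMatrix          # with missing-data masking applied
    matrix_complete: GenotypeMatrix  # before masking (split pairs identical)
    true_separations: pd.DataFrame   # pairwise mitotic path lengths
    newick: str
    config: SimulationConfig


# ---------------------------------------------------------------------------
# internals


def _draw_zygote(
    rng: np.random.Generator,
    n_loci: int,
    het_fraction: float,
    length_range: tuple[int, int],
) -> np.ndarray:
    lo, hi = length_range
    base = rng.integers(lo, hi + 1, size=n_loci)
    g = np.stack([base, base.copy()], axis=1).astype(np.int32)
    het = rng.random(n_loci) < het_fraction
    offsets = rng.choice([-3, -2, -1, 1, 2, 3], size=n_loci)
    g[het, 1] += offsets[het]
    return g


def _draw_branch_mutations(
    rng: np.random.Generator,
    divisions: int,
    n_loci: int,
    mu: float,
    steps: np.ndarray,
    probs: np.ndarray,
) -> list[tuple[int, int, int]]:
    """Mutation events on a branch spanning `divisions` synchronous divisions."""
    if divisions == 0 or mu == 0.0:
        return []
    counts = rng.binomial(divisions, mu, size=n_loci)
    events: list[tuple[int, int, int]] = []
    for locus in np.nonzero(counts)[0]:
        for _ in range(int(counts[locus])):
            slot = int(rng.integers(2))
            step = int(rng.choice(steps, p=probs))
            events.append((int(locus), slot, step))
    return events


def _sample_distinct(
    rng: np.random.Generator, upper: int, k: int, forbidden=None
) -> list[int]:
    """k distinct integers in [0, upper) avoiding a predicate, by rejection."""
    if forbidden is None:
        forbidden = lambda x: False
    chosen: set[int] = set()
    attempts = 0
    while len(chosen) < k:
        x = int(rng.integers(upper))
        if x not in chosen and not forbidden(x):
            chosen.add(x)
        attempts += 1
        if attempts > 1000 * k + 1000:
            raise RuntimeError("could not sample enough distinct uncommitted cells")
    return sorted(chosen)


def _build_genealogy(tip_paths: list[int], n_generations: int) -> LineageNode:
    """Genealogy of tips from their binary division paths (shared prefixes).

    The ancestor of a generation-G cell with path p at generation g is
    p >> (G - g); branching generations are where tip paths diverge.
    """

    def ancestor(path: int, gen: int) -> int:
        return path >> (n_generations - gen)

    def build(paths: list[int], start_gen: int) -> LineageNode:
        # advance while all paths share the same ancestor
        gen = start_gen
        while gen < n_generations:
            anc = {ancestor(p, gen + 1) for p in paths}
            if len(anc) > 1:
                break
            gen += 1
        node = LineageNode(path=ancestor(paths[0], gen), generation=gen)
        if gen == n_generations:
            return node  # a tip (all paths identical)
        left = [p for p in paths if ancestor(p, gen + 1) & 1 == 0]
        right = [p for p in paths if ancestor(p, gen + 1) & 1 == 1]
        for group in (left, right):
            if group:
                child = build(group, gen)  # advances past gen: group shares bit gen+1
                node.children.append(child)
                child.parent = node
        return node

    root = build(sorted(set(tip_paths)), 0)
    # wrap so that the root is the zygote at generation 0
    if root.generation > 0:
        zyg = LineageNode(path=0, generation=0)
        zyg.children.append(root)
        root.parent = zyg
        root = zyg
    return root


# ---------------------------------------------------------------------------
# public operations


def simulate_lineage(config: SimulationConfig) -> LineageSimulation:
    """Simulate one individual and return its sampled genotypes plus truth.

    Deterministic given ``config.seed``.  Raises ``ValueError`` when a
    commitment pool exceeds the number of cells alive at its generation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_generations
    steps = np.array(sorted(config.step_probabilities), dtype=int)
    probs = np.array([config.step_probabilities[s] for s in steps], dtype=float)

    zygote = _draw_zygote(
        rng, config.n_loci, config.zygote_het_fraction, config.allele_length_range
    )

    # --- commitment pools (disjoint across the schedule) ------------------
    committed: list[tuple[int, set[int]]] = []  # (generation, pool indices)
    pools: list[tuple[TissueCommitment, list[int]]] = []
    for com in sorted(config.commitment_schedule, key=lambda c: c.generation):
        alive = 1 << com.generation
        if com.pool_size > alive:
            raise ValueError(
                f"pool size {com.pool_size} exceeds the {alive} cells alive at "
                f"generation {com.generation} ({com.tissue}/{com.side})"
            )

        def taken(idx: int, gen: int = com.generation) -> bool:
            for g0, s0 in committed:
                if g0 <= gen and (idx >> (gen - g0)) in s0:
                    return True
            return False

        pool = _sample_distinct(rng, alive, com.pool_size, forbidden=taken)
        committed.append((com.generation, set(pool)))
        pools.append((com, pool))

    # --- sample tips -------------------------------------------------------
    tip_records: list[tuple[int, str, str, str]] = []  # (path, id, tissue, side)
    used_paths: set[int] = set()
    counter = 1
    for com, pool in pools:
        shift = G - com.generation
        for _ in range(config.cells_per_tissue):
            for _attempt in range(10_000):
                prog = pool[int(rng.integers(len(pool)))]
                path = (prog << shift) | int(rng.integers(1 << shift))
                if path not in used_paths:
                    used_paths.add(path)
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not sample distinct terminal cells")
            clone_id = f"{com.tissue[:3]}{com.side}{counter:03d}"
            counter += 1
            tip_records.append((path, clone_id, com.tissue, com.side))

    # --- genealogy + mutations ---------------------------------------------
    root = _build_genealogy([p for p, *_ in tip_records], G)

    def mutate(node: LineageNode) -> None:
        if node.parent is not None:
            d = node.generation - node.parent.generation
            node.mutations = _draw_branch_mutations(
                rng, d, config.n_loci, config.mu, steps, probs
            )
        for ch in node.children:
            mutate(ch)

    mutate(root)
    tree = LineageTree(root, zygote)

    # annotate tips (tips are found by their path)
    by_path = {t.path: t for t in tree.tips()}
    for path, clone_id, tissue, side in tip_records:
        tip = by_path[path]
        tip.clone_id, tip.tissue, tip.side = clone_id, tissue, side

    # --- genotype matrix ----------------------------------------------------
    clone_ids = [r[1] for r in tip_records]
    locus_ids = [f"pG{j + 1:03d}" for j in range(config.n_loci)]
    genotypes = {r[1]: tree.genotype_at(by_path[r[0]]) for r in tip_records}
    meta_rows = {
        r[1]: {"tissue": r[2], "side": r[3], "mouse": "sim", "split_pair": ""}
        for r in tip_records
    }

    # split-clone duplicates: same terminal cell genotyped twice
    n_pairs = min(config.split_clone_pairs, len(tip_records))
    if n_pairs:
        pick = rng.choice(len(tip_records), size=n_pairs, replace=False)
        for k, ti in enumerate(sorted(int(i) for i in pick), start=1):
            path, cid, tissue, side = tip_records[ti]
            dup = f"{cid}s"
            clone_ids.append(dup)
            genotypes[dup] = genotypes[cid].copy()
            meta_rows[dup] = {
                "tissue": tissue, "side": side, "mouse": "sim", "split_pair": f"sp{k}",
            }
            meta_rows[cid]["split_pair"] = f"sp{k}"

    alleles = np.stack([genotypes[c] for c in clone_ids]).astype(np.int32)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[clone_ids]
    complete = GenotypeMatrix(alleles.copy(), clone_ids, locus_ids, meta)

    masked = alleles.copy()
    if config.missing_rate > 0:
        mask = rng.random(masked.shape) < config.missing_rate
        masked[mask] = MISSING
    matrix = GenotypeMatrix(masked, clone_ids, locus_ids, meta)

    # --- true pairwise mitotic separations ----------------------------------
    path_of = {r[1]: r[0] for r in tip_records}
    for cid in clone_ids:
        if cid not in path_of:  # split duplicate shares its parent cell
            path_of[cid] = path_of[cid[:-1]]
    sep = np.zeros((len(clone_ids), len(clone_ids)), dtype=int)
    for i, ci in enumerate(clone_ids):
        for j in range(i + 1, len(clone_ids)):
            s = mitotic_separation(path_of[ci], path_of[clone_ids[j]], G)
            sep[i, j] = sep[j, i] = s
    true_separations = pd.DataFrame(sep, index=clone_ids, columns=clone_ids)

    return LineageSimulation(
        tree=tree,
        matrix=matrix,
        matrix_complete=complete,
        true_separations=true_separations,
        newick=tree.to_newick(),
        config=config,
    )


def mitotic_separation(path_a: int, path_b: int, n_generations: int) -> int:
    """Divisions along the pedigree path between two terminal cells."""
    if path_a == path_b:
        return 0
    diverged = (path_a ^ path_b).bit_length()  # bits below the common prefix
    return 2 * diverged


def simulate_subclone_experiment(config: SubcloneExperimentConfig) -> GenotypeMatrix:
    """Parent line plus subclones passaged for a fixed number of doublings.

    Returns a matrix whose first clone (``parent``) is the parental
    genotype and whose remaining rows each carry the new mutations
    accumulated over ``config.doublings`` divisions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    steps = np.array(sorted(config.step_probabilities), dtype=int)
    probs = np.array([config.step_probabilities[s] for s in steps], dtype=float)
    parent = _draw_zygote(
        rng, config.n_loci, config.zygote_het_fraction, config.allele_length_range
    )
    rows = [parent]
    ids = ["parent"]
    for k in range(config.n_subclones):
        g = parent.copy()
        for locus, slot, step in _draw_branch_mutations(
            rng, config.doublings, config.n_loci, config.mu, steps, probs
        ):
            g[locus, slot] += step
        rows.append(g)
        ids.append(f"subclone{k + 1:02d}")
    alleles = np.stack(rows).astype(np.int32)
    locus_ids = [f"pG{j + 1:03d}" for j in range(config.n_loci)]
    meta = pd.DataFrame(
        {"tissue": ["parent"] + ["subclone"] * config.n_subclones}, index=ids
    )
    return GenotypeMatrix(alleles, ids, locus_ids, meta)


# ---------------------------------------------------------------------------
# peak-profile synthesis (exercises the genotype caller)


@dataclass(frozen=True)
class StutterModel:
    """Fragment-analysis artifact model for synthetic electropherograms.

    ``ratio`` is the intensity of the stutter peak (one bp short of a true
    allele) relative to its parent peak; ``jitter`` is multiplicative
    replicate-to-replicate noise; ``noise_floor`` adds a weak background
    peak so every profile has at least three signals.
    """

    ratio: float = 0.15
    base_intensity: float = 30_000.0
    minor_allele_fraction: float = 0.9
    jitter: float = 0.03
    noise_floor: float = 400.0


def simulate_peak_profiles(
    genotype: Sequence[int],
    stutter: StutterModel = StutterModel(),
    seed: int | None = None,
    dropout_replicates: Sequence[int] = (),
):
    """Three replicate (size, intensity) profiles for one clone x locus.

    ``dropout_replicates`` lists replicate indices (0-2) in which the second
    allele fails to amplify, producing replicate-inconsistent profiles that
    the caller must flag as ambiguous.
    """
    from .calling import PeakProfile, PeakTriplicate  # local to avoid cycle

    a, b = int(genotype[0]), int(genotype[1])
    if a <= 0 or b <= 0:
        raise ValueError("allele lengths must be positive")
    rng = np.random.default_rng(seed)
    profiles = []
    for rep in range(3):
        jit = lambda x: float(x * (1.0 + rng.normal(0.0, stutter.jitter)))
        peaks: dict[int, float] = {}

        def add(size: int, intensity: float) -> None:
            peaks[size] = peaks.get(size, 0.0) + intensity

        main = jit(stutter.base_intensity)
        add(a, main)
        if b != a:
            minor = jit(stutter.base_intensity * stutter.minor_allele_fraction)
            if rep in dropout_replicates:
                minor = 0.02 * main
            add(b, minor)
            add(b - 1, stutter.ratio * minor)
        else:
            add(a, main)  # homozygote: both chromosomes amplify the same size
        add(a - 1, stutter.ratio * main)
        add(min(a, b) - 2, jit(stutter.noise_floor))
        profile = PeakProfile(sorted(peaks.items()))
        profiles.append(profile)
    return PeakTriplicate(tuple(profiles))
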