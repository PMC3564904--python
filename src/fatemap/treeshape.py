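"""Tree-imbalance statistics, the randomized-genotype null, NEXUS recoding
for external Bayesian inference, and a UPGMA distance-tree builder.

Imbalance is summarised two ways:

* ``nbar`` — the mean, over tips, of the number of internal nodes on the
  path from the tip to the root, counting the root (Kirkpatrick-Slatkin).
  A fully balanced tree with 2^k tips scores k; the n-tip caterpillar
  scores (n-1)(n+2)/(2n).
* ``colless`` — the sum over internal nodes of |tips(left) - tips(right)|
  for bifurcating trees, optionally normalised by its caterpillar maximum
  (n-1)(n-2)/2.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .distance import DistanceMatrix, distance_matrix
from .genotypes import GenotypeMatrix

Tree = dendropy.Tree


# ---------------------------------------------------------------------------
# imbalance statistics


@dataclass(frozen=True)
class ShapeStatistics:
    nbar: float
    colless_raw: int
    colless_normalized: float


def nbar(tree: Tree) -> float:
    """Mean number of internal nodes between each tip and the root
    (root included).  Handles multifurcations directly."""
    leaves = [nd for nd in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("nbar needs a tree with at least two tips")
    total = 0
    for leaf in leaves:
        node = leaf.parent_node
        depth = 0
        while node is not None:
            depth += 1
            node = node.parent_node
        total += depth
    return total / len(leaves)


def colless(
    tree: Tree, polytomies: str = "reject", seed: int | None = None
) -> ShapeStatistics:
    """Colless imbalance of a rooted bifurcating tree.

    ``polytomies='reject'`` raises on multifurcations; ``'resolve'``
    resolves them randomly (seeded) before measuring.
    """
    work = tree.clone(depth=1)
    internal = [nd for nd in work.preorder_node_iter() if not nd.is_leaf()]
    if any(len(nd.child_nodes()) > 2 for nd in internal):
        if polytomies == "reject":
            raise ValueError("tree has multifurcations; pass polytomies='resolve'")
        work.resolve_polytomies(rng=_random.Random(seed))
    # suppress unifurcations (e.g. a rooted stalk) so every split is binary
    work.suppress_unifurcations()
    n_tips = 0
    raw = 0
    sizes: dict = {}
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            sizes[nd] = 1
            n_tips += 1
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise ValueError("tree is not strictly bifurcating after resolution")
        sizes[nd] = sizes[kids[0]] + sizes[kids[1]]
        raw += abs(sizes[kids[0]] - sizes[kids[1]])
    if n_tips < 3:
        return ShapeStatistics(nbar=nbar(tree), colless_raw=raw, colless_normalized=0.0)
    norm = raw / ((n_tips - 1) * (n_tips - 2) / 2)
    return ShapeStatistics(nbar=nbar(tree), colless_raw=raw, colless_normalized=norm)


# ---------------------------------------------------------------------------
# reference topologies


def balanced_tree(n_tips: int) -> Tree:
    """Fully balanced bifurcating tree; n_tips must be a power of two."""
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of two >= 2")
    labels = iter(f"t{i + 1}" for i in range(n_tips))

    def build(k: int) -> str:
        if k == 1:
            return next(labels)
        return f"({build(k // 2)},{build(k // 2)})"

    return dendropy.Tree.get(data=build(n_tips) + ";", schema="newick")


def caterpillar_tree(n_tips: int) -> Tree:
    """Fully pectinate tree: each internal node has one tip child except
    the deepest, which has two."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    newick = f"(t1,t2)"
    for i in range(3, n_tips + 1):
        newick = f"({newick},t{i})"
    return dendropy.Tree.get(data=newick + ";", schema="newick")


# ---------------------------------------------------------------------------
# randomized-genotype null


def randomize_genotypes(
    matrix: GenotypeMatrix, seed: int | np.random.Generator | None = None
) -> GenotypeMatrix:
    """Shuffle, independently at each locus, which clone carries which
    genotype call (missing calls included).  Destroys lineage structure
    while preserving each locus's allele multiset exactly."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alleles = matrix.alleles.copy()
    for j in range(matrix.n_loci):
        order = rng.permutation(matrix.n_clones)
        alleles[:, j, :] = alleles[order, j, :]
    return GenotypeMatrix(
        alleles, list(matrix.clone_ids), list(matrix.locus_ids), matrix.meta.copy()
    )


# ---------------------------------------------------------------------------
# recoding for external Bayesian inference


@dataclass
class CharacterRecoding:
    """Allele lengths recoded as 0-9 digit characters, one column per
    parental allele slot, for standard-datatype phylogenetics."""

    matrix: pd.DataFrame  # clones x character columns, single-char strings

    def to_nexus(self, path: str | Path | None = None, mrbayes_block: bool = True) -> str:
        taxa = list(self.matrix.index)
        nchar = self.matrix.shape[1]
        width = max(len(t) for t in taxa) + 2
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={len(taxa)} NCHAR={nchar};",
            "    FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456789\" MISSING=? GAP=-;",
            "    MATRIX",
        ]
        for t in taxa:
            seq = "".join(self.matrix.loc[t])
            lines.append(f"    {t:<{width}}{seq}")
        lines += ["    ;", "END;"]
        if mrbayes_block:
            lines += [
                "",
                "BEGIN MRBAYES;",
                "    [ rate variation across sites: gamma with a uniform(0.05, 50)",
                "      prior on the shape; symmetric Dirichlet fixed to infinity ]",
                "    lset rates=gamma;",
                "    prset shapepr=uniform(0.05,50) symdirihyperpr=fixed(infinity);",
                "    mcmc;",
                "END;",
            ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def recode_for_phylogenetics(matrix: GenotypeMatrix) -> CharacterRecoding:
    """Map allele lengths to digits 0-9 per locus per allele slot.

    Digits rank alleles by descending frequency (0 = modal allele; ties by
    smaller length); with more than ten distinct alleles the rarest are
    merged into digit 9.  Missing becomes '?'.  Works best after parental
    assignment so that slots are comparable across clones.
    """
    cols = {}
    for j, locus in enumerate(matrix.locus_ids):
        for slot, tag in ((0, "a"), (1, "b")):
            col = matrix.alleles[:, j, slot]
            obs = col[col >= 0]
            codes: dict[int, str] = {}
            if obs.size:
                freq: dict[int, int] = {}
                for a in obs:
                    freq[int(a)] = freq.get(int(a), 0) + 1
                ranked = sorted(freq, key=lambda a: (-freq[a], a))
                for rank, a in enumerate(ranked):
                    codes[a] = str(min(rank, 9))
            cols[f"{locus}_{tag}"] = [
                "?" if a < 0 else codes[int(a)] for a in col
            ]
    frame = pd.DataFrame(cols, index=matrix.clone_ids)
    return CharacterRecoding(matrix=frame)


def read_nexus_characters(path: str | Path) -> pd.DataFrame:
    """Read a standard-datatype NEXUS character matrix back into a frame of
    single-character strings (columns positionally numbered)."""
    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    rows = {}
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        rows[taxon.label] = [str(c) for c in seq.symbols_as_list()]
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return frame


def read_trees(path: str | Path, schema: str = "newick") -> list[Tree]:
    """Read tree samples (e.g. from external Bayesian inference)."""
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    return list(tl)


# ---------------------------------------------------------------------------
# UPGMA distance tree


def build_distance_tree(dm: DistanceMatrix, method: str = "upgma") -> Tree:
    """Rooted tree by agglomerative clustering of the distance matrix.

    UPGMA (average linkage); ties break deterministically by input label
    order through scipy's observation indexing.  Undefined distances raise.
    """
    if method.lower() != "upgma":
        raise ValueError("only UPGMA is supported")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix has undefined entries")
    n = len(dm.clone_ids)
    if n < 2:
        raise ValueError("need at least two clones")
    iu, ju = np.triu_indices(n, k=1)
    condensed = dm.values[iu, ju]
    z = linkage(condensed, method="average")
    root, _ = to_tree(z, rd=True)

    # branch lengths: ultrametric heights halved; children carry height
    # differences relative to the parent
    def render2(node, parent_height: float) -> str:
        h = node.dist / 2.0
        blen = max(parent_height - h, 0.0)
        if node.is_leaf():
            return f"{dm.clone_ids[node.id]}:{parent_height:.8g}"
        parts = ",".join(render2(ch, h) for ch in (node.left, node.right))
        return f"({parts}):{blen:.8g}"

    newick = render2(root, root.dist / 2.0)
    # root branch length is 0 by construction of render2 at the top call
    return dendropy.Tree.get(data=newick + ";", schema="newick")


# ---------------------------------------------------------------------------
# observed-vs-null shape comparison


@dataclass
class ShapeNullComparison:
    """Paired distributions of imbalance statistics for observed trees vs
    trees rebuilt from randomized genotypes."""

    observed: pd.DataFrame  # columns nbar, colless_normalized
    null: pd.DataFrame
    nbar_shift: float       # mean(observed) - mean(null); negative = more symmetric
    nbar_p: float           # one-sided: observed more symmetric than null
    colless_shift: float
    colless_p: float


def _rank_p(observed_mean: float, null_values: np.ndarray) -> float:
    """One-sided rank p-value that the observed mean sits low in the null."""
    return float((1 + (null_values <= observed_mean).sum()) / (1 + null_values.size))


def shape_null_comparison(
    matrix: GenotypeMatrix,
    n_randomizations: int = 100,
    seed: int | None = None,
    observed_trees: list[Tree] | None = None,
) -> ShapeNullComparison:
    """Compare imbalance of observed-genotype trees against trees from
    randomized genotypes.

    When ``observed_trees`` is omitted a single UPGMA tree is built from
    the observed matrix; external tree samples (e.g. Bayesian posteriors)
    can be passed instead.  Null trees are UPGMA trees of per-locus
    randomized matrices.
    """
    if n_randomizations < 10:
        warnings.warn("fewer than 10 randomizations gives a coarse null")
    rng = np.random.default_rng(seed)
    if observed_trees is None:
        observed_trees = [build_distance_tree(distance_matrix(matrix))]

    def stats_of(tree: Tree) -> tuple[float, float]:
        s = colless(tree, polytomies="resolve", seed=int(rng.integers(2**31)))
        return (s.nbar, s.colless_normalized)

    obs = pd.DataFrame(
        [stats_of(t) for t in observed_trees], columns=["nbar", "colless_normalized"]
    )
    null_rows = []
    for _ in range(n_randomizations):
        rm = randomize_genotypes(matrix, rng)
        tree = build_distance_tree(distance_matrix(rm))
        null_rows.append(stats_of(tree))
    null = pd.DataFrame(null_rows, columns=["nbar", "colless_normalized"])

    def compare(col: str) -> tuple[float, float]:
        shift = float(obs[col].mean() - null[col].mean())
        if len(obs) > 1:
            p = float(
                stats.mannwhitneyu(obs[col], null[col], alternative="less").pvalue
            )
        else:
            p = _rank_p(float(obs[col].iloc[0]), null[col].to_numpy())
        return shift, p

    nbar_shift, nbar_p = compare("nbar")
    colless_shift, colless_p = compare("colless_normalized")
    return ShapeNullComparison(
        observed=obs,
        null=null,
        nbar_shift=nbar_shift,
        nbar_p=nbar_p,
        colless_shift=colless_shift,
        colless_p=colless_p,
    )
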