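"""Mutational-similarity networks among single-cell clones.

An edge joins a pair of clones whose genetic distance is significantly
smaller than expected under a permutation null in which each locus's
genotype calls are independently shuffled across clones (destroying lineage
signal while preserving every locus's allele multiset).  Per-pair p-values
are Benjamini-Hochberg corrected; node weights record the mean intra-tissue
distance of each clone's tissue group.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .distance import DistanceMatrix, distance_matrix
from .genotypes import GenotypeMatrix
from .treeshape import randomize_genotypes


def build_similarity_network(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int | None = None,
) -> nx.Graph:
    """Permutation-calibrated similarity network over a genotype matrix.

    The null distribution pools the pairwise distances of
    ``n_permutations`` per-locus genotype shufflings (clone pairs are
    exchangeable once every locus is shuffled, so pooling sharpens the
    p-value granularity well below 1/n_permutations); each observed
    distance gets a one-sided p-value (at least as small as the pooled
    null), BH correction is applied, and pairs significant at ``alpha``
    become edges.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    rng = np.random.default_rng(seed)
    dm = distance_matrix(matrix)
    n = matrix.n_clones
    iu, ju = np.triu_indices(n, k=1)
    observed = dm.values[iu, ju]

    null_pool = []
    for _ in range(n_permutations):
        perm = randomize_genotypes(matrix, rng)
        null_pool.append(distance_matrix(perm).values[iu, ju])
    null = np.concatenate(null_pool)
    null = np.sort(null[~np.isnan(null)])
    if null.size == 0 or null[0] == null[-1]:
        warnings.warn("zero-variance permutation null; no edges assigned")
        pvals = np.ones(observed.shape)
    else:
        leq = np.searchsorted(null, observed, side="right")
        pvals = (1.0 + leq) / (1.0 + null.size)
    defined = ~np.isnan(observed)
    reject = np.zeros(observed.shape, dtype=bool)
    qvals = np.full(observed.shape, np.nan)
    if defined.any():
        rej, q, *_ = multipletests(pvals[defined], alpha=alpha, method="fdr_bh")
        reject[defined] = rej
        qvals[defined] = q

    g = nx.Graph()
    meta = matrix.meta
    intra_means = _intra_tissue_means(dm, meta)
    for cid in matrix.clone_ids:
        key = (meta.loc[cid, "tissue"], meta.loc[cid, "side"])
        g.add_node(
            cid,
            tissue=meta.loc[cid, "tissue"],
            side=meta.loc[cid, "side"],
            weight=intra_means.get(key, float("nan")),
        )
    for k in np.nonzero(reject)[0]:
        a, b = matrix.clone_ids[iu[k]], matrix.clone_ids[ju[k]]
        g.add_edge(
            a,
            b,
            distance=float(observed[k]),
            p=float(pvals[k]),
            q=float(qvals[k]),
        )
    g.graph.update(alpha=alpha, n_permutations=n_permutations)
    return g


def _intra_tissue_means(dm: DistanceMatrix, meta: pd.DataFrame) -> dict:
    ids = np.array(dm.clone_ids)
    tissue = meta.loc[ids, "tissue"].to_numpy()
    side = meta.loc[ids, "side"].to_numpy()
    out = {}
    for key in {(t, s) for t, s in zip(tissue, side)}:
        sel = (tissue == key[0]) & (side == key[1])
        block = dm.values[np.ix_(sel, sel)]
        iu, ju = np.triu_indices(block.shape[0], k=1)
        vals = block[iu, ju]
        vals = vals[~np.isnan(vals)]
        out[key] = float(vals.mean()) if vals.size else float("nan")
    return out


def tissue_level_edges(g: nx.Graph) -> set[frozenset]:
    """Collapse clone-pair edges to unordered (tissue, side) group pairs."""
    out: set[frozenset] = set()
    for a, b in g.edges:
        ka = (g.nodes[a]["tissue"], g.nodes[a]["side"])
        kb = (g.nodes[b]["tissue"], g.nodes[b]["side"])
        if ka != kb:
            out.add(frozenset((ka, kb)))
    return out


def compare_networks(
    g1: nx.Graph, g2: nx.Graph, tissue_map: dict | None = None
) -> set[frozenset]:
    """Tissue-level edges present in both networks (conserved relationships).

    ``tissue_map`` optionally renames g2's (tissue, side) keys into g1's
    vocabulary before intersecting.  Conserved edges are also flagged on g1
    via the ``conserved`` edge attribute.
    """
    e1 = tissue_level_edges(g1)
    e2 = tissue_level_edges(g2)
    if tissue_map is not None:
        e2 = {frozenset(tissue_map.get(k, k) for k in e) for e in e2}
    conserved = e1 & e2
    for a, b in g1.edges:
        ka = (g1.nodes[a]["tissue"], g1.nodes[a]["side"])
        kb = (g1.nodes[b]["tissue"], g1.nodes[b]["side"])
        g1.edges[a, b]["conserved"] = (
            ka != kb and frozenset((ka, kb)) in conserved
        )
    return conserved


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {
            "clone_a": a,
            "clone_b": b,
            "distance": d.get("distance"),
            "p": d.get("p"),
            "q": d.get("q"),
            "conserved": d.get("conserved", False),
        }
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["clone_a", "clone_b", "distance", "p", "q", "conserved"]
    ).to_csv(path, sep="\t", index=False)
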