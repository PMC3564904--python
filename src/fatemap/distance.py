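"""Diploid genetic distance, tissue summaries, the molecular clock, and
lineage-history combinatorics.

The distance between two clones is the per-locus-normalised sum of minimal
allele-length differences: at each locus the contribution is the smaller of
the two ways of pairing the four alleles (sum of absolute bp differences).
Loci where the pair jointly has more than one missing ("X") allele are
excluded; with exactly one missing allele the known allele is compared to
the closer of its counterpart's two alleles.  The total is divided by the
number of usable loci for that pair, so distances are comparable across
pairs with different amounts of missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# pairwise distance


def pairwise_distance(g_a: np.ndarray, g_b: np.ndarray) -> tuple[float, int]:
    """Distance between two ``(n_loci, 2)`` genotype vectors.

    Returns ``(distance, n_usable_loci)``; the distance is ``nan`` when no
    locus is usable.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    if g_a.shape != g_b.shape or g_a.ndim != 2 or g_a.shape[1] != 2:
        raise ValueError("genotype vectors must share shape (n_loci, 2)")
    total = 0.0
    usable = 0
    for j in range(g_a.shape[0]):
        contrib = _locus_contribution(g_a[j], g_b[j])
        if contrib is None:
            continue
        usable += 1
        total += contrib
    if usable == 0:
        return (float("nan"), 0)
    return (total / usable, usable)


def _locus_contribution(a: np.ndarray, b: np.ndarray) -> float | None:
    """Minimal-difference contribution of one locus, or None if excluded."""
    miss = int((a < 0).sum() + (b < 0).sum())
    if miss > 1:
        return None
    if miss == 0:
        d0 = abs(int(a[0]) - int(b[0])) + abs(int(a[1]) - int(b[1]))
        d1 = abs(int(a[0]) - int(b[1])) + abs(int(a[1]) - int(b[0]))
        return float(min(d0, d1))
    if (a < 0).any():
        known = int(a[a >= 0][0])
        other = b
    else:
        known = int(b[b >= 0][0])
        other = a
    return float(min(abs(known - int(other[0])), abs(known - int(other[1]))))


@dataclass
class DistanceMatrix:
    """Symmetric per-locus-normalised distances among clones.

    ``values`` holds ``nan`` for undefined pairs (no jointly usable locus);
    ``n_usable`` the per-pair usable-locus counts.
    """

    clone_ids: list[str]
    values: np.ndarray
    n_usable: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.clone_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over clone_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.clone_ids, columns=self.clone_ids)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.clone_ids.index(a), self.clone_ids.index(b)]
        )

    def write_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "clone"
        frame.to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP-style square matrix (undefined pairs written as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.clone_ids)}\n")
            for i, cid in enumerate(self.clone_ids):
                row = " ".join(
                    f"{-1.0 if np.isnan(v) else v:.6f}" for v in self.values[i]
                )
                fh.write(f"{cid[:10]:<10} {row}\n")


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """All pairwise distances (vectorised over loci and clone pairs)."""
    if matrix.n_clones < 2:
        raise ValueError("need at least two clones")
    A = matrix.alleles.astype(np.int64)
    miss = (A < 0).sum(axis=2)  # (n, L) missing alleles per call
    # known single allele for one-missing calls (junk elsewhere, masked later)
    known = np.where(A[:, :, 0] < 0, A[:, :, 1], A[:, :, 0])

    a0, a1 = A[:, :, 0], A[:, :, 1]
    n = matrix.n_clones

    mm = miss[:, None, :] + miss[None, :, :]          # (n, n, L)
    usable = mm <= 1

    # complete-pair contribution: min over the two allele pairings
    d_dir = np.abs(a0[:, None, :] - a0[None, :, :]) + np.abs(
        a1[:, None, :] - a1[None, :, :]
    )
    d_swp = np.abs(a0[:, None, :] - a1[None, :, :]) + np.abs(
        a1[:, None, :] - a0[None, :, :]
    )
    full = np.minimum(d_dir, d_swp)

    # single-missing contribution: known allele vs closer counterpart allele
    i_single = np.minimum(
        np.abs(known[:, None, :] - a0[None, :, :]),
        np.abs(known[:, None, :] - a1[None, :, :]),
    )
    j_single = np.minimum(
        np.abs(known[None, :, :] - a0[:, None, :]),
        np.abs(known[None, :, :] - a1[:, None, :]),
    )
    contrib = np.where(
        mm == 0,
        full,
        np.where(miss[:, None, :] == 1, i_single, j_single),
    )
    counts = usable.sum(axis=2)
    totals = np.where(usable, contrib, 0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(matrix.clone_ids), values, counts)


def distance_to_reference(
    matrix: GenotypeMatrix, reference: np.ndarray
) -> pd.Series:
    """Distance of every clone to a reference genotype (e.g. the zygote)."""
    out = {}
    for cid in matrix.clone_ids:
        d, _ = pairwise_distance(matrix.genotype_of(cid), reference)
        out[cid] = d
    return pd.Series(out, name="distance_to_reference")


# ---------------------------------------------------------------------------
# tissue summaries (Table-1 style)


@dataclass
class TissueDistanceSummary:
    """Per-(tissue, side) group means of pairwise distances.

    ``table`` rows: intra-tissue, inter-tissue, to-zygote and left-to-right
    means with SEMs over the contributing pair values, plus two-sided
    one-sample t-test p-values of each group's pair distances against the
    global mean pairwise distance.
    """

    table: pd.DataFrame
    global_mean: float


def _sem(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def _ttest_vs(values: np.ndarray, popmean: float) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2 or np.allclose(values, values[0]):
        return float("nan")
    return float(stats.ttest_1samp(values, popmean).pvalue)


def tissue_distance_summary(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    zygote_distances: pd.Series | None = None,
) -> TissueDistanceSummary:
    """Summarise the distance matrix by tissue/side groups.

    intra-tissue: pairs within the group; inter-tissue: pairs with exactly
    one member in the group; to-zygote: members' distances to the zygote
    reference; left-to-right: cross-side pairs of the same tissue type.
    """
    ids = dm.clone_ids
    tissue = meta.loc[ids, "tissue"].to_numpy()
    side = meta.loc[ids, "side"].to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    pair_d = dm.values[iu, ju]
    valid = ~np.isnan(pair_d)
    global_vals = pair_d[valid]
    global_mean = float(global_vals.mean())

    rows = []
    for t in dict.fromkeys(tissue):
        for s in dict.fromkeys(side[tissue == t]):
            in_group = (tissue == t) & (side == s)
            gi, gj = in_group[iu], in_group[ju]
            intra = pair_d[gi & gj & valid]
            inter = pair_d[(gi ^ gj) & valid]
            same_tissue = (tissue[iu] == t) & (tissue[ju] == t)
            cross = pair_d[same_tissue & (side[iu] != side[ju]) & valid]
            row = {
                "tissue": t,
                "side": s,
                "n_clones": int(in_group.sum()),
                "intra_mean": float(intra.mean()) if intra.size else float("nan"),
                "intra_sem": _sem(intra),
                "intra_p": _ttest_vs(intra, global_mean),
                "inter_mean": float(inter.mean()) if inter.size else float("nan"),
                "inter_sem": _sem(inter),
                "inter_p": _ttest_vs(inter, global_mean),
                "left_right_mean": float(cross.mean()) if cross.size else float("nan"),
                "left_right_sem": _sem(cross),
            }
            if zygote_distances is not None:
                zd = zygote_distances.loc[np.array(ids)[in_group]].to_numpy(float)
                zd = zd[~np.isnan(zd)]
                row["zygote_mean"] = float(zd.mean()) if zd.size else float("nan")
                row["zygote_sem"] = _sem(zd)
            rows.append(row)
    return TissueDistanceSummary(table=pd.DataFrame(rows), global_mean=global_mean)


def intra_vs_inter_permutation_test(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    n_label_permutations: int = 199,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation-calibrated t-test of intra-group vs inter-group pair
    distances.

    Pairwise distances sharing clones are dependent, so the nominal t
    distribution is invalid; instead the Welch t statistic is referred to
    its distribution under random relabelling of clones into groups, which
    is exact under exchangeability.  Returns (t statistic, two-sided p).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    ids = dm.clone_ids
    key = (
        meta.loc[ids, "tissue"].astype(str) + "|" + meta.loc[ids, "side"].astype(str)
    ).to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    d = dm.values[iu, ju]
    valid = ~np.isnan(d)

    def t_of(labels: np.ndarray) -> float:
        same = labels[iu] == labels[ju]
        a, b = d[same & valid], d[~same & valid]
        if a.size < 2 or b.size < 2:
            return float("nan")
        return float(stats.ttest_ind(a, b, equal_var=False).statistic)

    t_obs = t_of(key)
    hits = 0
    for _ in range(n_label_permutations):
        t_perm = t_of(rng.permutation(key))
        if abs(t_perm) >= abs(t_obs):
            hits += 1
    p = (1 + hits) / (1 + n_label_permutations)
    return (t_obs, p)


# ---------------------------------------------------------------------------
# molecular clock


@dataclass(frozen=True)
class ClockModel:
    """Constant per-locus per-division mutation clock: D = mu x divisions."""

    mu: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def divisions_from_distance(d: float, clock: ClockModel) -> float:
    """Mitotic separation implied by a per-locus distance."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return d / clock.mu


def distance_from_divisions(divisions: float, clock: ClockModel) -> float:
    """Per-locus distance expected after a given mitotic separation."""
    return divisions * clock.mu


# ---------------------------------------------------------------------------
# combinatorics and cross-individual correlation


def count_lineage_histories(n: int) -> int:
    """Exact number of rooted lineage histories for n cells:
    (2n-3)! / (2^(n-2) (n-2)!)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return math.factorial(2 * n - 3) // (2 ** (n - 2) * math.factorial(n - 2))


def cross_individual_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson correlation of matched tissue-pair distances between two
    individuals: returns (r, R^2, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least three matched pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return (r, r * r, float(res.pvalue))
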