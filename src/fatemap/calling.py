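"""Genotype interpretation: from triplicate peak profiles to diploid calls,
parental-allele assignment, consensus genotypes, mutation summaries, and the
in-vitro mutation-rate estimator.

The caller reproduces the fragment-analysis decision rule used for polyG
markers: with I1H, I2H, I3H the highest, second- and third-highest peak
intensities of a replicate, a homozygote is assigned when
|I2H - I3H| <= intensity_gap (equivalently |(I1H-I2H) - (I1H-I3H)| below the
gap), a heterozygote when the gap is exceeded and I2H > het_ratio * I1H, and
anything in between — or any disagreement among the three replicates — is
ambiguous ("X").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeCall, GenotypeMatrix


@dataclass(frozen=True)
class PeakProfile:
    """One replicate's electropherogram: (fragment size bp, intensity U)."""

    peaks: tuple[tuple[int, float], ...]

    def __init__(self, peaks: Iterable[Sequence[float]]):
        cleaned = tuple(sorted((int(s), float(i)) for s, i in peaks))
        if any(i < 0 for _, i in cleaned) or any(s <= 0 for s, _ in cleaned):
            raise ValueError("sizes must be positive and intensities non-negative")
        object.__setattr__(self, "peaks", cleaned)

    def top3(self) -> list[tuple[int | None, float]]:
        """Three most intense peaks, padded with zero-intensity sentinels."""
        ranked = sorted(self.peaks, key=lambda p: (-p[1], p[0]))
        out: list[tuple[int | None, float]] = [(s, i) for s, i in ranked[:3]]
        while len(out) < 3:
            out.append((None, 0.0))
        return out


@dataclass(frozen=True)
class PeakTriplicate:
    replicates: tuple[PeakProfile, PeakProfile, PeakProfile]

    def __post_init__(self):
        if len(self.replicates) != 3:
            raise ValueError("a triplicate holds exactly three replicates")


@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds of the genotype caller.

    intensity_gap: U separating homozygote (<=) from heterozygote (>=) regimes.
    het_ratio: minimum I2H/I1H for a credible second allele.
    """

    intensity_gap: float = 1e4
    het_ratio: float = 0.8

    def __post_init__(self):
        if self.intensity_gap <= 0 or not (0 < self.het_ratio < 1):
            raise ValueError("invalid thresholds")


def _call_replicate(profile: PeakProfile, t: CallThresholds):
    """Call one replicate: ('hom', (a, a)) / ('het', (a, b)) / ('amb', top)."""
    if not profile.peaks:
        return ("amb", None)
    (s1, i1), (s2, i2), (s3, i3) = profile.top3()
    if abs(i2 - i3) <= t.intensity_gap:
        return ("hom", (s1, s1))
    if abs(i2 - i3) >= t.intensity_gap and i2 > t.het_ratio * i1:
        pair = tuple(sorted((s1, s2), reverse=True))
        return ("het", pair)
    return ("amb", s1)


def call_locus_genotype(
    triplicate: PeakTriplicate, thresholds: CallThresholds = CallThresholds()
) -> GenotypeCall:
    """Final diploid call for one clone x locus from its three replicates.

    The call must be identical across all three replicates; otherwise the
    locus is ambiguous.  When the top-intensity allele agrees across
    replicates the ambiguous call retains it (e.g. ``106/X``), else ``X/X``.
    """
    calls = [_call_replicate(p, thresholds) for p in triplicate.replicates]
    statuses = {c[0] for c in calls}
    alleles = {c[1] for c in calls}
    if statuses == {"hom"} and len(alleles) == 1:
        a = calls[0][1][0]
        return GenotypeCall(a, a)
    if statuses == {"het"} and len(alleles) == 1:
        a, b = calls[0][1]
        return GenotypeCall(a, b)
    tops = {p.top3()[0][0] for p in triplicate.replicates}
    if len(tops) == 1 and None not in tops:
        return GenotypeCall(tops.pop(), None)
    return GenotypeCall(None, None)


# ---------------------------------------------------------------------------
# peak tables


def read_peak_table(path: str | Path) -> dict[tuple[str, str], PeakTriplicate]:
    """Read a TSV of columns (clone, locus, replicate, size, intensity)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], PeakTriplicate] = {}
    for (clone, locus), grp in df.groupby(["clone", "locus"], sort=False):
        reps = []
        for r in sorted(grp["replicate"].unique()):
            sub = grp[grp["replicate"] == r]
            reps.append(PeakProfile(zip(sub["size"], sub["intensity"])))
        if len(reps) != 3:
            raise ValueError(f"clone {clone}, locus {locus}: expected 3 replicates")
        out[(str(clone), str(locus))] = PeakTriplicate(tuple(reps))
    return out


def call_genotype_matrix(
    peaks: Mapping[tuple[str, str], PeakTriplicate],
    thresholds: CallThresholds = CallThresholds(),
    meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Call every (clone, locus) triplicate into a GenotypeMatrix."""
    clones = list(dict.fromkeys(c for c, _ in peaks))
    loci = list(dict.fromkeys(l for _, l in peaks))
    alleles = np.full((len(clones), len(loci), 2), MISSING, dtype=np.int32)
    for (clone, locus), trip in peaks.items():
        call = call_locus_genotype(trip, thresholds)
        i, j = clones.index(clone), loci.index(locus)
        alleles[i, j, 0] = MISSING if call.allele_a is None else call.allele_a
        alleles[i, j, 1] = MISSING if call.allele_b is None else call.allele_b
    return GenotypeMatrix(alleles, clones, loci, meta)


# ---------------------------------------------------------------------------
# parental assignment / consensus


def _locus_founders(col: np.ndarray) -> tuple[int, int]:
    """Two most frequent allele lengths at a locus (ties -> smaller length)."""
    obs = col[col >= 0]
    if obs.size == 0:
        return (MISSING, MISSING)
    counts = Counter(int(a) for a in obs)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    f0 = ranked[0][0]
    f1 = ranked[1][0] if len(ranked) > 1 else f0
    return (f0, f1)


def assign_parental_alleles(matrix: GenotypeMatrix):
    """Orient each diploid call so slot 0 tracks one parental founder allele
    and slot 1 the other, minimising total absolute deviation from the
    founders.

    Founders per locus are the two most frequent observed allele lengths
    (a single founder when the locus is monomorphic).  Returns the oriented
    matrix and a founders table (loci with no calls are flagged missing).
    """
    if matrix.n_clones < 2:
        raise ValueError("parental assignment needs at least two clones")
    alleles = matrix.alleles.copy()
    founders = np.empty((matrix.n_loci, 2), dtype=np.int32)
    for j in range(matrix.n_loci):
        f0, f1 = _locus_founders(matrix.alleles[:, j, :].ravel())
        founders[j] = (f0, f1)
        if f0 == MISSING:
            continue
        for i in range(matrix.n_clones):
            a, b = (int(x) for x in alleles[i, j])
            if a < 0 and b < 0:
                continue
            if a < 0 or b < 0:
                known = b if a < 0 else a
                # known allele goes to the closer founder
                if abs(known - f0) <= abs(known - f1):
                    alleles[i, j] = (known, MISSING)
                else:
                    alleles[i, j] = (MISSING, known)
                continue
            direct = abs(a - f0) + abs(b - f1)
            swapped = abs(a - f1) + abs(b - f0)
            alleles[i, j] = (a, b) if direct <= swapped else (b, a)
    oriented = GenotypeMatrix(
        alleles, list(matrix.clone_ids), list(matrix.locus_ids), matrix.meta.copy()
    )
    founder_table = pd.DataFrame(
        founders, index=matrix.locus_ids, columns=["founder_a", "founder_b"]
    )
    return oriented, founder_table


def consensus_genotype(
    matrix: GenotypeMatrix, clones: Sequence[str] | None = None
) -> np.ndarray:
    """Per-locus, per-slot modal non-missing allele over a clone subset.

    Ties break to the smaller allele length; a slot with no non-missing
    calls in the subset stays missing.  Returns an ``(n_loci, 2)`` array.
    """
    sub = matrix if clones is None else matrix.select_clones(clones)
    if sub.n_clones == 0:
        raise ValueError("consensus over an empty clone subset")
    out = np.full((sub.n_loci, 2), MISSING, dtype=np.int32)
    for j in range(sub.n_loci):
        for slot in range(2):
            col = sub.alleles[:, j, slot]
            obs = col[col >= 0]
            if obs.size == 0:
                continue
            counts = Counter(int(a) for a in obs)
            out[j, slot] = min(
                counts, key=lambda a: (-counts[a], a)
            )
    return out


# ---------------------------------------------------------------------------
# mutation summaries


def _locus_mismatches(g: np.ndarray, ref: np.ndarray) -> int:
    """Minimum number of differing non-missing alleles over the two pairings."""

    def mism(x, y) -> int | None:
        if x < 0 or y < 0:
            return None  # uninformative comparison
        return int(x != y)

    best = None
    for pairing in ((0, 1), (1, 0)):
        total = 0
        for slot in range(2):
            m = mism(g[slot], ref[pairing[slot]])
            if m is not None:
                total += m
        best = total if best is None else min(best, total)
    return best or 0


@dataclass
class MutationSummary:
    """Per-clone / per-locus somatic mutation profile of a genotype matrix."""

    per_clone: pd.DataFrame   # n_mutant_alleles, n_mutated_loci, fraction_mutated
    per_locus: pd.DataFrame   # n_distinct_mutant_alleles
    mean_mutant_alleles_per_locus_per_cell: float
    mean_fraction_mutated: float


def identify_somatic_mutations(
    matrix: GenotypeMatrix, reference: np.ndarray
) -> MutationSummary:
    """Mutations are non-missing alleles differing from the reference allele
    of their (best-pairing) parental slot.

    Returns per-clone counts and fractions of mutated loci, per-locus counts
    of distinct mutant alleles, and the mean number of mutant alleles per
    locus per cell.
    """
    reference = np.asarray(reference)
    if reference.shape != (matrix.n_loci, 2):
        raise ValueError("reference must cover the matrix loci")
    n_clones, n_loci = matrix.n_clones, matrix.n_loci
    clone_mut = np.zeros(n_clones, dtype=int)
    clone_loci = np.zeros(n_clones, dtype=int)
    clone_usable = np.zeros(n_clones, dtype=int)
    locus_alleles: list[set[int]] = [set() for _ in range(n_loci)]
    for i in range(n_clones):
        for j in range(n_loci):
            g = matrix.alleles[i, j]
            if g[0] < 0 and g[1] < 0:
                continue
            clone_usable[i] += 1
            m = _locus_mismatches(g, reference[j])
            clone_mut[i] += m
            if m:
                clone_loci[i] += 1
                refset = {int(a) for a in reference[j] if a >= 0}
                for a in g:
                    if a >= 0 and int(a) not in refset:
                        locus_alleles[j].add(int(a))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(clone_usable > 0, clone_loci / np.maximum(clone_usable, 1), np.nan)
    per_clone = pd.DataFrame(
        {
            "n_mutant_alleles": clone_mut,
            "n_mutated_loci": clone_loci,
            "n_usable_loci": clone_usable,
            "fraction_mutated": frac,
        },
        index=matrix.clone_ids,
    )
    per_locus = pd.DataFrame(
        {"n_distinct_mutant_alleles": [len(s) for s in locus_alleles]},
        index=matrix.locus_ids,
    )
    return MutationSummary(
        per_clone=per_clone,
        per_locus=per_locus,
        mean_mutant_alleles_per_locus_per_cell=float(clone_mut.sum() / (n_clones * n_loci)),
        mean_fraction_mutated=float(np.nanmean(frac)),
    )


@dataclass
class MutationRateEstimate:
    """Pooled mutation-rate estimate from a subclone passaging experiment."""

    rate: float                  # mutations per locus per division (corrected)
    rate_raw: float              # simple ratio: visible changes / (loci x divisions)
    per_subclone: pd.DataFrame   # n_new_mutations, n_usable_loci, rate
    se: float                    # SE of the pooled mean over subclones
    doublings: int


def _expected_visible_changes(mu: float, divisions: int) -> float:
    """Expected visible length change (repeat units) per locus after a
    number of divisions, under per-locus Bernoulli(mu) single-unit
    slippage with +1/-1 equally likely.

    Opposite-direction events on the same allele cancel, so the visible
    change falls short of the event count: per allele the net displacement
    is a +/-1 random walk with Binomial(divisions, mu/2) steps.
    """
    half = mu / 2.0
    pk = stats.binom.pmf(np.arange(divisions + 1), divisions, half)
    e_abs = np.empty(divisions + 1)
    for k in range(divisions + 1):
        j = np.arange(k + 1)
        e_abs[k] = float(np.sum(stats.binom.pmf(j, k, 0.5) * np.abs(2 * j - k)))
    return 2.0 * float(np.sum(pk * e_abs))


def estimate_mutation_rate(
    matrix: GenotypeMatrix,
    doublings: int,
    parent: str = "parent",
    cancellation_correction: bool = True,
) -> MutationRateEstimate:
    """Rate = new mutations (absent from the parent) per locus per
    division, pooled over subclones; per-subclone rates give the SE.

    Mutations are counted as repeat units of length change under the
    minimal allele pairing: polyG slippage shifts length by one unit per
    event, so a +2 bp allele records two mutations.  This is the counting
    under which the molecular clock D = mu x divisions is consistent with
    the genetic-distance definition.

    With ``cancellation_correction`` (default) the pooled rate is the
    method-of-moments inversion of the expected visible change under
    single-unit stepwise slippage, compensating for opposite-direction
    events that cancel within a lineage; ``rate_raw`` always reports the
    uncorrected simple ratio.
    """
    from .distance import _locus_contribution

    if doublings <= 0:
        raise ValueError("doublings must be positive")
    if parent not in matrix.clone_ids:
        raise ValueError(f"parent clone {parent!r} not in matrix")
    pg = matrix.genotype_of(parent)
    rows = []
    for cid in matrix.clone_ids:
        if cid == parent:
            continue
        g = matrix.genotype_of(cid)
        new = 0
        usable = 0
        for j in range(matrix.n_loci):
            contrib = _locus_contribution(g[j], pg[j])
            if contrib is None:
                continue
            usable += 1
            new += int(contrib)
        rows.append((cid, new, usable))
    per = pd.DataFrame(rows, columns=["subclone", "n_new_mutations", "n_usable_loci"])
    per = per.set_index("subclone")
    if per["n_usable_loci"].sum() == 0:
        raise ValueError("no usable loci shared with the parent")
    per["rate"] = per["n_new_mutations"] / (per["n_usable_loci"] * doublings)
    rate_raw = float(
        per["n_new_mutations"].sum() / (per["n_usable_loci"].sum() * doublings)
    )
    rate = rate_raw
    if cancellation_correction and rate_raw > 0:
        visible_per_locus = float(
            per["n_new_mutations"].sum() / per["n_usable_loci"].sum()
        )
        from scipy.optimize import brentq

        upper = min(1.0, 4 * rate_raw + 0.05)
        if _expected_visible_changes(upper, doublings) > visible_per_locus:
            rate = float(
                brentq(
                    lambda m: _expected_visible_changes(m, doublings) - visible_per_locus,
                    0.0,
                    upper,
                )
            )
    correction = rate / rate_raw if rate_raw > 0 else 1.0
    per["rate"] *= correction
    n = len(per)
    se = float(per["rate"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return MutationRateEstimate(
        rate=rate, rate_raw=rate_raw, per_subclone=per, se=se, doublings=doublings
    )
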