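"""Genotype matrices of single-cell clones at polyguanine (polyG) loci.

The central object of the pipeline is a rectangular matrix of diploid
allele-length calls (in bp) for ``n_clones x n_loci``, with per-clone
metadata (tissue, body side, individual, split-clone pair).  Cells are
written on disk in the ``"106/105"`` convention, with ``"X"`` marking a
missing (ambiguous) allele call, e.g. ``"106/X"`` or ``"X/X"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel used internally for a missing allele call.
MISSING = -1

META_COLUMNS = ["tissue", "side", "mouse", "split_pair"]

_CELL_RE = re.compile(r"^\s*(\d+|X)\s*/\s*(\d+|X)\s*$")


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call at one locus.

    ``allele_a``/``allele_b`` are fragment lengths in bp, or ``None`` when
    the call is missing ("X").
    """

    allele_a: int | None
    allele_b: int | None

    @property
    def status(self) -> str:
        if self.allele_a is None or self.allele_b is None:
            return "ambiguous"
        return "homozygous" if self.allele_a == self.allele_b else "heterozygous"

    def __str__(self) -> str:
        fmt = lambda a: "X" if a is None else str(a)
        return f"{fmt(self.allele_a)}/{fmt(self.allele_b)}"


def parse_cell(text: str, *, clone: str = "?", locus: str = "?") -> tuple[int, int]:
    """Parse a ``"a/b"`` genotype cell into an allele pair (MISSING for X)."""
    m = _CELL_RE.match(str(text))
    if m is None:
        raise ValueError(
            f"unparseable genotype cell {text!r} at clone {clone!r}, locus {locus!r}"
        )
    return tuple(MISSING if g == "X" else int(g) for g in m.groups())  # type: ignore[return-value]


def format_cell(pair: Sequence[int]) -> str:
    return "/".join("X" if a < 0 else str(int(a)) for a in pair)


class GenotypeMatrix:
    """Clones x loci diploid allele-length calls plus clone metadata.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_clones, n_loci, 2)``; ``MISSING`` (-1)
        marks an "X" allele call.
    clone_ids, locus_ids
        Unique row/column identifiers.
    meta
        Optional per-clone table with columns among ``tissue``, ``side``,
        ``mouse``, ``split_pair``; reindexed to ``clone_ids``.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        clone_ids: Sequence[str],
        locus_ids: Sequence[str],
        meta: pd.DataFrame | None = None,
    ):
        alleles = np.asarray(alleles, dtype=np.int32)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_clones, n_loci, 2)")
        clone_ids = [str(c) for c in clone_ids]
        locus_ids = [str(l) for l in locus_ids]
        if alleles.shape[0] != len(clone_ids) or alleles.shape[1] != len(locus_ids):
            raise ValueError("alleles shape does not match id lists")
        if len(set(clone_ids)) != len(clone_ids):
            raise ValueError("clone ids must be unique")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("locus ids must be unique")
        self.alleles = alleles
        self.clone_ids = clone_ids
        self.locus_ids = locus_ids
        if meta is None:
            meta = pd.DataFrame(index=clone_ids)
        meta = meta.reindex(clone_ids)
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        self.meta = meta[META_COLUMNS].fillna("")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_clones(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_clones} clones x {self.n_loci} loci)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.clone_ids == other.clone_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.alleles, other.alleles)
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.alleles.copy(), list(self.clone_ids), list(self.locus_ids), self.meta.copy()
        )

    def call(self, clone: str, locus: str) -> GenotypeCall:
        i = self.clone_ids.index(clone)
        j = self.locus_ids.index(locus)
        a, b = (int(x) for x in self.alleles[i, j])
        return GenotypeCall(None if a < 0 else a, None if b < 0 else b)

    def genotype_of(self, clone: str) -> np.ndarray:
        """Return the ``(n_loci, 2)`` allele array of one clone."""
        return self.alleles[self.clone_ids.index(clone)]

    def select_clones(self, clones: Iterable[str]) -> "GenotypeMatrix":
        clones = list(clones)
        idx = [self.clone_ids.index(c) for c in clones]
        return GenotypeMatrix(
            self.alleles[idx], clones, list(self.locus_ids), self.meta.loc[clones]
        )

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_clones, n_loci, 2)`` mask of missing allele calls."""
        return self.alleles < 0

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cells = np.empty((self.n_clones, self.n_loci), dtype=object)
        for i in range(self.n_clones):
            for j in range(self.n_loci):
                cells[i, j] = format_cell(self.alleles[i, j])
        return pd.DataFrame(cells, index=self.clone_ids, columns=self.locus_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, meta: pd.DataFrame | None = None
    ) -> "GenotypeMatrix":
        clone_ids = [str(c) for c in frame.index]
        locus_ids = [str(l) for l in frame.columns]
        alleles = np.empty((len(clone_ids), len(locus_ids), 2), dtype=np.int32)
        for i, clone in enumerate(clone_ids):
            for j, locus in enumerate(locus_ids):
                alleles[i, j] = parse_cell(frame.iat[i, j], clone=clone, locus=locus)
        return cls(alleles, clone_ids, locus_ids, meta)

    def write_tsv(self, path: str | Path, sample_sheet: str | Path | None = None) -> None:
        frame = self.to_frame()
        frame.index.name = "clone"
        frame.to_csv(path, sep="\t")
        if sample_sheet is not None:
            meta = self.meta.copy()
            meta.index.name = "clone"
            meta.to_csv(sample_sheet, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, sample_sheet: str | Path | None = None
    ) -> "GenotypeMatrix":
        sep = "," if str(path).endswith(".csv") else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        meta = None
        if sample_sheet is not None:
            meta = pd.read_csv(sample_sheet, sep="\t", index_col=0, dtype=str)
        return cls.from_frame(frame, meta)
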