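"""Modified eBURST clustering of clones into clonal complexes.

Classical eBURST groups haploid multilocus genotypes by single-locus
variants; this diploid adaptation instead links any two clones whose
genetic distance falls at or below a threshold, takes connected components
as clonal complexes, and names as founder the member linked to the most
other members (ties: smallest mean distance to members, then clone id).
The default threshold 0.2 corresponds to ~15 cell divisions at a mutation
rate of 0.013 per locus per division.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distance import ClockModel, DistanceMatrix


@dataclass
class EburstConfig:
    threshold: float = 0.2
    clock: ClockModel | None = None

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class ClonalComplex:
    members: list[str]
    links: list[tuple[str, str, float]]
    founder: str
    link_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EburstResult:
    complexes: list[ClonalComplex]
    singletons: list[str]
    graph: nx.Graph
    config: EburstConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, cc in enumerate(self.complexes, start=1):
            for m in cc.members:
                rows.append(
                    {
                        "complex": f"CC{k}",
                        "member": m,
                        "is_founder": m == cc.founder,
                        "n_links": cc.link_counts.get(m, 0),
                    }
                )
        for s in self.singletons:
            rows.append(
                {"complex": "singleton", "member": s, "is_founder": False, "n_links": 0}
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_edge_list(self, path: str | Path) -> None:
        rows = [
            {"clone_a": a, "clone_b": b, "distance": d}
            for cc in self.complexes
            for a, b, d in cc.links
        ]
        pd.DataFrame(rows, columns=["clone_a", "clone_b", "distance"]).to_csv(
            path, sep="\t", index=False
        )


def build_clonal_complexes(
    dm: DistanceMatrix, config: EburstConfig = EburstConfig()
) -> EburstResult:
    """Connected components of the graph linking pairs with distance <=
    threshold; undefined (nan) distances are treated as unlinked."""
    g = nx.Graph()
    g.add_nodes_from(dm.clone_ids)
    n = len(dm.clone_ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.values[i, j]
            if np.isfinite(d) and d <= config.threshold:
                g.add_edge(dm.clone_ids[i], dm.clone_ids[j], distance=float(d))
    complexes: list[ClonalComplex] = []
    singletons: list[str] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            singletons.append(members[0])
            continue
        links = sorted(
            (min(a, b), max(a, b), g.edges[a, b]["distance"])
            for a, b in g.subgraph(members).edges
        )
        counts = {m: g.degree[m] for m in members}

        def founder_key(m: str):
            mean_d = float(
                np.mean([g.edges[m, o]["distance"] for o in g.neighbors(m)])
            )
            return (-counts[m], mean_d, m)

        founder = min(members, key=founder_key)
        complexes.append(
            ClonalComplex(members=members, links=links, founder=founder, link_counts=counts)
        )
    complexes.sort(key=lambda cc: (-len(cc.members), cc.members[0]))
    singletons.sort()
    return EburstResult(
        complexes=complexes, singletons=singletons, graph=g, config=config
    )


def threshold_in_divisions(config: EburstConfig) -> float:
    """Mitotic-separation equivalent of the distance threshold."""
    if config.clock is None:
        raise ValueError("config.clock must be set")
    return config.threshold / config.clock.mu


def cross_tissue_links(result: EburstResult, meta: pd.DataFrame) -> pd.DataFrame:
    """Complex links joining clones from different tissues or body sides —
    candidate cell-migration events."""
    rows = []
    for k, cc in enumerate(result.complexes, start=1):
        for a, b, d in cc.links:
            ta, sa = meta.loc[a, "tissue"], meta.loc[a, "side"]
            tb, sb = meta.loc[b, "tissue"], meta.loc[b, "side"]
            if ta != tb or sa != sb:
                rows.append(
                    {
                        "complex": f"CC{k}",
                        "clone_a": a,
                        "tissue_a": ta,
                        "side_a": sa,
                        "clone_b": b,
                        "tissue_b": tb,
                        "side_b": sb,
                        "distance": d,
                        "contralateral": ta == tb and sa != sb,
                    }
                )
    columns = [
        "complex", "clone_a", "tissue_a", "side_a",
        "clone_b", "tissue_b", "side_b", "distance", "contralateral",
    ]
    return pd.DataFrame(rows, columns=columns)
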