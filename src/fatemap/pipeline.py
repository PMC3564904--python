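"""End-to-end orchestration: simulate (or ingest) genotypes, then run the
mutation-profile, distance, eBURST, network and tree-shape analyses and
write every result, with a machine-readable manifest carrying the seed and
a configuration hash for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import consensus_genotype, identify_somatic_mutations
from .distance import (
    ClockModel,
    distance_matrix,
    distance_to_reference,
    tissue_distance_summary,
)
from .eburst import EburstConfig, build_clonal_complexes, cross_tissue_links, threshold_in_divisions
from .genotypes import GenotypeMatrix
from .network import build_similarity_network, write_edge_list
from .simulate import SimulationConfig, simulate_lineage
from .treeshape import shape_null_comparison

log = logging.getLogger("fatemap")


@dataclass
class PipelineConfig:
    """Everything needed to re-run one analysis.

    Exactly one of ``genotype_table`` (with optional ``sample_sheet``) or
    ``simulation`` must be set.
    """

    genotype_table: str | None = None
    sample_sheet: str | None = None
    simulation: SimulationConfig | None = None
    clock: ClockModel = field(default_factory=lambda: ClockModel(mu=0.013))
    eburst_threshold: float = 0.2
    network_alpha: float = 0.05
    network_permutations: int = 200
    shape_randomizations: int = 100
    out_dir: str = "fatemap_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.genotype_table is None) == (self.simulation is None):
            raise ValueError(
                "set exactly one of genotype_table or simulation in PipelineConfig"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"]["step_probabilities"] = {
                str(k): v for k, v in self.simulation.step_probabilities.items()
            }
        d["clock"] = {"mu": self.clock.mu}
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    outputs: dict[str, str] = {}

    def register(name: str, fname: str) -> Path:
        outputs[name] = fname
        return out / fname

    # --- input ------------------------------------------------------------
    if config.simulation is not None:
        sim_config = dataclasses.replace(config.simulation, seed=int(seeds[0]))
        log.info("simulating lineage (seed %d)", sim_config.seed)
        sim = simulate_lineage(sim_config)
        matrix = sim.matrix
        matrix.write_tsv(
            register("genotypes", "genotypes.tsv"),
            register("samples", "samples.tsv"),
        )
        register("truth_tree", "truth_tree.nwk").write_text(sim.newick)
        sim.true_separations.to_csv(
            register("truth_separations", "truth_separations.tsv"), sep="\t"
        )
    else:
        log.info("reading genotype table %s", config.genotype_table)
        matrix = GenotypeMatrix.read_tsv(config.genotype_table, config.sample_sheet)

    # --- mutation profile ----------------------------------------------------
    zygote = consensus_genotype(matrix)
    summary = identify_somatic_mutations(matrix, zygote)
    summary.per_clone.to_csv(register("per_clone_mutations", "per_clone_mutations.tsv"), sep="\t")
    summary.per_locus.to_csv(register("per_locus_mutations", "per_locus_mutations.tsv"), sep="\t")

    # --- distances ----------------------------------------------------------
    dm = distance_matrix(matrix)
    dm.write_tsv(register("distance_matrix", "distance_matrix.tsv"))
    dm.write_phylip(register("distance_phylip", "distance_matrix.phylip"))
    zd = distance_to_reference(matrix, zygote)
    tsum = tissue_distance_summary(dm, matrix.meta, zd)
    tsum.table.to_csv(register("tissue_summary", "tissue_summary.tsv"), sep="\t", index=False)

    # --- eBURST --------------------------------------------------------------
    econf = EburstConfig(threshold=config.eburst_threshold, clock=config.clock)
    eb = build_clonal_complexes(dm, econf)
    eb.write_tsv(register("clonal_complexes", "clonal_complexes.tsv"))
    eb.write_edge_list(register("complex_links", "complex_links.tsv"))
    migration = cross_tissue_links(eb, matrix.meta)
    migration.to_csv(register("cross_tissue_links", "cross_tissue_links.tsv"), sep="\t", index=False)

    # --- similarity network --------------------------------------------------
    net = build_similarity_network(
        matrix,
        alpha=config.network_alpha,
        n_permutations=config.network_permutations,
        seed=int(seeds[1]),
    )
    write_edge_list(net, register("network_edges", "network_edges.tsv"))

    # --- tree shape ------------------------------------------------------------
    shape = shape_null_comparison(
        matrix, n_randomizations=config.shape_randomizations, seed=int(seeds[2])
    )
    shape.observed.to_csv(register("shape_observed", "shape_observed.tsv"), sep="\t", index=False)
    shape.null.to_csv(register("shape_null", "shape_null.tsv"), sep="\t", index=False)

    manifest = {
        "fatemap_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "n_clones": matrix.n_clones,
        "n_loci": matrix.n_loci,
        "results": {
            "mean_mutant_alleles_per_locus_per_cell": summary.mean_mutant_alleles_per_locus_per_cell,
            "mean_fraction_mutated": summary.mean_fraction_mutated,
            "global_mean_distance": tsum.global_mean,
            "eburst_threshold_divisions": threshold_in_divisions(econf),
            "n_complexes": len(eb.complexes),
            "n_singletons": len(eb.singletons),
            "n_cross_tissue_links": int(len(migration)),
            "n_network_edges": net.number_of_edges(),
            "nbar_shift": shape.nbar_shift,
            "nbar_p": shape.nbar_p,
        },
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
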