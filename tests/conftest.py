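import numpy as np
import pandas as pd
import pytest

from fatemap import GenotypeMatrix, SimulationConfig, simulate_lineage


@pytest.fixture(scope="session")
def small_lineage():
    """A compact simulated individual shared by read-only tests."""
    return simulate_lineage(
        SimulationConfig(n_loci=60, cells_per_tissue=8, seed=1234)
    )


@pytest.fixture()
def tiny_matrix():
    """Three clones x two loci, hand-written calls."""
    frame = pd.DataFrame(
        {
            "L1": ["106/108", "106/106", "106/X"],
            "L2": ["200/200", "200/202", "X/X"],
        },
        index=["a", "b", "c"],
    )
    meta = pd.DataFrame(
        {"tissue": ["fib", "fib", "pre"], "side": ["L", "L", "R"]},
        index=["a", "b", "c"],
    )
    return GenotypeMatrix.from_frame(frame, meta)


def random_diploid_pair(rng, n_loci=5, missing_rate=0.2, span=6):
    """Random genotype pair with missing calls, for oracle comparisons."""
    base = rng.integers(100, 100 + span, size=(2, n_loci, 2))
    mask = rng.random((2, n_loci, 2)) < missing_rate
    base[mask] = -1
    return base[0].astype(np.int32), base[1].astype(np.int32)
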