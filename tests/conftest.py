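import numpy as np
import pytest

from cageforge import sim
from cageforge.ctss import CtssTable


@pytest.fixture(scope="session")
def small_genome():
    return sim.generate_genome(seed=3, n_chrom=1, length=10_000, gc=0.45)


@pytest.fixture(scope="session")
def promoter_dataset():
    """500 promoters, 4 samples, moderate depth; no shifts, light noise."""
    specs = sim.generate_promoterome(seed=5, n_promoters=500,
                                     sharp_fraction=0.5, alpha=1.25,
                                     n_samples=4, genome_length=200_000)
    table, truth, _ = sim.generate_ctss(specs, seed=5, depth_per_sample=50_000,
                                        noise_rate=0.02,
                                        genome_length=200_000)
    return specs, table, truth


@pytest.fixture
def tiny_table():
    """Two samples, handful of CTSSs on both strands."""
    recs = [("chr1", 100, "+"), ("chr1", 105, "+"), ("chr1", 130, "+"),
            ("chr1", 200, "-"), ("chr1", 202, "-"), ("chr2", 50, "+")]
    counts = np.array([[5, 1], [3, 0], [2, 4], [7, 2], [1, 1], [4, 9]],
                      dtype=float)
    return CtssTable.from_records(recs, counts, ["s1", "s2"])
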