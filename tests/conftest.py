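import numpy as np
import pandas as pd
import pytest

from quidsig import simulate as sim
from quidsig.catalog import MutationCatalog, ReferenceGenome, RegionSet


@pytest.fixture(scope="session")
def small_genome():
    """A 300 kb chromosome with 3 CpG islands, shared across tests."""
    spec = sim.GenomeSpec(length=300_000, n_islands=3)
    genome, islands = sim.simulate_genome(spec, seed=11)
    return genome, islands, spec


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """A 4-sample cohort of 800 mutations each on the small genome."""
    genome, islands, spec = small_genome
    prof = sim.CohortProfile(
        name="toy",
        n_samples=4,
        mixture_means=(0.53, 0.09, 0.38),
        genome=spec,
    )
    return sim.simulate_cohort(
        prof, seed=5, n_mut_per_sample=800, genome=genome, islands=islands
    )


@pytest.fixture()
def tiny_genome():
    """A hand-written genome for exact-arithmetic checks."""
    return ReferenceGenome({"chr1": "ACGTACGTACGTACGTACGT"})


@pytest.fixture()
def tiny_catalog():
    rows = [
        ("s1", "1", 2, "C", "T"),
        ("s1", "1", 6, "C", "A"),
        ("s2", "1", 3, "G", "A"),
    ]
    return MutationCatalog(
        pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    )
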