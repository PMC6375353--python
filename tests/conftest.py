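import numpy as np
import pytest

from sexscan.io_core import GenotypeMatrix
from sexscan.simulate import SimConfig, simulate_cohort


def make_matrix(genotypes, contig="chr1", positions=None, samples=None):
    """Small GenotypeMatrix from a (sites x samples) list of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        list(samples),
        np.array([contig] * n_sites, dtype=str),
        np.asarray(positions, dtype=np.int64),
        np.array(["A"] * n_sites, dtype=object),
        np.array(["T"] * n_sites, dtype=object),
        g,
    )


def small_sim_config(seed=11, **overrides):
    """A fast cohort: three 100 kb contigs, sd region on c2."""
    params = dict(
        seed=seed,
        contigs={"c1": 100_000, "c2": 100_000, "c3": 100_000},
        sd_region=("c2", 20_000, 80_000),
        n_y_insertions=3,
        y_insertion_length=1_500,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def xy_cohort():
    """One shared small simulated XX-XY cohort (seeded)."""
    return simulate_cohort(small_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
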