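import numpy as np
import pytest

from breedarch import simdata
from breedarch.markers import GenotypeMatrix
from breedarch.noia import build_kernels, noia_coding


@pytest.fixture
def toy_genotypes():
    """Four individuals, one locus with genotype frequencies (1/4, 1/2, 1/4)."""
    return GenotypeMatrix(
        np.array([[2], [1], [1], [0]], dtype=np.int8),
        chrom=["chr1"], pos=[100], ids=["i1", "i2", "i3", "i4"],
    )


def random_genotypes(rng, n, L, missing_rate=0.0):
    """Random genotype matrix with arbitrary genotype frequencies (no HWE)."""
    probs = rng.dirichlet(np.ones(3), size=L)  # per-locus (p0, p1, p2)
    u = rng.random((n, L))
    c = np.cumsum(probs, axis=1)
    codes = (u[..., None] > c[None, :, :]).sum(axis=2).astype(np.int8)
    if missing_rate > 0:
        codes[rng.random((n, L)) < missing_rate] = -1
    return GenotypeMatrix(
        codes,
        chrom=np.repeat("chr1", L),
        pos=np.arange(1, L + 1) * 1000,
        ids=np.array([f"i{i}" for i in range(n)]),
    )


@pytest.fixture(scope="session")
def breeding_pop():
    """Small breeding population (~200 S0 individuals, 150 markers)."""
    panel = simdata.simulate_founders(n_chrom=5, markers_per_chrom=30, seed=101)
    plan = simdata.default_plan(panel, n_families=50, sibs_per_family=4, seed=102)
    geno, ped = simdata.simulate_breeding_population(panel, plan, seed=103)
    return geno, ped


@pytest.fixture(scope="session")
def breeding_design(breeding_pop):
    geno, _ = breeding_pop
    return noia_coding(geno)


@pytest.fixture(scope="session")
def breeding_kernels(breeding_pop):
    geno, _ = breeding_pop
    return build_kernels(geno, with_gk=True)
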