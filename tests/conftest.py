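import numpy as np
import pytest
from shapely.geometry import Polygon

from camelroutes.genotype_io import GenotypeMatrix
from camelroutes.synthetic_data import IslandModelSpec, simulate_island_genotypes


@pytest.fixture(scope="session")
def island_3pop():
    """Strongly structured 3-population cohort (FST 0.2)."""
    spec = IslandModelSpec(n_pops=3, n_per_pop=20, n_snps=300, fst=0.2, seed=42)
    return simulate_island_genotypes(spec)


@pytest.fixture(scope="session")
def island_unstructured():
    """Panmictic cohort split into two nominal populations (FST 0)."""
    spec = IslandModelSpec(n_pops=2, n_per_pop=30, n_snps=300, fst=0.0, seed=43)
    return simulate_island_genotypes(spec)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized genotype matrix: 4 individuals, 3 SNPs, one missing call."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],
            [0, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["i1", "i2", "i3", "i4"], ["s1", "s2", "s3"], calls)


@pytest.fixture(scope="session")
def rectangle_polygon():
    return Polygon([(0, 0), (10, 0), (10, 5), (0, 5)])
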