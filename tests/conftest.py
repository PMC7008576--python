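import numpy as np
import pytest

from breedsim import Population, build_genome, read_vcf
from breedsim.fixtures import make_fixture


@pytest.fixture(scope="session")
def diploid_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("diploid")
    return make_fixture(d, n_founders=20, n_chrom=2, n_snps=100, ploidy=2, seed=1)


@pytest.fixture(scope="session")
def tetraploid_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("tetra")
    return make_fixture(d, n_founders=12, n_chrom=2, n_snps=80, ploidy=4, seed=2)


@pytest.fixture(scope="session")
def sexed_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("sexed")
    return make_fixture(
        d, n_founders=20, n_chrom=2, n_snps=100, ploidy=2,
        sex_chrom=True, mito=True, seed=3,
    )


@pytest.fixture(scope="session")
def diploid_data(diploid_paths):
    fh, meta = read_vcf(diploid_paths["vcf"])
    genome = build_genome(meta)
    return fh, meta, genome


@pytest.fixture(scope="session")
def tetraploid_data(tetraploid_paths):
    fh, meta = read_vcf(tetraploid_paths["vcf"])
    genome = build_genome(meta)
    return fh, meta, genome


@pytest.fixture(scope="session")
def sexed_data(sexed_paths):
    fh, meta = read_vcf(sexed_paths["vcf"])
    genome = build_genome(meta)
    return fh, meta, genome


@pytest.fixture
def diploid_pop(diploid_data):
    fh, meta, genome = diploid_data
    return Population(genome, fh)


@pytest.fixture
def sexed_pop(sexed_data):
    fh, meta, genome = sexed_data
    return Population(genome, fh)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
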