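"""Meiosis and the block representation.

The central correctness check: decoding block-represented genomes must
equal a naive simulator that propagates full per-SNP allele vectors
through the exact same meioses. Each meiosis records its stochastic plan
(bivalent pairing, crossover positions, strand choices) in a trace; the
naive simulator replays that plan on allele vectors, so the two paths
share the randomness but none of the block machinery.
"""

import numpy as np
import pytest

from breedsim import Population, build_genome, read_vcf
from breedsim.fixtures import make_fixture
from breedsim.genome import GeneticMap
from breedsim.meiosis import Homolog, recombine


from oracles import (
    _founder_allele_vectors,
    _naive_gamete,
    _run_oracle_pedigree,
    _split_trace,
)


@pytest.mark.parametrize("fixture_name", ["diploid_paths", "tetraploid_paths"])
def test_block_decode_equals_allele_propagation(fixture_name, request):
    """5-generation pedigree: block decode == naive allele propagation."""
    paths = request.getfixturevalue(fixture_name)
    pop, vecs = _run_oracle_pedigree(paths)
    genome = pop.genome
    dec = pop.decode()
    for ind in pop.individuals:
        expected = np.concatenate(
            [np.sum(vecs[ind.id][ci], axis=0) for ci in range(genome.n_chrom)]
        )
        # fixture SNPs are already in (chrom, position) order
        np.testing.assert_array_equal(dec[ind.id], expected,
                                      err_msg=f"individual {ind.id}")


# --------------------------------------------------------------------------
# recombine() mechanics
# --------------------------------------------------------------------------

class TestRecombine:
    def test_no_crossover_returns_a_parental_homolog(self):
        h1 = Homolog([100.0], [0])
        h2 = Homolog([100.0], [1])
        assert recombine(h1, h2, np.empty(0), 0) == h1
        assert recombine(h1, h2, np.empty(0), 1) == h2

    def test_single_crossover_switches_template(self):
        h1 = Homolog([100.0], [0])
        h2 = Homolog([100.0], [1])
        out = recombine(h1, h2, np.array([40.0]), 0)
        assert list(out.ends) == [40.0, 100.0]
        assert list(out.haps) == [0, 1]

    def test_two_crossovers_return_to_start_template(self):
        h1 = Homolog([100.0], [0])
        h2 = Homolog([100.0], [1])
        out = recombine(h1, h2, np.array([30.0, 60.0]), 0)
        assert list(out.haps) == [0, 1, 0]

    def test_crossover_at_existing_boundary(self):
        h1 = Homolog([50.0, 100.0], [0, 1])
        h2 = Homolog([100.0], [2])
        out = recombine(h1, h2, np.array([50.0]), 0)
        assert list(out.ends) == [50.0, 100.0]
        assert list(out.haps) == [0, 2]

    def test_normalization_fuses_but_preserves_decode(self):
        h = Homolog([30.0, 60.0, 100.0], [5, 5, 7])
        norm = h.normalize()
        assert norm.n_blocks == 2
        pos = np.array([10.0, 30.0, 45.0, 60.0, 99.0])
        np.testing.assert_array_equal(h.hap_at(pos), norm.hap_at(pos))

    def test_block_growth_bounded_by_crossovers(self):
        h1 = Homolog([50.0, 100.0], [0, 1])
        h2 = Homolog([20.0, 100.0], [2, 3])
        xo = np.array([10.0, 35.0, 80.0])
        out = recombine(h1, h2, xo, 0)
        assert out.n_blocks <= h1.n_blocks + h2.n_blocks + len(xo)


# --------------------------------------------------------------------------
# transmission rules
# --------------------------------------------------------------------------

class TestTransmission:
    def test_zero_genetic_length_transmits_parental_homolog(self, diploid_data, rng):
        from breedsim.genome import Chromosome, Genome
        from breedsim.meiosis import founder_genome, make_gamete
        fh, meta, _ = diploid_data
        chrom = Chromosome("1", 1_000_000, "autosome",
                           GeneticMap.zero(1_000_000))
        genome = Genome([chrom], [("1", 100)], 2)
        parent = founder_genome(genome, 0, "female")
        g = make_gamete(parent, genome, rng)
        assert g.homologs[0][0] in parent.homologs[0]

    def test_offspring_blocks_reference_parental_haplotypes(self, diploid_pop, rng):
        child = diploid_pop.add_offspring(0, 1, rng)
        allowed = {0, 1, 2, 3}  # haplotype columns of founders 0 and 1
        for hs in child.genome.homologs:
            for h in hs:
                assert set(h.haps.tolist()) <= allowed

    def test_sons_y_identical_to_sires(self, sexed_pop, rng):
        yi = next(i for i, c in enumerate(sexed_pop.genome.chromosomes)
                  if c.kind == "sex_y")
        sons = 0
        while sons < 5:
            child = sexed_pop.add_offspring(0, 1, rng, sex="male")
            assert child.genome.homologs[yi][0] == sexed_pop[1].genome.homologs[yi][0]
            sons += 1

    def test_mito_maternal_and_intact(self, sexed_pop, rng):
        mi = next(i for i, c in enumerate(sexed_pop.genome.chromosomes)
                  if c.kind == "mito")
        for _ in range(5):
            child = sexed_pop.add_offspring(0, 1, rng)
            assert child.genome.homologs[mi][0] == sexed_pop[0].genome.homologs[mi][0]

    def test_daughter_one_x_from_each_parent(self, sexed_pop, rng):
        xi = next(i for i, c in enumerate(sexed_pop.genome.chromosomes)
                  if c.kind == "sex_x")
        child = sexed_pop.add_offspring(0, 1, rng, sex="female")
        xs = child.genome.homologs[xi]
        assert len(xs) == 2
        mat_cols = set(range(0, 2))   # founder 0 haplotype columns
        pat_cols = set(range(2, 4))   # founder 1
        assert set(xs[0].haps.tolist()) <= mat_cols
        assert set(xs[1].haps.tolist()) <= pat_cols

    def test_sex_consistent_with_sex_homolog(self, sexed_pop, rng):
        xi = next(i for i, c in enumerate(sexed_pop.genome.chromosomes)
                  if c.kind == "sex_x")
        yi = next(i for i, c in enumerate(sexed_pop.genome.chromosomes)
                  if c.kind == "sex_y")
        for _ in range(20):
            child = sexed_pop.add_offspring(0, 1, rng)
            if child.sex == "male":
                assert len(child.genome.homologs[xi]) == 1
                assert len(child.genome.homologs[yi]) == 1
            else:
                assert len(child.genome.homologs[xi]) == 2
                assert len(child.genome.homologs[yi]) == 0

    def test_same_sex_mating_rejected(self, diploid_pop, rng):
        with pytest.raises(ValueError):
            diploid_pop.add_offspring(0, 2, rng)  # two females

    def test_offspring_sex_ratio_roughly_even(self, diploid_pop):
        rng = np.random.default_rng(5)
        sexes = [diploid_pop.add_offspring(0, 1, rng).sex for _ in range(400)]
        frac = np.mean([s == "male" for s in sexes])
        assert 0.4 < frac < 0.6


class TestDihaploid:
    def test_homozygous_everywhere(self, diploid_pop, rng):
        for _ in range(5):
            child = diploid_pop.add_dihaploid(0, rng)
            dos = diploid_pop.decode([child.id])
            assert np.isin(dos, (0, 2)).all()

    def test_inbred_parent_reproduced_exactly(self, diploid_data, rng):
        import numpy as np
        from breedsim import FounderHaplotypes, Population
        fh, meta, genome = diploid_data
        # make founder 0 fully inbred: copy haplotype 0 over haplotype 1
        alleles = fh.alleles.copy()
        alleles[:, 1] = alleles[:, 0]
        pop = Population(genome, FounderHaplotypes(alleles, 2))
        child = pop.add_dihaploid(0, rng)
        dos = pop.decode([0, child.id])
        np.testing.assert_array_equal(dos[0], dos[1])

    def test_tetraploid_parent_rejected(self, tetraploid_data, rng):
        fh, meta, genome = tetraploid_data
        pop = Population(genome, fh)
        with pytest.raises(ValueError):
            pop.add_dihaploid(0, rng)


class TestDecode:
    def test_founder_decodes_to_input_dosages(self, diploid_pop):
        dec = diploid_pop.decode(range(20))
        np.testing.assert_array_equal(dec, diploid_pop.founders.dosages())

    def test_f1_of_opposite_homozygotes_is_all_het(self, diploid_data, rng):
        from breedsim import FounderHaplotypes, Population
        fh, meta, genome = diploid_data
        alleles = np.zeros_like(fh.alleles)
        alleles[:, 2:4] = 1  # founder 1 homozygous alt, founder 0 hom ref
        pop = Population(genome, FounderHaplotypes(alleles, 2))
        child = pop.add_offspring(0, 1, rng)
        assert (pop.decode([child.id]) == 1).all()

    def test_y_snps_missing_in_females(self, sexed_pop, rng):
        genome = sexed_pop.genome
        y_snps = genome.snp_indices_of("Y")
        child = sexed_pop.add_offspring(0, 1, rng, sex="female")
        dos = sexed_pop.decode([child.id], y_snps)
        assert (dos == -1).all()

    def test_male_x_dosage_bounded_by_one(self, sexed_pop, rng):
        genome = sexed_pop.genome
        x_snps = genome.snp_indices_of("X")
        child = sexed_pop.add_offspring(0, 1, rng, sex="male")
        dos = sexed_pop.decode([child.id], x_snps)
        assert dos.min() >= 0 and dos.max() <= 1

    def test_unknown_snp_index_rejected(self, diploid_pop):
        with pytest.raises(KeyError):
            diploid_pop.decode([0], np.array([10_000]))


class TestGeneDrop:
    def test_pedigree_of_founders_only(self, diploid_data, rng):
        from breedsim import gene_drop
        import pandas as pd
        fh, meta, genome = diploid_data
        ped = pd.DataFrame({"id": ["a", "b"], "sire": ["0", "0"],
                            "dam": ["0", "0"], "sex": ["F", "M"]})
        pop = gene_drop(ped, fh, genome, rng)
        assert pop.size == 2
        np.testing.assert_array_equal(pop.decode(), fh.dosages()[:2])

    def test_three_generation_toy(self, diploid_data, rng):
        from breedsim import gene_drop
        import pandas as pd
        rows = [("f%d" % i, "0", "0", "F" if i % 2 == 0 else "M") for i in range(4)]
        rows += [("c1", "f1", "f0", "F"), ("c2", "f3", "f2", "M"),
                 ("g1", "c2", "c1", "0")]
        ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
        fh, meta, genome = diploid_data
        pop = gene_drop(ped, fh, genome, rng)
        assert pop.size == 7
        g1 = pop.individuals[-1]
        assert pop[g1.mother].sex == "female" and pop[g1.father].sex == "male"

    def test_single_unknown_parent_rejected(self, diploid_data, rng):
        from breedsim import gene_drop
        import pandas as pd
        ped = pd.DataFrame({"id": ["a", "b"], "sire": ["0", "a"],
                            "dam": ["0", "0"], "sex": ["M", "0"]})
        with pytest.raises(ValueError, match="one parent"):
            gene_drop(ped, fh_or(diploid_data), genome_of(diploid_data), rng)

    def test_unsorted_pedigree_rejected(self, diploid_data, rng):
        from breedsim import gene_drop
        import pandas as pd
        # the bred parent "mid" appears after its offspring "kid"
        ped = pd.DataFrame({"id": ["f1", "f2", "kid", "mid"],
                            "sire": ["0", "0", "mid", "f1"],
                            "dam": ["0", "0", "f2", "f2"],
                            "sex": ["M", "F", "0", "M"]})
        with pytest.raises(ValueError, match="sorted"):
            gene_drop(ped, fh_or(diploid_data), genome_of(diploid_data), rng)

    def test_neutral_drift_preserves_mean_frequency(self, diploid_data):
        import pandas as pd
        from breedsim import gene_drop
        fh, meta, genome = diploid_data
        rows = [(f"f{i}", "0", "0", "F" if i % 2 == 0 else "M") for i in range(20)]
        rng0 = np.random.default_rng(3)
        for j in range(200):
            dam = f"f{2 * rng0.integers(10)}"
            sire = f"f{2 * rng0.integers(10) + 1}"
            rows.append((f"o{j}", sire, dam, "0"))
        ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])
        pop = gene_drop(ped, fh, genome, np.random.default_rng(4))
        dos = pop.decode(range(20, pop.size))
        p_off = dos.mean(axis=0) / 2
        p0 = fh.frequencies
        assert np.abs(p_off.mean() - p0.mean()) < 0.02


def fh_or(data):
    return data[0]


def genome_of(data):
    return data[2]
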