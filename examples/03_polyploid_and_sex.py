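"""Autotetraploid meiosis, sex-linked and mitochondrial inheritance.

Builds a tetraploid founder panel with an X/Y pair and an MT chromosome
and shows the transmission rules: four homologs on autosomes, at most two
at X-linked loci, intact paternal Y, maternal mito, and fully homozygous
dihaploids (from a separate diploid panel).
"""

import tempfile

import numpy as np

from breedsim import Population, build_genome, read_vcf
from breedsim.fixtures import make_fixture

tmp = tempfile.mkdtemp()
paths = make_fixture(tmp, n_founders=12, n_chrom=1, n_snps=60, ploidy=4,
                     sex_chrom=True, mito=True, seed=3)
founders, meta = read_vcf(paths["vcf"])
genome = build_genome(meta)  # ploidy and X/Y/MT detected from names
print(f"detected ploidy: {meta.ploidy}")
print("chromosomes:", [(c.name, c.kind) for c in genome.chromosomes])

rng = np.random.default_rng(3)
pop = Population(genome, founders)
son = pop.add_offspring(0, 1, rng, sex="male")
daughter = pop.add_offspring(0, 1, rng, sex="female")

idx = {c.kind: i for i, c in enumerate(genome.chromosomes)}
print(f"son homologs — autosome: {len(son.genome.homologs[idx['autosome']])}, "
      f"X: {len(son.genome.homologs[idx['sex_x']])}, "
      f"Y: {len(son.genome.homologs[idx['sex_y']])}")
print(f"daughter homologs — X: {len(daughter.genome.homologs[idx['sex_x']])}, "
      f"Y: {len(daughter.genome.homologs[idx['sex_y']])}")
print("son Y identical to sire's Y:",
      son.genome.homologs[idx["sex_y"]][0] == pop[1].genome.homologs[idx["sex_y"]][0])
print("offspring mito identical to dam's:",
      son.genome.homologs[idx["mito"]][0] == pop[0].genome.homologs[idx["mito"]][0])

# dihaploids need a diploid genome
paths2 = make_fixture(tmp + "/d", n_founders=6, n_chrom=2, n_snps=50, seed=5)
f2, m2 = read_vcf(paths2["vcf"])
pop2 = Population(build_genome(m2), f2)
dh = pop2.add_dihaploid(0, rng)
dos = pop2.decode([dh.id])
print(f"dihaploid dosages are all 0 or 2 (homozygous genome-wide): "
      f"{bool(np.isin(dos, (0, 2)).all())}")
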