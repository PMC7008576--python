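"""Naive allele-propagation oracle for the block-representation check.

Replays traced meioses (bivalent pairings, crossover positions, strand
choices) on full per-SNP allele vectors, independently of the block
machinery, so decoded block genomes can be compared against it exactly.
"""

import numpy as np

from breedsim import Population, build_genome, read_vcf

def _founder_allele_vectors(pop):
    """Per founder, per chromosome: list of per-SNP allele vectors."""
    genome, fh = pop.genome, pop.founders
    out = {}
    for ind in pop.individuals:
        if not ind.is_founder:
            continue
        per_chrom = []
        for ci in range(genome.n_chrom):
            rows = np.nonzero(genome.snp_chrom == ci)[0]
            vecs = [fh.alleles[rows, h.haps[0]] for h in ind.genome.homologs[ci]]
            per_chrom.append(vecs)
        out[ind.id] = per_chrom
    return out


def _naive_gamete(parent_vecs, genome, records):
    """Replay one traced gamete on allele vectors. Autosomes only."""
    it = iter(records)
    gamete = []
    for ci, chrom in enumerate(genome.chromosomes):
        pos = genome.snp_bp[genome.snp_chrom == ci].astype(float)
        homs = parent_vecs[ci]
        rec = next(it)
        assert rec["kind"] == "pairing" and rec["chrom"] == ci
        perm = rec["perm"]
        strands = []
        for b in range(len(homs) // 2):
            biv = next(it)
            assert biv["kind"] == "bivalent"
            pair = (int(perm[2 * b]), int(perm[2 * b + 1]))
            assert biv["pair"] == pair
            xo = np.sort(biv["xo_bp"])
            # a SNP at bp x belongs to the segment ending at x: count
            # crossovers strictly below x to find the active template
            switches = np.searchsorted(xo, pos, side="left")
            src = (biv["start"] + switches) % 2
            strand = np.where(src == 0, homs[pair[0]], homs[pair[1]])
            strands.append(strand)
        gamete.append(strands)
    return gamete


def _split_trace(trace, genome, ploidy):
    """A mate() trace holds the maternal gamete's records then the paternal's."""
    per_gamete = genome.n_chrom * (1 + ploidy // 2)
    assert len(trace) == 2 * per_gamete
    return trace[:per_gamete], trace[per_gamete:]


def _run_oracle_pedigree(paths, n_generations=5, n_per_gen=4, seed=99):
    fh, meta = read_vcf(paths["vcf"])
    genome = build_genome(meta)
    rng = np.random.default_rng(seed)
    pop = Population(genome, fh)
    vecs = _founder_allele_vectors(pop)
    for gen in range(1, n_generations + 1):
        prev = pop.ids_of_generation(gen - 1) if gen > 1 else list(vecs)
        females = [i for i in prev if pop[i].sex == "female"]
        males = [i for i in prev if pop[i].sex == "male"]
        for _ in range(n_per_gen):
            dam = int(rng.choice(females))
            sire = int(rng.choice(males))
            tr = []
            child = pop.add_offspring(dam, sire, rng, trace=tr)
            mt, pt = _split_trace(tr, genome, genome.ploidy)
            mg = _naive_gamete(vecs[dam], genome, mt)
            pg = _naive_gamete(vecs[sire], genome, pt)
            vecs[child.id] = [m + p for m, p in zip(mg, pg)]
    return pop, vecs


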