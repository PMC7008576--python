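"""Population container: founders, pedigree bookkeeping, gene dropping.

A ``Population`` owns the genome, the founder haplotype matrix and an
ordered list of individuals (parents always precede offspring). It is the
object selection cycles and diagnostics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import FounderHaplotypes, FounderMetadata
from .genome import Genome
from .meiosis import (
    FEMALE,
    MALE,
    IndividualGenome,
    decode_genotypes,
    founder_genome,
    make_dihaploid,
    make_gamete,
    mate,
    recombine,
    Homolog,
)

__all__ = ["Individual", "Population", "gene_drop", "read_pedigree_file"]


@dataclass
class Individual:
    """One simulated individual: identity, pedigree links, blocks, trait values."""

    id: int
    sex: str
    mother: int | None  # internal id, None for founders
    father: int | None
    generation: int
    genome: IndividualGenome
    is_base: bool = False  # founder or dummy founder
    g: np.ndarray | None = None  # genotypic value per trait
    e: np.ndarray | None = None  # environmental deviation per trait
    y: np.ndarray | None = None  # phenotype per trait

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


class Population:
    """Founders plus everything bred from them.

    Parameters
    ----------
    genome, founders
        The chromosome catalogue and the phased founder allele matrix.
    sexes
        Optional per-founder sexes; default alternates female, male, ...
        so both sexes are always available for mating.
    labels
        Optional external labels (e.g. VCF sample names) for the founders.
    """

    def __init__(self, genome: Genome, founders: FounderHaplotypes,
                 sexes: list[str] | None = None, labels: list[str] | None = None):
        self.genome = genome
        self.founders = founders
        self.individuals: list[Individual] = []
        self._by_label: dict[str, int] = {}
        n = founders.n_founders
        if sexes is None:
            sexes = [FEMALE if i % 2 == 0 else MALE for i in range(n)]
        if len(sexes) != n:
            raise ValueError("one sex per founder required")
        for i in range(n):
            ind = Individual(
                id=i, sex=sexes[i], mother=None, father=None, generation=0,
                genome=founder_genome(genome, i, sexes[i]), is_base=True,
            )
            self.individuals.append(ind)
            if labels is not None:
                self._by_label[str(labels[i])] = i

    # -- bookkeeping ---------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.individuals)

    def __getitem__(self, i: int) -> Individual:
        return self.individuals[i]

    @property
    def n_generations(self) -> int:
        return max(ind.generation for ind in self.individuals) + 1

    def ids_of_generation(self, t: int) -> list[int]:
        return [ind.id for ind in self.individuals if ind.generation == t]

    def pedigree(self) -> pd.DataFrame:
        """id / sire / dam / sex / generation table, parents coded -1 for founders."""
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire": [-1 if i.father is None else i.father for i in self.individuals],
                "dam": [-1 if i.mother is None else i.mother for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
            }
        )

    # -- growth --------------------------------------------------------

    def add_offspring(self, mother: int, father: int, rng, sex=None,
                      generation: int | None = None, trace=None) -> Individual:
        mo, fa = self.individuals[mother], self.individuals[father]
        child_genome = mate(mo.genome, fa.genome, self.genome, rng, sex=sex, trace=trace)
        gen = generation if generation is not None else max(mo.generation, fa.generation) + 1
        ind = Individual(self.size, child_genome.sex, mother, father, gen, child_genome)
        self.individuals.append(ind)
        return ind

    def add_dihaploid(self, parent: int, rng, generation: int | None = None) -> Individual:
        pa = self.individuals[parent]
        child_genome = make_dihaploid(pa.genome, self.genome, rng)
        gen = generation if generation is not None else pa.generation + 1
        # both genome copies stem from the single parent
        ind = Individual(self.size, child_genome.sex, parent, parent, gen, child_genome)
        self.individuals.append(ind)
        return ind

    def make_dummy_founders(self, n_new: int, rng, mode: str = "gene_drop") -> list[Individual]:
        """Expand the base population with recombinant "dummy" founders.

        ``gene_drop`` breeds each dummy as the terminal individual of a
        short random pedigree (random founder grandparents, then parents);
        ``random_blocks`` draws Poisson breakpoints per homolog and fills
        the blocks with uniformly drawn founder haplotypes. Dummies are
        flagged as base-population members (generation 0).
        """
        if n_new < 0:
            raise ValueError("n_new must be >= 0")
        if mode not in ("gene_drop", "random_blocks"):
            raise ValueError(f"unknown dummy mode {mode!r}")
        real = [i for i in self.individuals if i.is_founder and i.is_base]
        out = []
        for _ in range(n_new):
            if mode == "gene_drop":
                ind = self._dummy_by_gene_drop(real, rng)
            else:
                ind = self._dummy_by_random_blocks(rng)
            out.append(ind)
        return out

    def _dummy_by_gene_drop(self, real, rng) -> Individual:
        females = [i.id for i in real if i.sex == FEMALE]
        males = [i.id for i in real if i.sex == MALE]
        if not females or not males:
            raise ValueError("gene_drop dummies need founders of both sexes")
        # depth-2 random pedigree: grandparents -> parents -> dummy
        gm1, gm2 = rng.choice(females, 2)
        gf1, gf2 = rng.choice(males, 2)
        dam_g = mate(self.individuals[gm1].genome, self.individuals[gf1].genome,
                     self.genome, rng, sex=FEMALE)
        sire_g = mate(self.individuals[gm2].genome, self.individuals[gf2].genome,
                      self.genome, rng, sex=MALE)
        child = mate(dam_g, sire_g, self.genome, rng)
        ind = Individual(self.size, child.sex, None, None, 0, child, is_base=True)
        self.individuals.append(ind)
        return ind

    def _dummy_by_random_blocks(self, rng) -> Individual:
        p = self.genome.ploidy
        nf = self.founders.n_founders
        sex = FEMALE if rng.random() < 0.5 else MALE
        homs: list[list[Homolog]] = []
        for chrom in self.genome.chromosomes:
            n_hom = self.genome.homolog_count(chrom, sex)
            gmap = chrom.map_female
            chrom_homs = []
            for _ in range(n_hom):
                L = gmap.length_morgans
                k = int(rng.poisson(L)) if L > 0 else 0
                cuts = np.sort(rng.uniform(0, L, k)) if k else np.empty(0)
                bp = gmap.to_bp(cuts) if k else np.empty(0)
                ends = np.append(np.atleast_1d(bp), float(chrom.length_bp))
                haps = rng.integers(0, nf * p, ends.size)
                chrom_homs.append(Homolog(ends, haps).normalize())
            homs.append(chrom_homs)
        ind = Individual(self.size, sex, None, None, 0,
                         IndividualGenome(sex, homs), is_base=True)
        self.individuals.append(ind)
        return ind

    # -- genotypes -----------------------------------------------------

    def decode(self, ids=None, snp_indices=None) -> np.ndarray:
        """Dosage matrix for the given individuals (default: all) and SNPs."""
        inds = self.individuals if ids is None else [self.individuals[i] for i in ids]
        return decode_genotypes((i.genome for i in inds), self.genome,
                                self.founders, snp_indices)

    def base_ids(self) -> list[int]:
        return [i.id for i in self.individuals if i.is_base]


def read_pedigree_file(path) -> pd.DataFrame:
    """Read a pedigree file: whitespace-delimited id, sire, dam[, sex].

    ``0`` denotes an unknown parent (allowed only for founders, i.e. both
    parents unknown). Sex is ``F``/``M``/``0`` (0 = unspecified).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("pedigree needs columns: id, sire, dam[, sex]")
    out = pd.DataFrame(
        {"id": df.iloc[:, 0], "sire": df.iloc[:, 1], "dam": df.iloc[:, 2]}
    )
    out["sex"] = df.iloc[:, 3].str.upper().str[0] if df.shape[1] > 3 else "0"
    return out


def gene_drop(pedigree: pd.DataFrame, founders: FounderHaplotypes, genome: Genome,
              rng, labels: list[str] | None = None) -> Population:
    """Drop founder alleles down a fixed pedigree — no selection.

    Pedigree rows whose parents are both ``0`` are founders and are mapped,
    in order of appearance, to the founder genotype columns. Rows must be
    sorted (or sortable) so parents precede offspring; a row with exactly
    one known parent, or a pedigree cycle, is an error.
    """
    ped = pedigree.reset_index(drop=True)
    ids = list(ped["id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    sire = list(ped["sire"].astype(str))
    dam = list(ped["dam"].astype(str))
    sexes = list(ped["sex"].astype(str)) if "sex" in ped else ["0"] * len(ids)

    founder_rows = [k for k in range(len(ids)) if sire[k] == "0" and dam[k] == "0"]
    for k in range(len(ids)):
        if (sire[k] == "0") != (dam[k] == "0"):
            raise ValueError(f"individual {ids[k]}: exactly one parent unknown")
    if len(founder_rows) > founders.n_founders:
        raise ValueError(
            f"pedigree has {len(founder_rows)} founders but only "
            f"{founders.n_founders} genotyped founders are available"
        )

    # founder sexes: honour the pedigree where given, else infer from use as
    # sire/dam, else alternate
    used_as_sire = set(sire) - {"0"}
    used_as_dam = set(dam) - {"0"}
    founder_sexes = []
    for j, k in enumerate(founder_rows):
        s = {"F": FEMALE, "M": MALE}.get(sexes[k], None)
        if s is None:
            if ids[k] in used_as_dam:
                s = FEMALE
            elif ids[k] in used_as_sire:
                s = MALE
            else:
                s = FEMALE if j % 2 == 0 else MALE
        founder_sexes.append(s)

    sub = FounderHaplotypes(
        founders.alleles[:, : len(founder_rows) * founders.ploidy], founders.ploidy
    )
    pop = Population(genome, sub, sexes=founder_sexes)
    internal: dict[str, int] = {}
    for j, k in enumerate(founder_rows):
        internal[ids[k]] = j

    founder_set = set(founder_rows)
    for k in range(len(ids)):
        if k in founder_set:
            continue
        if sire[k] not in internal or dam[k] not in internal:
            raise ValueError(
                f"individual {ids[k]}: parent appears after offspring or is missing "
                "(pedigree must be sorted parents-first)"
            )
        want = {"F": FEMALE, "M": MALE}.get(sexes[k], None)
        if want is None:  # a later parental role fixes the sex
            if ids[k] in used_as_dam:
                want = FEMALE
            elif ids[k] in used_as_sire:
                want = MALE
        child = pop.add_offspring(internal[dam[k]], internal[sire[k]], rng, sex=want)
        internal[ids[k]] = child.id
    pop._by_label = internal
    return pop
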