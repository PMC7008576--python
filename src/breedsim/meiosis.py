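"""Gamete formation on the recombination-block genome representation.

An individual's genome is not a list of SNP alleles but, per homolog, an
ordered list of blocks ``(end_bp, founder_haplotype_id)`` covering
``(0, length_bp]``: every descendant chromosome is a mosaic of founder
haplotypes, and genotypes are recovered on demand by binary search into the
founder allele matrix. Meiosis is simplified and ploidy-generic:

1. homologs of each chromosome are randomly paired into bivalents;
2. within a bivalent, the crossover count is Poisson with mean equal to the
   chromosome's genetic length in Morgans (for the parent's sex), crossover
   genetic positions are uniform, and they are placed physically through the
   inverse genetic map — no interference, no obligate chiasma;
3. one of the two recombinant strands of each bivalent enters the gamete
   with probability 1/2.

Sex chromosomes are capped at two homologs: a female recombines her two X
copies as an ordinary bivalent, a male transmits his X or his Y intact with
probability 1/2 each (the whole Y is non-recombining, and there is no
pseudo-autosomal region). The mitochondrial chromosome is a single homolog
transmitted maternally and intact.

Every stochastic step can be recorded in a *trace* (pairings, crossover
positions, strand choices), which lets an external check replay the exact
same meioses on full per-SNP allele vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AUTOSOME, MITO, SEX_X, SEX_Y, Genome

__all__ = [
    "Homolog",
    "IndividualGenome",
    "Gamete",
    "make_gamete",
    "mate",
    "make_dihaploid",
    "decode_genotypes",
    "founder_genome",
]

FEMALE = "female"
MALE = "male"
MISSING_DOSAGE = -1  # structurally absent (e.g. Y-linked SNPs in females)


class Homolog:
    """One chromosome copy: blocks ``(end_bp, founder_haplotype_id]``.

    ``ends`` are strictly increasing and the last equals the chromosome
    length; a position ``x`` belongs to the first block with ``end >= x``
    (half-open intervals, open at the start).
    """

    __slots__ = ("ends", "haps")

    def __init__(self, ends, haps):
        self.ends = np.asarray(ends, dtype=np.float64)
        self.haps = np.asarray(haps, dtype=np.int64)
        if self.ends.size != self.haps.size or self.ends.size == 0:
            raise ValueError("ends and haps must be equal-length, non-empty")

    @classmethod
    def whole(cls, length_bp: float, hap_id: int) -> "Homolog":
        return cls([float(length_bp)], [hap_id])

    @property
    def n_blocks(self) -> int:
        return int(self.ends.size)

    def copy(self) -> "Homolog":
        return Homolog(self.ends.copy(), self.haps.copy())

    def normalize(self) -> "Homolog":
        """Fuse adjacent blocks with the same haplotype id (decode-invariant)."""
        if self.n_blocks == 1:
            return self
        keep = np.append(self.haps[:-1] != self.haps[1:], True)
        return Homolog(self.ends[keep], self.haps[keep])

    def hap_at(self, bp) -> np.ndarray:
        """Founder haplotype id covering position(s) ``bp``."""
        idx = np.searchsorted(self.ends, np.asarray(bp, dtype=np.float64), side="left")
        idx = np.minimum(idx, self.ends.size - 1)
        return self.haps[idx]

    def __eq__(self, other):
        return (
            isinstance(other, Homolog)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.haps, other.haps)
        )

    def __repr__(self):
        return f"Homolog({list(zip(self.ends, self.haps))})"


def _copy_segment(hom: Homolog, start: float, stop: float, out_ends, out_haps) -> None:
    """Append hom's blocks covering (start, stop], truncated at stop."""
    i = int(np.searchsorted(hom.ends, start, side="right"))
    while start < stop:
        e = min(float(hom.ends[i]), stop)
        out_ends.append(e)
        out_haps.append(int(hom.haps[i]))
        start = e
        i += 1


def recombine(h1: Homolog, h2: Homolog, xo_bp: np.ndarray, start: int) -> Homolog:
    """Recombinant strand of a bivalent.

    The strand starts on ``h1`` if ``start == 0`` else ``h2`` and switches
    template at every crossover position; positions at or beyond either
    chromosome end are inert.
    """
    length = float(h1.ends[-1])
    cur, other = (h1, h2) if start == 0 else (h2, h1)
    xo = np.asarray(xo_bp, dtype=np.float64)
    xo = np.sort(xo[(xo > 0) & (xo < length)])
    ends: list[float] = []
    haps: list[int] = []
    prev = 0.0
    for x in xo:
        _copy_segment(cur, prev, float(x), ends, haps)
        cur, other = other, cur
        prev = float(x)
    _copy_segment(cur, prev, length, ends, haps)
    return Homolog(ends, haps).normalize()


@dataclass
class IndividualGenome:
    """Block-represented genome: per chromosome, a list of homologs.

    Homolog counts follow the transmission rules: ``ploidy`` on autosomes,
    two X's in females, X+Y in males (the Y list is empty in females), one
    mitochondrial homolog.
    """

    sex: str
    homologs: list[list[Homolog]]  # indexed like genome.chromosomes

    def copy(self) -> "IndividualGenome":
        return IndividualGenome(self.sex, [[h.copy() for h in hs] for hs in self.homologs])


@dataclass
class Gamete:
    """Half-genome: ploidy/2 autosomal homologs, one sex homolog, maternal mito."""

    homologs: list[list[Homolog]]
    sex_carried: str  # "X" or "Y"


def founder_genome(genome: Genome, founder: int, sex: str) -> IndividualGenome:
    """Whole-chromosome blocks pointing at a founder's haplotype columns."""
    p = genome.ploidy
    cols = [founder * p + k for k in range(p)]
    homs: list[list[Homolog]] = []
    for chrom in genome.chromosomes:
        n = genome.homolog_count(chrom, sex)
        homs.append([Homolog.whole(chrom.length_bp, cols[k]) for k in range(n)])
    return IndividualGenome(sex, homs)


def make_gamete(
    parent: IndividualGenome,
    genome: Genome,
    rng: np.random.Generator,
    force_sex_carried: str | None = None,
    trace: list | None = None,
) -> Gamete:
    """Simulate one meiosis of ``parent``; see the module docstring.

    ``force_sex_carried`` ("X"/"Y") fixes which sex homolog a male
    transmits, used when the offspring sex is requested explicitly. When
    ``trace`` is a list, one record per stochastic decision is appended.
    """
    out: list[list[Homolog]] = []
    sex_carried = "X"
    male_choice: str | None = None
    if parent.sex == MALE and genome.sex_chromosomes_present:
        male_choice = force_sex_carried or ("Y" if rng.random() < 0.5 else "X")
        sex_carried = male_choice
    for ci, chrom in enumerate(genome.chromosomes):
        homs = parent.homologs[ci]
        gmap = chrom.genetic_map(parent.sex)
        if chrom.kind == MITO:
            out.append([homs[0].copy()] if parent.sex == FEMALE and homs else [])
            continue
        if chrom.kind == SEX_Y:
            if male_choice == "Y" and homs:
                out.append([homs[0].copy()])
            else:
                out.append([])
            continue
        if chrom.kind == SEX_X:
            if parent.sex == MALE:
                # hemizygous X: transmitted intact or not at all
                out.append([homs[0].copy()] if male_choice == "X" and homs else [])
                continue
            # female: ordinary bivalent of her two X copies
            out.append([_bivalent_strand(homs, (0, 1), gmap, rng, trace, ci)])
            continue
        # autosome: random bivalent partition, one strand per bivalent
        perm = rng.permutation(len(homs))
        if trace is not None:
            trace.append({"chrom": ci, "kind": "pairing", "perm": perm.copy()})
        gam = [
            _bivalent_strand(homs, (int(perm[2 * b]), int(perm[2 * b + 1])), gmap, rng, trace, ci)
            for b in range(len(homs) // 2)
        ]
        out.append(gam)
    return Gamete(out, sex_carried)


def _bivalent_strand(homs, pair, gmap, rng, trace, ci) -> Homolog:
    ia, ib = pair
    L = gmap.length_morgans
    k = int(rng.poisson(L)) if L > 0 else 0
    xo_m = np.sort(rng.uniform(0.0, L, k)) if k else np.empty(0)
    xo_bp = gmap.to_bp(xo_m) if k else np.empty(0)
    start = int(rng.integers(2))
    if trace is not None:
        trace.append(
            {"chrom": ci, "kind": "bivalent", "pair": (ia, ib),
             "xo_bp": np.atleast_1d(xo_bp).copy(), "start": start}
        )
    return recombine(homs[ia], homs[ib], np.atleast_1d(xo_bp), start)


def mate(
    mother: IndividualGenome,
    father: IndividualGenome,
    genome: Genome,
    rng: np.random.Generator,
    sex: str | None = None,
    trace: list | None = None,
) -> IndividualGenome:
    """Offspring genome: union of one maternal and one paternal gamete.

    With sex chromosomes present the offspring is male iff it received the
    paternal Y, so a requested ``sex`` fixes the paternal transmission;
    otherwise the sex is drawn 1:1 (or set to ``sex`` when given).
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("mate() requires a female mother and a male father")
    if sex not in (None, "random", FEMALE, MALE):
        raise ValueError(f"invalid sex {sex!r}")
    want = None if sex in (None, "random") else sex
    force = None
    if genome.sex_chromosomes_present and want is not None:
        force = "Y" if want == MALE else "X"
    mg = make_gamete(mother, genome, rng, trace=trace)
    pg = make_gamete(father, genome, rng, force_sex_carried=force, trace=trace)
    if genome.sex_chromosomes_present:
        child_sex = MALE if pg.sex_carried == "Y" else FEMALE
    else:
        child_sex = want if want is not None else (MALE if rng.random() < 0.5 else FEMALE)
    homs: list[list[Homolog]] = []
    for ci, chrom in enumerate(genome.chromosomes):
        if chrom.kind == MITO:
            homs.append(mg.homologs[ci])  # maternal only
        else:
            homs.append(mg.homologs[ci] + pg.homologs[ci])
    return IndividualGenome(child_sex, homs)


def make_dihaploid(
    parent: IndividualGenome, genome: Genome, rng: np.random.Generator,
    trace: list | None = None,
) -> IndividualGenome:
    """Doubled haploid: one gamete, duplicated — homozygous genome-wide.

    Only diploid parents are supported. The duplicated gamete is always
    X-bearing, so dihaploids are female (XX) when sex chromosomes are
    declared. The mitochondrial homolog, if any, is copied from the parent
    (single copy, as always).
    """
    if genome.ploidy != 2:
        raise ValueError("dihaploids are only supported for diploid genomes")
    force = "X" if (parent.sex == MALE and genome.sex_chromosomes_present) else None
    g = make_gamete(parent, genome, rng, force_sex_carried=force, trace=trace)
    homs: list[list[Homolog]] = []
    for ci, chrom in enumerate(genome.chromosomes):
        if chrom.kind == MITO:
            homs.append([parent.homologs[ci][0].copy()] if parent.homologs[ci] else [])
        else:
            homs.append([h.copy() for h in g.homologs[ci]] + [h.copy() for h in g.homologs[ci]])
    return IndividualGenome(FEMALE, homs)


def decode_genotypes(
    individuals, genome: Genome, founders, snp_indices=None
) -> np.ndarray:
    """Dosage matrix (individuals x SNPs) recovered from block pointers.

    For each SNP the covering block of every homolog is found by binary
    search and the founder alleles summed, so values run 0..(homolog
    count). SNPs on chromosomes an individual does not carry (Y in
    females) are reported as ``MISSING_DOSAGE``.
    """
    if snp_indices is None:
        snp_indices = np.arange(genome.n_snps)
    snp_indices = np.asarray(snp_indices, dtype=np.int64)
    if snp_indices.size and (snp_indices.min() < 0 or snp_indices.max() >= genome.n_snps):
        raise KeyError("SNP index outside genome SNP list")
    inds = list(individuals)
    out = np.zeros((len(inds), snp_indices.size), dtype=np.int16)
    chrom_of = genome.snp_chrom[snp_indices]
    pos_of = genome.snp_bp[snp_indices]
    for ci in range(genome.n_chrom):
        cols = np.nonzero(chrom_of == ci)[0]
        if cols.size == 0:
            continue
        pos = pos_of[cols].astype(np.float64)
        rows = snp_indices[cols]
        for i, ind in enumerate(inds):
            homs = ind.homologs[ci]
            if not homs:
                out[i, cols] = MISSING_DOSAGE
                continue
            dose = np.zeros(cols.size, dtype=np.int16)
            for h in homs:
                dose += founders.alleles[rows, h.hap_at(pos)]
            out[i, cols] = dose
    return out
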