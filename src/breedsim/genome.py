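"""Chromosome catalogue, SNP coordinates and recombination maps.

Physical coordinates are 1-based base pairs, as in VCF. Genetic maps are
piecewise-linear: a list of (bp, cumulative cM) anchors per sex, linearly
interpolated between anchors with the last interval's rate extrapolated to
the chromosome end. With no user map, the default rate of 1 cM per Mb
applies everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CM_PER_MB",
    "GeneticMap",
    "Chromosome",
    "Genome",
    "build_genome",
    "read_map_file",
]

DEFAULT_CM_PER_MB = 1.0

AUTOSOME = "autosome"
SEX_X = "sex_x"
SEX_Y = "sex_y"
MITO = "mito"
CHROM_KINDS = (AUTOSOME, SEX_X, SEX_Y, MITO)


class GeneticMap:
    """Cumulative genetic map for one chromosome and one sex.

    Parameters
    ----------
    anchors_bp, anchors_cm
        Ordered anchor positions (bp, strictly increasing) and the
        cumulative map (cM, non-decreasing) at each anchor.
    length_bp
        Chromosome length; the last anchor interval's recombination rate is
        extrapolated out to this position.
    """

    def __init__(self, anchors_bp, anchors_cm, length_bp: int):
        bp = np.asarray(anchors_bp, dtype=float)
        cm = np.asarray(anchors_cm, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size == 0:
            raise ValueError("anchors must be equal-length 1-d sequences")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        # ensure the map starts at the origin
        if bp[0] != 0.0:
            bp = np.concatenate([[0.0], bp])
            cm = np.concatenate([[0.0], cm])
        if cm[0] != 0.0:
            raise ValueError("cumulative cM at bp=0 must be 0")
        # extrapolate the last interval's rate to length_bp
        if bp[-1] < length_bp:
            if bp.size >= 2:
                rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
            else:
                rate = DEFAULT_CM_PER_MB * 1e-6
            bp = np.concatenate([bp, [float(length_bp)]])
            cm = np.concatenate([cm, [cm[-1] + rate * (length_bp - bp[-2])]])
        self._bp = bp
        self._cm = cm
        self.length_bp = int(length_bp)

    @classmethod
    def default(cls, length_bp: int, cm_per_mb: float = DEFAULT_CM_PER_MB) -> "GeneticMap":
        return cls([0.0, float(length_bp)], [0.0, cm_per_mb * length_bp * 1e-6], length_bp)

    @classmethod
    def zero(cls, length_bp: int) -> "GeneticMap":
        """Achiasmate map: zero genetic length everywhere (no recombination)."""
        return cls([0.0, float(length_bp)], [0.0, 0.0], length_bp)

    @property
    def length_morgans(self) -> float:
        return float(self._cm[-1]) / 100.0

    def to_morgans(self, bp):
        """Genetic position (Morgans) of physical position(s) ``bp``."""
        bp_arr = np.asarray(bp, dtype=float)
        if np.any(bp_arr < 0) or np.any(bp_arr > self.length_bp):
            raise ValueError(f"bp position outside [0, {self.length_bp}]")
        out = np.interp(bp_arr, self._bp, self._cm) / 100.0
        return float(out) if np.isscalar(bp) or bp_arr.ndim == 0 else out

    def to_bp(self, morgans):
        """Physical position(s) of genetic position(s) ``morgans``.

        Exact functional inverse of :meth:`to_morgans` in the interior of
        strictly increasing map segments; within flat (zero-rate) segments
        the left endpoint is returned.
        """
        cm = np.asarray(morgans, dtype=float) * 100.0
        if np.any(cm < 0) or np.any(cm > self._cm[-1] + 1e-9):
            raise ValueError("genetic position outside map range")
        out = np.interp(cm, self._cm, self._bp)
        return float(out) if np.isscalar(morgans) or cm.ndim == 0 else out


@dataclass
class Chromosome:
    """One chromosome: physical length, kind and per-sex genetic maps.

    ``kind`` is one of ``autosome``, ``sex_x``, ``sex_y``, ``mito``; the Y
    and the mitochondrial chromosome never recombine regardless of map.
    """

    name: str
    length_bp: int
    kind: str = AUTOSOME
    map_female: GeneticMap | None = None
    map_male: GeneticMap | None = None

    def __post_init__(self):
        if self.kind not in CHROM_KINDS:
            raise ValueError(f"unknown chromosome kind {self.kind!r}")
        if self.map_female is None:
            self.map_female = GeneticMap.default(self.length_bp)
        if self.map_male is None:
            self.map_male = self.map_female
        if self.kind in (SEX_Y, MITO):
            # structurally non-recombining
            self.map_female = GeneticMap.zero(self.length_bp)
            self.map_male = GeneticMap.zero(self.length_bp)

    def genetic_map(self, sex: str) -> GeneticMap:
        if sex == "female":
            return self.map_female
        if sex == "male":
            return self.map_male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def genetic_position(self, bp, sex: str = "female"):
        return self.genetic_map(sex).to_morgans(bp)

    def physical_position(self, morgans, sex: str = "female"):
        return self.genetic_map(sex).to_bp(morgans)


class Genome:
    """Ordered chromosome catalogue plus the genome-wide SNP list.

    SNPs are held as parallel arrays (chromosome index, bp position) sorted
    by chromosome order then position; all dosage matrices in the package
    use this SNP order. Autosomes carry ``ploidy`` homologs; sex chromosomes
    at most two (X+X or X+Y); the mitochondrial chromosome exactly one.
    """

    def __init__(self, chromosomes: list[Chromosome], snps: list[tuple[str, int]], ploidy: int = 2):
        if ploidy < 2 or ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2")
        self.ploidy = int(ploidy)
        self.chromosomes = list(chromosomes)
        self._chrom_index = {c.name: i for i, c in enumerate(self.chromosomes)}
        if len(self._chrom_index) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for kind in (SEX_X, SEX_Y, MITO):
            if sum(c.kind == kind for c in self.chromosomes) > 1:
                raise ValueError(f"at most one {kind} chromosome allowed")
        ci = np.array([self._chrom_index[c] for c, _ in snps], dtype=np.int64)
        bp = np.array([p for _, p in snps], dtype=np.int64)
        order = np.lexsort((bp, ci))
        self.snp_chrom = ci[order]
        self.snp_bp = bp[order]
        for i, chrom in enumerate(self.chromosomes):
            pos = self.snp_bp[self.snp_chrom == i]
            if pos.size and np.any(np.diff(pos) == 0):
                raise ValueError(f"duplicate SNP positions on chromosome {chrom.name}")
            if pos.size and pos[-1] > chrom.length_bp:
                raise ValueError(f"SNP beyond length of chromosome {chrom.name}")

    @property
    def n_snps(self) -> int:
        return int(self.snp_bp.size)

    @property
    def n_chrom(self) -> int:
        return len(self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        return self.chromosomes[self._chrom_index[name]]

    def snp_indices_of(self, chrom_name: str) -> np.ndarray:
        """Indices into the genome SNP list of all SNPs on one chromosome."""
        return np.nonzero(self.snp_chrom == self._chrom_index[chrom_name])[0]

    def snp_index(self, chrom_name: str, bp: int) -> int:
        ci = self._chrom_index[chrom_name]
        hit = np.nonzero((self.snp_chrom == ci) & (self.snp_bp == bp))[0]
        if hit.size == 0:
            raise KeyError(f"no SNP at {chrom_name}:{bp}")
        return int(hit[0])

    def homolog_count(self, chrom: Chromosome, sex: str) -> int:
        """Number of homologs an individual of ``sex`` carries for ``chrom``."""
        if chrom.kind == AUTOSOME:
            return self.ploidy
        if chrom.kind == SEX_X:
            return 2 if sex == "female" else 1
        if chrom.kind == SEX_Y:
            return 0 if sex == "female" else 1
        return 1  # mito

    @property
    def sex_chromosomes_present(self) -> bool:
        return any(c.kind in (SEX_X, SEX_Y) for c in self.chromosomes)

    def subset_snps(self, keep: np.ndarray) -> "Genome":
        """New genome with the SNP list restricted to boolean/index mask ``keep``."""
        names = [self.chromosomes[c].name for c in self.snp_chrom[keep]]
        snps = list(zip(names, (int(b) for b in self.snp_bp[keep])))
        return Genome(self.chromosomes, snps, self.ploidy)


def read_map_file(path) -> pd.DataFrame:
    """Read a recombination-map file.

    Whitespace-delimited columns: chromosome, bp, cumulative cM (female),
    optionally cumulative cM (male; defaults to the female value). A header
    line is detected by a non-numeric second column.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 3:
        raise ValueError("map file needs >= 3 columns: chrom, bp, cM_female[, cM_male]")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0].astype(str),
            "bp": df.iloc[:, 1].astype(float).astype(np.int64),
            "cm_female": df.iloc[:, 2].astype(float),
        }
    )
    out["cm_male"] = df.iloc[:, 3].astype(float) if df.shape[1] > 3 else out["cm_female"]
    return out


def build_genome(
    founder_metadata,
    chrom_kinds: dict[str, str] | None = None,
    map_file=None,
    ploidy: int | None = None,
    auto_sex_names: bool = True,
) -> Genome:
    """Assemble a :class:`Genome` from founder metadata.

    ``founder_metadata`` is the object returned by the founder readers
    (needs ``snps`` as a list of (chrom name, bp) and ``ploidy``).
    ``chrom_kinds`` maps chromosome names to kinds; with
    ``auto_sex_names``, chromosomes named ``X``/``Y`` are taken as the sex
    chromosomes and ``MT`` as mitochondrial unless overridden. Chromosome
    length defaults to the last SNP position when no map file extends it.
    """
    snps = list(founder_metadata.snps)
    if ploidy is None:
        ploidy = founder_metadata.ploidy
    chrom_names: list[str] = []
    for name, _ in snps:
        if name not in chrom_names:
            chrom_names.append(name)
    kinds = {}
    if auto_sex_names:
        for name in chrom_names:
            if name.upper() == "X":
                kinds[name] = SEX_X
            elif name.upper() == "Y":
                kinds[name] = SEX_Y
            elif name.upper() == "MT":
                kinds[name] = MITO
    for name, kind in (chrom_kinds or {}).items():
        if name not in chrom_names:
            raise ValueError(f"chromosome {name!r} not present in founder data")
        kinds[name] = kind

    maps = None
    if map_file is not None:
        maps = read_map_file(map_file) if not isinstance(map_file, pd.DataFrame) else map_file
        unknown = set(maps["chrom"].astype(str)) - set(chrom_names)
        if unknown:
            raise ValueError(f"map file references unknown chromosome(s): {sorted(unknown)}")

    chromosomes = []
    for name in chrom_names:
        last_snp = max(p for c, p in snps if c == name)
        map_f = map_m = None
        length = last_snp
        if maps is not None:
            sub = maps[maps["chrom"] == name]
            if len(sub):
                length = max(last_snp, int(sub["bp"].max()))
                map_f = GeneticMap(sub["bp"].to_numpy(), sub["cm_female"].to_numpy(), length)
                map_m = GeneticMap(sub["bp"].to_numpy(), sub["cm_male"].to_numpy(), length)
        chromosomes.append(
            Chromosome(name, length, kinds.get(name, AUTOSOME), map_f, map_m)
        )
    return Genome(chromosomes, snps, ploidy)
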