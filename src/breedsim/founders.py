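"""Founder genotype input: VCF and PED/MAP readers, MAF filtering.

Founder haplotypes are the source of every allele the simulator will ever
produce: descendants only carry pointers into this matrix. The VCF reader
auto-detects ploidy from the GT field (any even level); the plink-like
PED/MAP dialect is diploid only. Only biallelic SNPs are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = ["FounderHaplotypes", "FounderMetadata", "read_vcf", "read_pedlike", "maf_filter"]


@dataclass
class FounderMetadata:
    """What the readers learn about the data: samples, ploidy, SNP coordinates."""

    sample_names: list[str]
    ploidy: int
    snps: list[tuple[str, int]]  # (chromosome name, 1-based bp)

    @property
    def n_founders(self) -> int:
        return len(self.sample_names)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chrom_names(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.snps:
            if c not in seen:
                seen.append(c)
        return seen


class FounderHaplotypes:
    """Phased founder allele matrix: one row per SNP, one column per haplotype.

    Column ``f * ploidy + k`` is haplotype ``k`` of founder ``f``; entries
    are 0 (reference) or 1 (alternative). Allele-1 frequencies ``p_j`` are
    recomputed after any filtering.
    """

    def __init__(self, alleles: np.ndarray, ploidy: int):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 2:
            raise ValueError("alleles must be 2-d (snps x haplotypes)")
        if alleles.shape[1] % ploidy:
            raise ValueError("haplotype column count must be a multiple of ploidy")
        if alleles.size and not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be coded 0/1")
        self.alleles = alleles
        self.ploidy = int(ploidy)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[1] // self.ploidy

    @property
    def frequencies(self) -> np.ndarray:
        """Per-SNP allele-1 frequency p_j over all founder haplotypes."""
        return self.alleles.mean(axis=1)

    def haplotype_columns(self, founder: int) -> np.ndarray:
        return np.arange(founder * self.ploidy, (founder + 1) * self.ploidy)

    def dosages(self) -> np.ndarray:
        """Founder dosage matrix (founders x SNPs), values 0..ploidy."""
        n = self.n_founders
        return (
            self.alleles.reshape(self.n_snps, n, self.ploidy)
            .sum(axis=2, dtype=np.int16)
            .T
        )

    def subset_snps(self, keep: np.ndarray) -> "FounderHaplotypes":
        return FounderHaplotypes(self.alleles[keep], self.ploidy)


def read_vcf(path, missing_seed: int = 0) -> tuple[FounderHaplotypes, FounderMetadata]:
    """Read phased founder haplotypes from a VCF.

    Ploidy is the number of alleles in the GT field and must be uniform
    across samples and sites. Multi-allelic sites are dropped (logged).
    Unphased separators are accepted; the within-GT allele order is taken
    as phase. Missing calls are imputed by drawing allele 1 with the site's
    observed frequency, using ``missing_seed``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, snps = [], []
    ploidy = None
    n_multi = 0
    rng = np.random.default_rng(missing_seed)
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # list per sample: [a1, ..., a_ploidy, phased]
        calls = np.array([g[:-1] for g in gts], dtype=np.int16)
        if ploidy is None:
            ploidy = calls.shape[1]
        elif calls.shape[1] != ploidy:
            raise ValueError(
                f"mixed ploidy: {var.CHROM}:{var.POS} has {calls.shape[1]} alleles, "
                f"expected {ploidy}"
            )
        flat = calls.reshape(-1).astype(np.int8)
        miss = flat < 0
        if miss.any():
            known = flat[~miss]
            p = known.mean() if known.size else 0.5
            flat[miss] = (rng.random(miss.sum()) < p).astype(np.int8)
        rows.append(flat)
        snps.append((var.CHROM, var.POS))
    if ploidy is None:
        raise ValueError("no biallelic SNPs found in VCF")
    if ploidy % 2:
        raise ValueError(f"odd ploidy {ploidy} is not supported")
    if n_multi:
        logger.info("dropped %d multi-allelic site(s)", n_multi)
    alleles = np.vstack(rows)
    meta = FounderMetadata(samples, ploidy, snps)
    logger.info(
        "read %d SNPs on %d chromosome(s), %d samples, ploidy %d",
        meta.n_snps, len(meta.chrom_names), meta.n_founders, ploidy,
    )
    return FounderHaplotypes(alleles, ploidy), meta


def read_pedlike(ped_path, map_path) -> tuple[FounderHaplotypes, FounderMetadata]:
    """Read diploid founders from classic 6-column PED + 4-column MAP files.

    PED: family, individual, father, mother, sex, phenotype, then two allele
    columns per SNP. MAP: chromosome, SNP id, cM, bp. Alleles are recoded to
    0/1 with the first-observed allele as 0; more than two observed alleles
    at a SNP is an error. Polyploid data must come through VCF.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] < 4:
        raise ValueError("MAP file needs 4 columns: chrom, id, cM, bp")
    snps = [(str(c), int(float(b))) for c, b in zip(mp.iloc[:, 0], mp.iloc[:, 3])]
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    n_snps = len(snps)
    if ped.shape[1] != 6 + 2 * n_snps:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * n_snps} for {n_snps} SNPs"
        )
    samples = list(ped.iloc[:, 1].astype(str))
    raw = ped.iloc[:, 6:].to_numpy(dtype=str)  # samples x (2*n_snps)
    alleles = np.empty((n_snps, 2 * len(samples)), dtype=np.int8)
    for j in range(n_snps):
        pair = raw[:, 2 * j : 2 * j + 2].reshape(-1)  # sample-major haplotypes
        observed: list[str] = []
        for a in pair:
            if a in ("0", "-9"):
                raise ValueError(f"missing alleles not supported in PED (SNP {j})")
            if a not in observed:
                observed.append(a)
        if len(observed) > 2:
            raise ValueError(f"SNP {j} has {len(observed)} alleles; biallelic only")
        code = {a: i for i, a in enumerate(observed)}
        alleles[j] = [code[a] for a in pair]
    meta = FounderMetadata(samples, 2, snps)
    return FounderHaplotypes(alleles, 2), meta


def maf_filter(
    founders: FounderHaplotypes, min_maf: float, metadata: FounderMetadata | None = None
):
    """Drop SNPs with minor allele frequency below ``min_maf``.

    Returns the filtered haplotypes, or a (haplotypes, metadata) pair when
    ``metadata`` is given so the SNP list stays aligned.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    p = founders.frequencies
    keep = np.minimum(p, 1 - p) >= min_maf if min_maf > 0 else np.ones(p.size, bool)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter %.3g removed %d of %d SNPs", min_maf, n_drop, p.size)
    out = founders.subset_snps(keep)
    if metadata is None:
        return out
    new_meta = FounderMetadata(
        metadata.sample_names,
        metadata.ploidy,
        [s for s, k in zip(metadata.snps, keep) if k],
    )
    return out, new_meta


def write_snp_sidecar(metadata: FounderMetadata, path) -> None:
    """Write the SNP-position sidecar (chromosome, bp, index) as TSV."""
    pd.DataFrame(
        {
            "chrom": [c for c, _ in metadata.snps],
            "bp": [b for _, b in metadata.snps],
            "index": np.arange(metadata.n_snps),
        }
    ).to_csv(path, sep="\t", index=False)
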