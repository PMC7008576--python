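"""Synthetic founder data: VCF, map, pedigree, QTN and chip files.

Generates small but complete input sets so every reader in the package can
be exercised without external downloads. Founder haplotypes are drawn
independently per site from per-SNP allele frequencies ~ Uniform(0.05,
0.95) (unrelated founders, no LD); an optional block-LD mode draws each
founder chromosome from a small shared haplotype pool, which gives the
marker-QTN associations genomic prediction needs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["make_fixture", "write_vcf"]


def write_vcf(path, chrom_names, lengths, positions, gt_matrix, sample_names) -> None:
    """Write a minimal phased VCF 4.2.

    ``positions`` is a list of (chrom index, bp); ``gt_matrix`` is
    (n_snps, n_samples, ploidy) of 0/1 alleles.
    """
    n_snps, n_samples, _ = gt_matrix.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, ln in zip(chrom_names, lengths):
            fh.write(f"##contig=<ID={name},length={int(ln)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for j in range(n_snps):
            ci, bp = positions[j]
            gts = "\t".join("|".join(map(str, gt_matrix[j, s])) for s in range(n_samples))
            fh.write(f"{chrom_names[ci]}\t{int(bp)}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def make_fixture(
    outdir,
    n_founders: int = 20,
    n_chrom: int = 2,
    n_snps: int = 100,
    ploidy: int = 2,
    sex_chrom: bool = False,
    mito: bool = False,
    seed: int = 0,
    chrom_length: int = 1_000_000,
    ld_blocks: int = 0,
    prefix: str = "fixture",
) -> dict[str, Path]:
    """Write a synthetic founder VCF plus companion files; return the paths.

    ``n_snps`` is the total across the ``n_chrom`` autosomes; when
    ``sex_chrom``/``mito`` are set, an X (and, with ``sex_chrom``, a Y) and
    an MT chromosome are appended carrying a tenth of the autosomal SNP
    density each. ``ld_blocks > 0`` switches to the shared-haplotype-pool
    mode with that many blocks per chromosome.

    Companion files: a recombination map (default 1 cM/Mb written
    explicitly), a 3-generation pedigree over the founders, a QTN
    positions file, a QTN effects file (one trait), and a chip file with
    every other SNP.
    """
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    if min(n_founders, n_chrom, n_snps) < 1:
        raise ValueError("n_founders, n_chrom and n_snps must be positive")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_names = [str(i + 1) for i in range(n_chrom)]
    per_chrom = [n_snps // n_chrom] * n_chrom
    per_chrom[-1] += n_snps - sum(per_chrom)
    extra = max(1, (n_snps // n_chrom) // 10)
    if sex_chrom:
        chrom_names += ["X", "Y"]
        per_chrom += [extra, extra]
    if mito:
        chrom_names += ["MT"]
        per_chrom += [extra]

    positions = []
    lengths = []
    for ci, k in enumerate(per_chrom):
        pos = np.sort(rng.choice(np.arange(1, chrom_length), k, replace=False))
        positions.extend((ci, int(b)) for b in pos)
        lengths.append(chrom_length)

    n_total = len(positions)
    gt = np.empty((n_total, n_founders, ploidy), dtype=np.int8)
    row = 0
    for ci, k in enumerate(per_chrom):
        if ld_blocks > 0:
            gt[row : row + k] = _ld_block_haplotypes(k, n_founders, ploidy, ld_blocks, rng)
        else:
            freqs = rng.uniform(0.05, 0.95, k)
            gt[row : row + k] = (
                rng.random((k, n_founders, ploidy)) < freqs[:, None, None]
            ).astype(np.int8)
        row += k

    paths = {"vcf": outdir / f"{prefix}.vcf"}
    write_vcf(paths["vcf"], chrom_names, lengths, positions, gt,
              [f"F{i:03d}" for i in range(n_founders)])

    # recombination map: the default rate made explicit (all chromosomes)
    paths["map"] = outdir / f"{prefix}.map"
    with open(paths["map"], "w") as fh:
        fh.write("chrom bp cm_female cm_male\n")
        for name, ln in zip(chrom_names, lengths):
            fh.write(f"{name} 1 0.0 0.0\n")
            fh.write(f"{name} {ln} {ln * 1e-6:.6f} {ln * 1e-6:.6f}\n")

    # 3-generation pedigree: founders, then two bred generations
    paths["pedigree"] = outdir / f"{prefix}.ped"
    with open(paths["pedigree"], "w") as fh:
        for i in range(n_founders):
            fh.write(f"I{i} 0 0 {'F' if i % 2 == 0 else 'M'}\n")
        n_g1 = max(2, n_founders // 2)
        for j in range(n_g1):
            dam = 2 * (j % max(1, n_founders // 2))
            sire = min(dam + 1, n_founders - 1)
            fh.write(f"G1_{j} I{sire} I{dam} {'F' if j % 2 == 0 else 'M'}\n")
        for j in range(n_g1):
            dam = 2 * (j % max(1, n_g1 // 2))
            sire = min(dam + 1, n_g1 - 1)
            fh.write(f"G2_{j} G1_{sire} G1_{dam} 0\n")

    # QTN files: positions only, and positions + (a, d) for one trait
    n_qtn = max(1, min(10, n_total // 10))
    qtn_rows = sorted(rng.choice(n_total, n_qtn, replace=False))
    paths["qtn_positions"] = outdir / f"{prefix}.qtn"
    with open(paths["qtn_positions"], "w") as fh:
        for r in qtn_rows:
            ci, bp = positions[r]
            fh.write(f"{chrom_names[ci]} {bp}\n")
    paths["qtn_effects"] = outdir / f"{prefix}.qtneff"
    with open(paths["qtn_effects"], "w") as fh:
        for r in qtn_rows:
            ci, bp = positions[r]
            a = rng.gamma(0.2, 5.0) * rng.choice([-1, 1])
            fh.write(f"{chrom_names[ci]} {bp} {a:.6f} 0.0\n")

    # chip: every other SNP (by position line)
    paths["chip"] = outdir / f"{prefix}.chip"
    with open(paths["chip"], "w") as fh:
        for r in range(0, n_total, 2):
            ci, bp = positions[r]
            fh.write(f"{chrom_names[ci]} {bp}\n")
    return paths


def _ld_block_haplotypes(k, n_founders, ploidy, n_blocks, rng, pool_size: int = 4):
    """Haplotypes copied blockwise from a small shared pool -> strong LD."""
    pool = (rng.random((pool_size, k)) < rng.uniform(0.05, 0.95, k)).astype(np.int8)
    bounds = np.linspace(0, k, n_blocks + 1).astype(int)
    out = np.empty((k, n_founders, ploidy), dtype=np.int8)
    for s in range(n_founders):
        for h in range(ploidy):
            hap = np.empty(k, dtype=np.int8)
            for b in range(n_blocks):
                src = rng.integers(pool_size)
                hap[bounds[b]: bounds[b + 1]] = pool[src, bounds[b]: bounds[b + 1]]
            out[:, s, h] = hap
    return out
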