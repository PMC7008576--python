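"""QTN architectures, genotypic values, heritability calibration.

A trait is controlled by a set of quantitative trait nucleotides (QTN)
drawn from the genome SNP list, each with an additive effect ``a`` (half
the difference between homozygotes in diploids; the per-copy effect in
polyploids) and a dominance effect ``d``. Genotypic values are

* diploid:   g = sum_j gamma_ij a_j + sum_j delta_ij d_j, with
  gamma in {-1, 0, +1} for the three genotype classes and delta = 1 for
  heterozygotes only;
* polyploid: g = sum_j eta_ij a_j + sum_j phi_ij d_j, with
  eta = (copies of allele 1) - ploidy/2 and phi = 1 for every dosage >= 1
  — any carrier of allele 1, including the complete '1' homozygote, takes
  the dominance value.

Phenotypes are y = mu + g + e with e ~ N(0, Var(e)), and Var(e) is
calibrated against a target broad-sense heritability H^2 from the founder
genotypic variance: Var(e) = Var(g) (1 - H^2) / H^2. Random architectures
sample |a| from a gamma distribution (default shape 0.2, scale 5) with a
symmetric random sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Architecture",
    "TraitValue",
    "GAMMA_SHAPE",
    "GAMMA_SCALE",
    "sample_effect_magnitudes",
    "sample_architecture",
    "genotypic_value",
    "calibrate_var_e",
    "simulate_phenotypes",
    "phenotype_population",
    "qtn_variance_decomposition",
    "read_qtn_file",
]

GAMMA_SHAPE = 0.2
GAMMA_SCALE = 5.0


@dataclass
class TraitValue:
    """Phenotype decomposition for one individual: y = mu + g + e, per trait."""

    g: np.ndarray
    e: np.ndarray
    y: np.ndarray


@dataclass
class Architecture:
    """QTN positions and effects for ``n_traits`` traits.

    ``a`` and ``d`` are (n_qtn, n_traits) arrays; a QTN with zero effect on
    a trait simply does not contribute to it (that is how no-pleiotropy
    multi-trait architectures are written). ``var_e`` is filled in by
    :func:`calibrate_var_e`; environmental deviations are always
    independent across traits.
    """

    qtn_indices: np.ndarray  # indices into the genome SNP list
    a: np.ndarray
    d: np.ndarray
    mu: np.ndarray  # per trait
    h2: np.ndarray  # target broad-sense heritability per trait
    var_e: np.ndarray | None = None

    def __post_init__(self):
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=np.int64)
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        if self.a.shape[0] == 1 and self.qtn_indices.size != 1:
            self.a = self.a.T
            self.d = self.d.T
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if np.any(self.h2 <= 0) or np.any(self.h2 > 1):
            raise ValueError("H^2 must lie in (0, 1]")
        if self.a.shape != self.d.shape or self.a.shape[0] != self.qtn_indices.size:
            raise ValueError("a and d must be (n_qtn, n_traits) and match qtn_indices")

    @property
    def n_qtn(self) -> int:
        return int(self.qtn_indices.size)

    @property
    def n_traits(self) -> int:
        return int(self.a.shape[1]) if self.n_qtn else int(self.mu.size)


def sample_effect_magnitudes(n: int, rng, shape: float = GAMMA_SHAPE,
                             scale: float = GAMMA_SCALE) -> np.ndarray:
    """|a| draws from the default gamma effect-size distribution."""
    return rng.gamma(shape, scale, n)


def sample_architecture(
    mode: str,
    founders,
    genome,
    rng,
    n_qtn: int | None = None,
    h2: float | np.ndarray = 0.5,
    mu: float | np.ndarray = 0.0,
    positions: np.ndarray | None = None,
    effects: tuple[np.ndarray, np.ndarray] | None = None,
    shape: float = GAMMA_SHAPE,
    scale: float = GAMMA_SCALE,
) -> Architecture:
    """Build an :class:`Architecture` one of three ways.

    ``random``: ``n_qtn`` positions drawn uniformly without replacement
    from the segregating SNPs; |a| ~ Gamma(shape, scale), sign +-1 with
    probability 1/2 each; single trait, no dominance.
    ``positions_file``: QTN positions given (array of SNP indices); effects
    sampled as in ``random``; single trait, no dominance.
    ``full_file``: positions and per-trait (a, d) arrays given verbatim.
    QTN are not removed from the sequence SNP set.
    """
    if mode == "random":
        if n_qtn is None:
            raise ValueError("mode 'random' needs n_qtn")
        p = founders.frequencies
        segregating = np.nonzero((p > 0) & (p < 1))[0]
        if n_qtn > segregating.size:
            raise ValueError(
                f"n_qtn={n_qtn} exceeds the {segregating.size} segregating SNPs"
            )
        idx = np.sort(rng.choice(segregating, n_qtn, replace=False))
        mag = sample_effect_magnitudes(n_qtn, rng, shape, scale)
        sign = rng.choice([-1.0, 1.0], n_qtn)
        a = (mag * sign)[:, None]
        d = np.zeros_like(a)
    elif mode == "positions_file":
        if positions is None:
            raise ValueError("mode 'positions_file' needs positions")
        idx = np.asarray(positions, dtype=np.int64)
        _check_positions(idx, genome)
        mag = sample_effect_magnitudes(idx.size, rng, shape, scale)
        sign = rng.choice([-1.0, 1.0], idx.size)
        a = (mag * sign)[:, None]
        d = np.zeros_like(a)
    elif mode == "full_file":
        if positions is None or effects is None:
            raise ValueError("mode 'full_file' needs positions and effects")
        idx = np.asarray(positions, dtype=np.int64)
        _check_positions(idx, genome)
        a = np.atleast_2d(np.asarray(effects[0], dtype=float))
        d = np.atleast_2d(np.asarray(effects[1], dtype=float))
        if a.shape[0] != idx.size:
            a, d = a.T, d.T
    else:
        raise ValueError(f"unknown architecture mode {mode!r}")
    n_traits = a.shape[1]
    if mode in ("random", "positions_file") and (
        np.atleast_1d(h2).size > 1 or n_traits > 1
    ):
        raise ValueError("random-effect modes support a single trait only")
    mu_arr = np.broadcast_to(np.atleast_1d(mu).astype(float), (n_traits,)).copy()
    h2_arr = np.broadcast_to(np.atleast_1d(h2).astype(float), (n_traits,)).copy()
    return Architecture(idx, a, d, mu_arr, h2_arr)


def _check_positions(idx: np.ndarray, genome) -> None:
    if idx.size and (idx.min() < 0 or idx.max() >= genome.n_snps):
        raise ValueError("QTN position outside the genome SNP list")
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate QTN positions")


def genotypic_value(dosages: np.ndarray, arch: Architecture, ploidy: int) -> np.ndarray:
    """Genotypic values (n_individuals, n_traits) from QTN dosages.

    ``dosages`` holds allele-1 copy numbers at the QTN (columns in
    ``arch.qtn_indices`` order). Structurally missing dosages (coded
    negative, e.g. Y-linked QTN in females) contribute nothing. Loci with
    fewer homologs than the nominal ploidy (male X) enter through the same
    dosage coding.
    """
    dos = np.atleast_2d(np.asarray(dosages, dtype=float))
    if arch.n_qtn == 0:
        return np.zeros((dos.shape[0], arch.n_traits))
    missing = dos < 0
    dos = np.where(missing, 0.0, dos)
    add_coef = dos - ploidy / 2.0
    if ploidy == 2:
        dom_coef = (dos == 1).astype(float)
    else:
        dom_coef = (dos >= 1).astype(float)
    add_coef[missing] = 0.0
    dom_coef[missing] = 0.0
    return add_coef @ arch.a + dom_coef @ arch.d


def calibrate_var_e(founder_g: np.ndarray, h2) -> np.ndarray:
    """Var(e) per trait from Var(e) = Var(g) (1 - H^2) / H^2.

    ``founder_g`` is the (n_founders, n_traits) matrix of base-population
    genotypic values; the population variance (divisor n) is used. A trait
    with Var(g) = 0 can only be calibrated at H^2 = 1.
    """
    g = np.atleast_2d(np.asarray(founder_g, dtype=float))
    if g.shape[0] < 2:
        raise ValueError("need at least two founders to calibrate Var(e)")
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(h2, dtype=float)), (g.shape[1],))
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("H^2 must lie in (0, 1]")
    var_g = g.var(axis=0)  # population variance
    bad = (var_g == 0) & (h2 < 1)
    if np.any(bad):
        raise ValueError("Var(g) = 0: heritability below 1 is uncalibratable")
    return var_g * (1.0 - h2) / h2


def simulate_phenotypes(g: np.ndarray, arch: Architecture, rng) -> TraitValue:
    """Draw e ~ N(0, Var(e)) independently per individual and trait."""
    if arch.var_e is None:
        raise ValueError("architecture not calibrated: var_e is unset")
    g = np.atleast_2d(np.asarray(g, dtype=float))
    e = rng.normal(0.0, np.sqrt(arch.var_e), g.shape)
    y = arch.mu + g + e
    return TraitValue(g, e, y)


def phenotype_population(pop, arch: Architecture, rng, ids=None,
                         calibrate: bool = True) -> None:
    """Decode QTN dosages, compute g, calibrate Var(e) on the base
    population if not yet done, and attach (g, e, y) to each individual.

    Only individuals without a phenotype are drawn; already-phenotyped
    individuals keep their values.
    """
    if calibrate and arch.var_e is None:
        base = pop.base_ids()
        g_base = genotypic_value(pop.decode(base, arch.qtn_indices), arch, pop.genome.ploidy)
        arch.var_e = calibrate_var_e(g_base, arch.h2)
    todo = [i for i in (range(pop.size) if ids is None else ids)
            if pop[i].y is None]
    if not todo:
        return
    g = genotypic_value(pop.decode(todo, arch.qtn_indices), arch, pop.genome.ploidy)
    tv = simulate_phenotypes(g, arch, rng)
    for row, i in enumerate(todo):
        pop[i].g = tv.g[row]
        pop[i].e = tv.e[row]
        pop[i].y = tv.y[row]


def qtn_variance_decomposition(arch: Architecture, frequencies: np.ndarray,
                               trait: int = 0, ploidy: int = 2,
                               founder_dosages: np.ndarray | None = None) -> pd.DataFrame:
    """Per-QTN variance components under one-locus equilibrium.

    For diploids, the allele substitution effect is alpha = a + d(1 - 2p)
    and the components are V_A = 2p(1-p) alpha^2, V_D = (2p(1-p) d)^2. For
    polyploids the components are computed empirically as the variances of
    the additive and dominance terms over ``founder_dosages``. Returns one
    row per QTN (MAF, alpha, V_A, V_D) sorted by MAF with cumulative
    variance columns — the data behind variance-vs-MAF, histogram and
    cumulative plots.
    """
    p = np.asarray(frequencies, dtype=float)[arch.qtn_indices]
    a = arch.a[:, trait]
    d = arch.d[:, trait]
    if ploidy == 2 or founder_dosages is None:
        alpha = a + d * (1.0 - 2.0 * p)
        va = 2.0 * p * (1.0 - p) * alpha**2
        vd = (2.0 * p * (1.0 - p) * d) ** 2
    else:
        dos = np.asarray(founder_dosages, dtype=float)
        alpha = a + d * (1.0 - 2.0 * p)
        va = ((dos - ploidy / 2.0) * a).var(axis=0)
        vd = ((dos >= 1).astype(float) * d).var(axis=0)
    df = pd.DataFrame(
        {
            "qtn_index": arch.qtn_indices,
            "p": p,
            "maf": np.minimum(p, 1 - p),
            "a": a,
            "d": d,
            "alpha": alpha,
            "var_additive": va,
            "var_dominance": vd,
        }
    ).sort_values("maf", kind="stable").reset_index(drop=True)
    df["cum_var_additive"] = df["var_additive"].cumsum()
    df["cum_var_dominance"] = df["var_dominance"].cumsum()
    return df


def read_qtn_file(path, genome, with_effects: bool) -> tuple[np.ndarray, tuple | None]:
    """Read a QTN file: ``chrom bp`` per line, or with per-trait effect
    pairs ``a_t d_t`` appended when ``with_effects``. Returns SNP indices
    (and the (a, d) arrays for the effects variant)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    idx = np.array(
        [genome.snp_index(str(c), int(float(b))) for c, b in zip(df.iloc[:, 0], df.iloc[:, 1])],
        dtype=np.int64,
    )
    if not with_effects:
        return idx, None
    eff = df.iloc[:, 2:].astype(float).to_numpy()
    if eff.shape[1] == 0 or eff.shape[1] % 2:
        raise ValueError("effects file needs an (a, d) pair per trait")
    a = eff[:, 0::2]
    d = eff[:, 1::2]
    return idx, (a, d)
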