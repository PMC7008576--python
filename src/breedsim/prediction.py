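"""Relationship matrices and single-trait genetic evaluation.

Implements the standard animal-model toolbox the selection cycle draws
from: the pedigree numerator relationship matrix A (tabular method), the
VanRaden genomic relationship matrix G computed on a SNP chip, the
single-step H-inverse combining both, and the mixed-model equations with
an overall mean as the only fixed effect and a user-supplied heritability
(variance components are never estimated). Mass selection (EBV = own
phenotype) and an export/import round trip for external evaluation
complete the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chip",
    "EvaluationResult",
    "compute_G",
    "compute_A",
    "compute_H_inverse",
    "blup_solve",
    "mass_selection_ebv",
    "evaluate",
    "export_evaluation_data",
    "import_ebvs",
]

G_DIAGONAL_INFLATION = 1.05


@dataclass
class Chip:
    """A genotyping array: a named subset of genome SNP indices.

    Chips let the same simulated data be evaluated under different
    genotyping strategies; a chip that excludes the QTN is how causal loci
    are hidden from evaluation.
    """

    name: str
    snp_indices: np.ndarray

    def __post_init__(self):
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)
        if np.unique(self.snp_indices).size != self.snp_indices.size:
            raise ValueError("chip SNP indices must be unique")

    @classmethod
    def from_file(cls, path, genome, name: str | None = None) -> "Chip":
        """One SNP per line: either ``chrom bp`` or a single integer index."""
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
        if df.shape[1] >= 2:
            idx = [genome.snp_index(str(c), int(float(b)))
                   for c, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
        else:
            idx = df.iloc[:, 0].astype(int).tolist()
        return cls(name or str(path), np.array(idx, dtype=np.int64))

    @property
    def n_snps(self) -> int:
        return int(self.snp_indices.size)


@dataclass
class EvaluationResult:
    """EBVs from one evaluation: method, chip (if any), h2 used, and which
    individuals' phenotypes entered the equations."""

    method: str
    chip: str | None
    ids: np.ndarray  # individuals receiving an EBV, in order
    ebv: np.ndarray
    h2: float | None
    phenotyped_ids: np.ndarray

    def ranking(self) -> np.ndarray:
        """Ids sorted by decreasing EBV (ties broken by ascending id)."""
        order = np.lexsort((self.ids, -self.ebv))
        return self.ids[order]


def compute_G(dosages: np.ndarray, inflate_diagonal: bool = True,
              ploidy: int | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix G = XX' / (2 sum p_j (1-p_j)).

    ``dosages`` is (individuals x chip SNPs); X is the dosage matrix with
    each column centered by its observed mean (2p_j for diploids, with p_j
    taken from the evaluated individuals themselves). The diagonal is then
    multiplied by 1.05 to ward off singularity. ``ploidy`` defaults to the
    smallest even level consistent with the observed dosages.
    """
    dos = np.asarray(dosages, dtype=float)
    if dos.ndim != 2 or dos.shape[1] < 1:
        raise ValueError("dosages must be (individuals x SNPs)")
    mean = dos.mean(axis=0)
    if ploidy is None:
        ploidy = _infer_ploidy(dos)
    p = mean / ploidy
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0 or not np.any(dos.var(axis=0) > 0):
        raise ValueError("all chip SNPs are monomorphic: G is degenerate")
    x = dos - mean
    g = x @ x.T / denom
    if inflate_diagonal:
        g[np.diag_indices_from(g)] *= G_DIAGONAL_INFLATION
    return g


def _infer_ploidy(dos: np.ndarray) -> int:
    m = float(np.nanmax(dos)) if dos.size else 2.0
    return max(2, int(np.ceil(m / 2.0)) * 2)


def compute_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` needs integer columns ``id``, ``sire``, ``dam`` with -1
    for unknown parents; rows must be sorted parents-first. Founders are
    taken as unrelated and non-inbred.
    """
    ids = pedigree["id"].to_numpy()
    pos = {int(v): i for i, v in enumerate(ids)}
    n = len(ids)
    sire = np.array([pos[int(s)] if int(s) >= 0 else -1 for s in pedigree["sire"]])
    dam = np.array([pos[int(d)] if int(d) >= 0 else -1 for d in pedigree["dam"]])
    if np.any(sire >= np.arange(n)) or np.any(dam >= np.arange(n)):
        raise ValueError("pedigree must be sorted parents-first (no cycles)")
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            a[i, :i] = a[:i, i] = 0.5 * (a[s, :i] + a[d, :i])
            a[i, i] = 1.0 + 0.5 * a[s, d]
        elif s >= 0 or d >= 0:
            k = max(s, d)
            a[i, :i] = a[:i, i] = 0.5 * a[k, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
    return a


def compute_H_inverse(a: np.ndarray, g: np.ndarray, genotyped: np.ndarray) -> np.ndarray:
    """Single-step combined matrix: H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1].

    ``genotyped`` holds row indices (into A's order) of the genotyped
    individuals, matching G's order. G should already carry the diagonal
    safeguard from :func:`compute_G`.
    """
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if g.shape != (genotyped.size, genotyped.size):
        raise ValueError("G must be square over the genotyped individuals")
    try:
        a_inv = np.linalg.inv(a)
        h_inv = a_inv.copy()
        if genotyped.size:
            a22_inv = np.linalg.inv(a[np.ix_(genotyped, genotyped)])
            g_inv = np.linalg.inv(g)
            h_inv[np.ix_(genotyped, genotyped)] += g_inv - a22_inv
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular matrix in single-step assembly ({err}); check that G "
            "has the diagonal safeguard and A22 individuals are connected"
        ) from err
    return h_inv


def blup_solve(
    y: np.ndarray,
    h2: float,
    relationship: np.ndarray | None = None,
    relationship_inv: np.ndarray | None = None,
    phenotyped: np.ndarray | None = None,
    method: str = "blup",
    chip: str | None = None,
    ids: np.ndarray | None = None,
) -> EvaluationResult:
    """Solve the single-trait animal-model mixed-model equations.

    The model is y = 1 mu + u + e with Var(u) proportional to the
    relationship matrix, lambda = (1 - h2)/h2, and the overall mean as the
    only fixed effect. ``y`` has one entry per individual in the
    relationship matrix with NaN marking unphenotyped individuals; every
    individual receives an EBV.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1) for BLUP")
    y = np.asarray(y, dtype=float)
    n = y.size
    if relationship_inv is None:
        if relationship is None:
            raise ValueError("need a relationship matrix or its inverse")
        if relationship.shape != (n, n):
            raise ValueError("relationship matrix does not match y length")
        try:
            relationship_inv = np.linalg.inv(relationship)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular relationship matrix: {err}") from err
    obs = np.nonzero(~np.isnan(y))[0] if phenotyped is None else np.asarray(phenotyped)
    if obs.size == 0:
        raise ValueError("no phenotyped individuals")
    lam = (1.0 - h2) / h2
    z = np.zeros((obs.size, n))
    z[np.arange(obs.size), obs] = 1.0
    yo = y[obs]
    # MME: [n_obs  1'Z; Z'1  Z'Z + K^-1 lam] [mu; u] = [1'y; Z'y]
    c = np.zeros((n + 1, n + 1))
    c[0, 0] = obs.size
    c[0, 1:] = z.sum(axis=0)
    c[1:, 0] = z.sum(axis=0)
    c[1:, 1:] = z.T @ z + relationship_inv * lam
    rhs = np.concatenate([[yo.sum()], z.T @ yo])
    try:
        sol = np.linalg.solve(c, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {err}") from err
    all_ids = np.arange(n) if ids is None else np.asarray(ids)
    return EvaluationResult(method, chip, all_ids, sol[1:], h2, all_ids[obs])


def mass_selection_ebv(y: np.ndarray, ids: np.ndarray | None = None) -> EvaluationResult:
    """EBV = own phenotype; individuals without a phenotype are excluded."""
    y = np.asarray(y, dtype=float)
    obs = np.nonzero(~np.isnan(y))[0]
    all_ids = np.arange(y.size) if ids is None else np.asarray(ids)
    return EvaluationResult("mass", None, all_ids[obs], y[obs], None, all_ids[obs])


def evaluate(pop, method: str, h2: float | None = None, chip: Chip | None = None,
             ids=None, trait: int = 0) -> EvaluationResult:
    """Run one genetic evaluation over ``ids`` (default: the whole
    population so far) and return EBVs for all of them.

    ``method`` is one of ``mass``, ``blup``, ``gblup``, ``ssgblup``. BLUP
    variants need ``h2``; genomic variants need a ``chip``. For
    ``ssgblup`` the genotyped set is taken as the chip-genotyped
    individuals recorded on the population (``pop.genotyped_ids``) or, if
    absent, all evaluated individuals.
    """
    idx = list(range(pop.size)) if ids is None else list(ids)
    y = np.array(
        [pop[i].y[trait] if pop[i].y is not None else np.nan for i in idx], dtype=float
    )
    ids_arr = np.asarray(idx)
    if method == "mass":
        return mass_selection_ebv(y, ids_arr)
    if h2 is None:
        raise ValueError(f"method {method!r} needs h2")
    if method == "blup":
        ped = pop.pedigree().iloc[idx].copy()
        # parents outside the window are treated as unknown
        inset = set(idx)
        ped["sire"] = [s if s in inset else -1 for s in ped["sire"]]
        ped["dam"] = [d if d in inset else -1 for d in ped["dam"]]
        a = compute_A(ped)
        return blup_solve(y, h2, relationship=a, method="blup", ids=ids_arr)
    if method in ("gblup", "ssgblup"):
        if chip is None:
            raise ValueError(f"method {method!r} needs a chip")
        if method == "gblup":
            g = compute_G(pop.decode(idx, chip.snp_indices), ploidy=pop.genome.ploidy)
            return blup_solve(y, h2, relationship=g, method="gblup",
                              chip=chip.name, ids=ids_arr)
        geno = getattr(pop, "genotyped_ids", None)
        geno = set(idx) if geno is None else (set(geno) & set(idx))
        rows = np.array([k for k, i in enumerate(idx) if i in geno], dtype=np.int64)
        ped = pop.pedigree().iloc[idx].copy()
        inset = set(idx)
        ped["sire"] = [s if s in inset else -1 for s in ped["sire"]]
        ped["dam"] = [d if d in inset else -1 for d in ped["dam"]]
        a = compute_A(ped)
        if rows.size == 0:
            return blup_solve(y, h2, relationship=a, method="ssgblup",
                              chip=chip.name, ids=ids_arr)
        g = compute_G(pop.decode([idx[k] for k in rows], chip.snp_indices), ploidy=pop.genome.ploidy)
        h_inv = compute_H_inverse(a, g, rows)
        return blup_solve(y, h2, relationship_inv=h_inv, method="ssgblup",
                          chip=chip.name, ids=ids_arr)
    raise ValueError(f"unknown evaluation method {method!r}")


def export_evaluation_data(pop, chip: Chip, dosage_path, phenotype_path,
                           ids=None, trait: int = 0) -> None:
    """Write chip dosages and phenotypes as id-keyed TSV for external GP."""
    idx = list(range(pop.size)) if ids is None else list(ids)
    dos = pop.decode(idx, chip.snp_indices)
    pd.DataFrame(dos, index=pd.Index(idx, name="id")).to_csv(dosage_path, sep="\t")
    y = [pop[i].y[trait] if pop[i].y is not None else np.nan for i in idx]
    pd.DataFrame({"id": idx, "y": y}).to_csv(phenotype_path, sep="\t", index=False)


def import_ebvs(path, pop, chip_name: str | None = None) -> EvaluationResult:
    """Read externally computed EBVs (``id value`` per line)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["id", "ebv"])
    ids = df["id"].astype(int).to_numpy()
    if ids.size and (ids.min() < 0 or ids.max() >= pop.size):
        raise ValueError("EBV file references unknown individual id")
    return EvaluationResult("external", chip_name, ids, df["ebv"].to_numpy(),
                            None, np.empty(0, dtype=int))
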