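"""Diagnostics on a population snapshot: PCA, single-marker GWAS, summaries.

These work on plain dosage matrices, so any SNP subset (whole sequence or
a chip) and any set of individuals can be analysed. Outputs are data
tables ready for plotting with any layer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["pca", "gwas", "summarize_population"]


def pca(dosages: np.ndarray, n_components: int = 2):
    """Principal components of a column-centered dosage matrix.

    Returns ``(scores, variance_explained)``: per-individual projections
    on the leading components and the fraction of total variance each
    explains. Dosages are centered but not variance-standardized. The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so results are deterministic.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-d dosage matrix with >= 2 individuals")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
        n_components = rank
    # deterministic sign: largest-|loading| coordinate positive
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    total = np.sum(s**2)
    explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, explained


def gwas(phenotypes: np.ndarray, dosages: np.ndarray, n_pcs: int = 0,
         chrom=None, bp=None) -> pd.DataFrame:
    """Single-marker association scan with Benjamini-Hochberg FDR.

    Each SNP is tested by least-squares regression of phenotype on dosage
    (two-sided t test, n-2 df). With ``n_pcs > 0`` the phenotype is first
    residualized on the leading principal components of the dosage matrix
    (population-structure correction). Monomorphic SNPs are reported with
    effect 0 and p = 1. Returns a table with chrom, bp (if given), effect,
    se, p and the BH q-value.
    """
    y = np.asarray(phenotypes, dtype=float)
    x = np.asarray(dosages, dtype=float)
    if y.ndim != 1 or x.shape[0] != y.size:
        raise ValueError("phenotype and dosage rows must align")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    if n_pcs > 0:
        scores, _ = pca(x, n_pcs)
        q, _ = np.linalg.qr(np.column_stack([np.ones(y.size), scores]))
        y = y - q @ (q.T @ y)
    n = y.size
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    poly = sxx > 0
    beta = np.zeros(x.shape[1])
    se = np.full(x.shape[1], np.nan)
    pval = np.ones(x.shape[1])
    if poly.any():
        sxy = xc[:, poly].T @ yc
        b = sxy / sxx[poly]
        # residual SS of y on each SNP separately
        ssy = (yc**2).sum()
        rss = np.maximum(ssy - b * sxy, 0.0)
        df = n - 2
        s2 = rss / df
        se_b = np.sqrt(s2 / sxx[poly])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se_b > 0, b / se_b, np.inf * np.sign(b))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        beta[poly] = b
        se[poly] = se_b
        pval[poly] = p
    _, qval, _, _ = multipletests(pval, method="fdr_bh")
    out = pd.DataFrame({"effect": beta, "se": se, "p": pval, "q": qval})
    if chrom is not None:
        out.insert(0, "chrom", np.asarray(chrom))
    if bp is not None:
        out.insert(1 if chrom is not None else 0, "bp", np.asarray(bp))
    return out


def summarize_population(pop, trait: int = 0) -> pd.DataFrame:
    """One row per generation: counts, phenotype and genotypic moments."""
    rows = []
    for t in range(pop.n_generations):
        ids = pop.ids_of_generation(t)
        y = np.array([pop[i].y[trait] for i in ids if pop[i].y is not None])
        g = np.array([pop[i].g[trait] for i in ids if pop[i].g is not None])
        rows.append(
            {
                "generation": t,
                "n": len(ids),
                "n_females": sum(pop[i].sex == "female" for i in ids),
                "n_males": sum(pop[i].sex == "male" for i in ids),
                "mean_y": y.mean() if y.size else np.nan,
                "var_y": y.var() if y.size else np.nan,
                "mean_g": g.mean() if g.size else np.nan,
                "var_g": g.var() if g.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
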