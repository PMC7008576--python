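"""The three-step breeding cycle: evaluate, select, mate.

Each generation, (1) EBVs are computed with the chosen method over the
evaluation window (all individuals so far, by default), (2) the top
``n_selected_females`` dams and ``n_selected_males`` sires among the
candidates are kept by truncation on EBV (ties broken by ascending id),
and (3) each selected dam produces ``offspring_per_female`` offspring with
her assigned sire under the chosen mating scheme (hierarchical by default;
random and assortative also available). Offspring are phenotyped at birth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import Architecture, phenotype_population
from .meiosis import FEMALE, MALE
from .prediction import Chip, EvaluationResult, evaluate, import_ebvs

logger = logging.getLogger(__name__)

__all__ = ["SelectionPlan", "select_parents", "return_new_ped", "run_cycles"]

METHODS = ("mass", "blup", "gblup", "ssgblup", "external")
MATING = ("hierarchical", "random", "assortative")


@dataclass
class SelectionPlan:
    """Everything a breeding program needs to run unattended."""

    n_generations: int
    n_selected_females: int
    n_selected_males: int
    offspring_per_female: int
    method: str = "mass"
    chip: Chip | None = None
    h2: float | None = None  # h2 used in the MME (not estimated)
    mating: str = "hierarchical"
    generations: str = "discrete"  # or "continuous"
    trait: int = 0

    def __post_init__(self):
        if min(self.n_generations, self.n_selected_females,
               self.n_selected_males, self.offspring_per_female) < 1:
            raise ValueError("plan counts must be positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.mating not in MATING:
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if self.generations not in ("discrete", "continuous"):
            raise ValueError("generations must be 'discrete' or 'continuous'")
        if self.method in ("blup", "gblup", "ssgblup") and self.h2 is None:
            raise ValueError(f"method {self.method!r} needs h2")
        if self.method in ("gblup", "ssgblup") and self.chip is None:
            raise ValueError(f"method {self.method!r} needs a chip")

    @property
    def cohort_size(self) -> int:
        return self.n_selected_females * self.offspring_per_female

    @classmethod
    def from_config(cls, path, genome=None) -> "SelectionPlan":
        """Read a key = value text config (chip given as a chip file path)."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        ints = {k: int(kv[k]) for k in
                ("n_generations", "n_selected_females", "n_selected_males",
                 "offspring_per_female") if k in kv}
        opt = {}
        for k in ("method", "mating", "generations"):
            if k in kv:
                opt[k] = kv[k]
        if "h2" in kv:
            opt["h2"] = float(kv["h2"])
        if "trait" in kv:
            opt["trait"] = int(kv["trait"])
        if "chip" in kv:
            if genome is None:
                raise ValueError("a genome is required to resolve the chip file")
            opt["chip"] = Chip.from_file(kv["chip"], genome)
        return cls(**ints, **opt)


def select_parents(candidate_ids, sexes, ebvs, n_f: int, n_m: int):
    """Truncation selection within sex: top-n by EBV, ties by ascending id.

    ``ebvs`` may be NaN for candidates without an EBV (e.g. unphenotyped
    under mass selection); those are never selected.
    """
    ids = np.asarray(candidate_ids)
    ebv = np.asarray(ebvs, dtype=float)
    sexes = np.asarray(sexes)
    out = []
    for sex, n in ((FEMALE, n_f), (MALE, n_m)):
        mask = (sexes == sex) & ~np.isnan(ebv)
        if mask.sum() < n:
            raise ValueError(
                f"only {int(mask.sum())} eligible {sex} candidates, need {n}"
            )
        sub_ids, sub_ebv = ids[mask], ebv[mask]
        order = np.lexsort((sub_ids, -sub_ebv))
        out.append(sub_ids[order[:n]])
    return out[0], out[1]  # dams, sires


def return_new_ped(dams, sires, plan: SelectionPlan, rng,
                   dam_ebv=None, sire_ebv=None) -> list[tuple[int, int]]:
    """Mating list of (dam, sire) pairs, one per selected dam.

    hierarchical: each sire serves ceil(n_f/n_m) consecutive dams (the
    remainder goes to the top sires); random: dams shuffled over sires;
    assortative: dams and sires rank-matched on EBV (the sire list is
    recycled when dams outnumber sires).
    """
    dams = list(dams)
    sires = list(sires)
    if len(sires) > len(dams):
        logger.warning(
            "more sires (%d) selected than dams (%d): surplus sires unused",
            len(sires), len(dams),
        )
    if plan.mating == "hierarchical":
        per = math.ceil(len(dams) / len(sires))
        pairs = [(d, sires[min(i // per, len(sires) - 1)]) for i, d in enumerate(dams)]
    elif plan.mating == "random":
        assign = rng.integers(0, len(sires), len(dams))
        pairs = [(d, sires[a]) for d, a in zip(dams, assign)]
    else:  # assortative: rank-match on EBV
        if dam_ebv is None or sire_ebv is None:
            raise ValueError("assortative mating needs dam and sire EBVs")
        d_order = np.lexsort((dams, -np.asarray(dam_ebv, dtype=float)))
        s_order = np.lexsort((sires, -np.asarray(sire_ebv, dtype=float)))
        pairs = [
            (dams[d_order[i]], sires[s_order[min(i, len(sires) - 1)] if len(sires) >= len(dams)
                                     else s_order[i * len(sires) // len(dams)]])
            for i in range(len(dams))
        ]
    return pairs


def run_cycles(pop, plan: SelectionPlan, arch: Architecture, rng,
               external_ebv_files=None) -> pd.DataFrame:
    """Run ``plan.n_generations`` breeding cycles in place.

    Returns the per-generation summary: cohort size, phenotype and
    genotypic mean/variance, and the realized accuracy corr(EBV, g) among
    candidates. The founder generation must be phenotyped first (done here
    if needed). ``external_ebv_files`` supplies one EBV file per cycle for
    ``method='external'``.
    """
    phenotype_population(pop, arch, rng)
    start_gen = pop.n_generations - 1
    ever_selected: set[int] = set()
    rows = [_summary_row(pop, pop.ids_of_generation(start_gen), start_gen, np.nan)]
    for cycle in range(plan.n_generations):
        gen = start_gen + cycle
        window = list(range(pop.size))
        if plan.method == "external":
            if not external_ebv_files:
                raise ValueError("method 'external' needs EBV files")
            res = import_ebvs(external_ebv_files[cycle], pop)
        else:
            res = evaluate(pop, plan.method, h2=plan.h2, chip=plan.chip,
                           ids=window, trait=plan.trait)
        ebv_of = dict(zip(res.ids.tolist(), res.ebv.tolist()))
        if plan.generations == "discrete":
            cands = pop.ids_of_generation(gen)
        else:
            cands = [i for i in window if i not in ever_selected]
        sexes = [pop[i].sex for i in cands]
        ebvs = [ebv_of.get(i, np.nan) for i in cands]
        dams, sires = select_parents(cands, sexes, ebvs, plan.n_selected_females,
                                     plan.n_selected_males)
        ever_selected.update(dams.tolist())
        ever_selected.update(sires.tolist())
        pairs = return_new_ped(dams, sires, plan, rng,
                               dam_ebv=[ebv_of[d] for d in dams],
                               sire_ebv=[ebv_of[s] for s in sires])
        newborn = []
        for dam, sire in pairs:
            for _ in range(plan.offspring_per_female):
                child = pop.add_offspring(int(dam), int(sire), rng, generation=gen + 1)
                newborn.append(child.id)
        phenotype_population(pop, arch, rng, ids=newborn)
        acc = _accuracy(pop, cands, ebvs, plan.trait)
        rows.append(_summary_row(pop, newborn, gen + 1, acc))
    return pd.DataFrame(rows)


def _accuracy(pop, cands, ebvs, trait) -> float:
    g = np.array([pop[i].g[trait] for i in cands], dtype=float)
    e = np.asarray(ebvs, dtype=float)
    ok = ~np.isnan(e)
    if ok.sum() < 3 or g[ok].std() == 0 or e[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(g[ok], e[ok])[0, 1])


def _summary_row(pop, ids, gen, accuracy) -> dict:
    y = np.array([pop[i].y[0] for i in ids if pop[i].y is not None], dtype=float)
    g = np.array([pop[i].g[0] for i in ids if pop[i].g is not None], dtype=float)
    return {
        "generation": gen,
        "n": len(ids),
        "mean_y": y.mean() if y.size else np.nan,
        "var_y": y.var() if y.size else np.nan,
        "mean_g": g.mean() if g.size else np.nan,
        "var_g": g.var() if g.size else np.nan,
        "accuracy": accuracy,
    }
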