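# breedsim

Forward-in-time simulation of breeding programs for quantitative-genetics
research: given founder genotypes, **breedsim** simulates meioses —
including autopolyploid, sex-linked and mitochondrial inheritance —
attaches complex-trait phenotypes under a user-specified QTN architecture,
and runs multi-generation selection schemes evaluated by mass selection,
pedigree BLUP, GBLUP or single-step GBLUP, with GWAS and PCA diagnostics.
It is aimed at breeders and quantitative geneticists who want to compare
genomic-prediction strategies (chips, methods, intensities) on realistic
genomes before committing to an experiment.

## The model

**Genomes as recombination blocks.** Descendant chromosomes are stored as
ordered blocks `(end_bp, founder_haplotype_id)` rather than SNP-by-SNP
allele lists: every allele ever observed traces back, by binary search,
to the phased founder matrix. This makes million-SNP simulations cheap in
memory and exactly reproducible.

**Meiosis.** Per chromosome, homologs are paired at random into bivalents
(ploidy/2 of them); within each bivalent the crossover count is
Poisson-distributed with mean equal to the genetic length in Morgans for
the parent's sex, crossover positions are uniform on the genetic map and
placed physically through the inverse map, and one recombinant strand per
bivalent enters the gamete. No interference, no obligate chiasma, no
preferential pairing or double reduction. Default map: 1 cM/Mb;
per-chromosome, sex-specific cumulative-cM maps are supported (an all-zero
male map gives achiasmate males). Sex chromosomes are capped at two
homologs; the Y is non-recombining and the mitochondrial chromosome is
transmitted maternally and intact. Dihaploids (doubled gametes) are
supported for diploids.

**Phenotypes.** For individual *i*, `y_i = mu + g_i + e_i` with
`e ~ N(0, Var(e))`. Diploid genotypic values use
`g = Σ γ_j a_j + Σ δ_j d_j` with γ ∈ {−1, 0, +1} and δ = 1 for
heterozygotes; polyploids use `g = Σ η_j a_j + Σ φ_j d_j` with
η = dosage − ploidy/2 and φ = 1 for every carrier of allele 1.
`Var(e)` is calibrated to a target broad-sense heritability from the
founder genotypic variance: `Var(e) = Var(g)(1 − H²)/H²`. Random
architectures draw |a| from Γ(shape = 0.2, scale = 5) with symmetric
random signs.

**Evaluation.** The genomic relationship matrix follows VanRaden,
`G = XX′ / (2 Σ p_j(1−p_j))` with mean-centered chip dosages and the
diagonal multiplied by 1.05 against singularity; A comes from the tabular
method; single-step combines them through
`H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]`. The mixed-model equations use an
overall mean as the only fixed effect and a user-supplied h²
(`λ = (1−h²)/h²`); heritabilities are never estimated.

## Worked example

```python
import numpy as np, tempfile
from breedsim import (Chip, Population, SelectionPlan, build_genome,
                      read_vcf, run_cycles, sample_architecture)
from breedsim.fixtures import make_fixture

paths = make_fixture(tempfile.mkdtemp(), n_founders=60, n_chrom=2,
                     n_snps=400, ld_blocks=20, seed=7)
founders, meta = read_vcf(paths["vcf"])     # ploidy auto-detected
genome = build_genome(meta)
rng = np.random.default_rng(7)
pop = Population(genome, founders)
arch = sample_architecture("random", founders, genome, rng, n_qtn=50, h2=0.5)
plan = SelectionPlan(n_generations=5, n_selected_females=15,
                     n_selected_males=5, offspring_per_female=8,
                     method="gblup", h2=0.5,
                     chip=Chip("seq", np.arange(genome.n_snps)))
print(run_cycles(pop, plan, arch, rng).round(2).to_string(index=False))
```

```
 generation   n  mean_y  var_y  mean_g  var_g  accuracy
          0  60  -14.23 311.24  -13.28 219.77       NaN
          1 120   -2.12 582.89   -1.68 226.61      0.67
          2 120   18.33 437.26   17.79 247.27      0.89
          3 120   38.15 353.72   38.75 116.51      0.95
          4 120   54.35 256.78   53.12  31.69      0.96
          5 120   60.39 213.58   59.86   9.85      0.97
```

Each row is one generation: `mean_g` is the true mean genotypic value
(the genetic gain — here +73 units over five GBLUP cycles), `var_g` the
genetic variance it erodes, and `accuracy` is corr(EBV, g) among the
selection candidates. Running the same plan with `method="mass"` gives a
gain of +65 with accuracies near 0.65 — the GBLUP advantage the simulator
exists to quantify. See `examples/` for gene dropping, polyploid/sex-linked
inheritance, and GWAS/PCA diagnostics; a thin CLI (`breedsim --help`)
wraps the same calls for shell use.

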