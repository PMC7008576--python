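# Methods

This note documents the models implemented in breedsim, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Genome representation and coordinates

Physical coordinates are 1-based base pairs, matching VCF. A genetic map
is a list of `(bp, cumulative cM)` anchors per chromosome and sex,
linearly interpolated between anchors; the last interval's rate is
extrapolated to the chromosome end, and the map is forced to start at
`(0, 0)`. With no user map the default is 1 cM/Mb everywhere, so a
chromosome's genetic length is `length_bp x 1e-8` Morgans exactly. The
inverse map (Morgans → bp) is the exact functional inverse inside
strictly increasing segments; inside flat (zero-rate) segments the left
endpoint is returned, which is immaterial because crossover positions are
drawn uniformly on the *genetic* axis and flat segments have measure
zero there. A chromosome's length defaults to its last SNP position when
no map file extends it, since VCF carries no lengths. An all-zero male
map is the supported mechanism for achiasmate males (the Drosophila
pattern); there is no special flag. Pseudo-autosomal regions and
crossover interference are out of scope.

Descendant chromosomes are block lists `(end_bp, founder_haplotype_id)`
covering `(0, length_bp]`, half-open at the start: a position `x` belongs
to the first block with `end >= x`. Crossover positions are floats, so
collisions with integer SNP positions essentially never occur, but the
tie rule above makes them well-defined anyway. Adjacent blocks with equal
haplotype id are fused after every meiosis; fusion never changes decoded
genotypes (tested).

## Meiosis

Per chromosome and meiosis: homologs are partitioned uniformly at random
into ploidy/2 bivalents; each bivalent receives `Poisson(L)` crossovers
(`L` = genetic length in Morgans for the parent's sex — zero crossovers
is possible, there is no obligate chiasma), at uniform genetic positions
mapped to bp through the inverse map; one of the two recombinant strands
enters the gamete with probability 1/2. Taking one strand per bivalent is
what yields exactly ploidy/2 gamete homologs; since the strand switches
template at every crossover, the expected crossover count *observed on a
transmitted strand* equals the map length in Morgans, which is the
standard definition of map distance and is what the acceptance check on
the default map verifies (~1 cM/Mb realized). Preferential pairing and
double reduction are deliberately not modelled.

Sex chromosomes carry at most two homologs regardless of autosomal
ploidy. A female recombines her two X copies as an ordinary bivalent; a
male transmits his X or his Y intact with equal probability (the male X
has no pairing partner, hence no recombination). Offspring sex equals the
paternal transmission (male iff Y received); when a specific offspring
sex is requested, the paternal choice is fixed accordingly rather than
rejection-sampled. Without sex chromosomes, sex is drawn 1:1. The
mitochondrial chromosome is one homolog, transmitted maternally, intact.
Dihaploids duplicate a single gamete (diploids only); the gamete is
forced X-bearing so dihaploids are female when sex chromosomes are
declared. New mutations are never generated: the simulator targets
short-horizon selection experiments, not long-term variability.

Every stochastic decision in a meiosis (pairing permutation, crossover
positions, strand choice) can be recorded in a trace. The test suite
replays traces on naive per-SNP allele vectors, which is the central
correctness check of the block machinery: both paths share the sampled
meiosis plan but no code.

## Founder input

VCF is read through cyvcf2; ploidy is the GT allele count and must be
uniform (any even level; odd ploidies are rejected). Within-GT allele
order is taken as phase, also for `/`-separated calls, because founder
haplotypes must be defined and typical inputs are phased panels or inbred
lines. Multi-allelic sites are dropped with a logged count. Missing calls
are imputed by drawing allele 1 with the site's observed frequency under
a caller-supplied seed — the simulator needs complete haplotypes. The
plink-like dialect is the classic 6-column PED + 4-column MAP, diploid
only, recoded 0/1 by first-observed allele; polyploids must come through
VCF. Founder sexes default to alternating female/male so both sexes are
always available; a pedigree or explicit list overrides this.

Dummy founders expand a small sequenced panel: `gene_drop` mode breeds
each dummy through a depth-2 random pedigree over real founders (random
grandparents → parents → dummy), a shape chosen as the smallest pedigree
that makes every dummy a genuine recombinant of several founders;
`random_blocks` mode draws Poisson breakpoints per homolog and fills
blocks with uniformly chosen founder haplotypes, which preserves founder
allele frequencies exactly in expectation and is the fastest way to a
large Hardy-Weinberg base population. Dummies are flagged as
base-population members (generation 0) and enter heritability
calibration.

## Trait architecture

Diploid genotypic values: `g = Σ γ a + Σ δ d`, γ = dosage − 1 ∈
{−1, 0, +1}, δ = 1 iff heterozygous. Polyploid: `g = Σ η a + Σ φ d`,
η = dosage − ploidy/2, and φ = 1 for *every* dosage ≥ 1: all carriers,
including the complete alternative homozygote, share the dominance
value — the one-parameter summary of polyploid dominance this model
family uses. Structurally missing dosages (Y-linked loci in females)
contribute nothing.

Random architectures draw QTN positions uniformly without replacement
from segregating SNPs and |a| from Γ(shape = 0.2, scale = 5) — scale,
not rate, so E|a| = 1 — with sign ±1 equiprobably, which avoids a
directional bias in the founder population that signed sampling is
silent about. Random-effect modes are single-trait and additive-only;
multi-trait and dominance architectures are specified explicitly in an
effects file (zero cross-trait effects encode no pleiotropy; genetic
correlations from linkage are not auto-adjusted). QTN stay in the
sequence SNP set; hide them from evaluation by defining a chip without
them.

`Var(e) = Var(g)(1 − H²)/H²` with `Var(g)` the *population* variance
(divisor n, declared for reproducibility) of base-population genotypic
values, including dominance terms — H² is broad-sense. Environmental
deviations are independent across individuals and traits. The per-QTN
variance decomposition uses the one-locus equilibrium forms
α = a + d(1 − 2p), `V_A = 2p(1−p)α²`, `V_D = (2p(1−p)d)²` with p from
the supplied frequencies; for polyploids the components are computed
empirically from founder dosages instead, since the diploid closed forms
do not carry over.

## Evaluation and selection

`G = XX′/(2Σ p_j(1−p_j))` with columns centered by their observed mean
dosage (equal to 2p for diploids); frequencies come from the evaluated
individuals themselves, a declared choice. The diagonal is multiplied by
1.05 — the standard ridge against singularity; off-diagonals are
untouched. A uses the tabular method with founders unrelated and
non-inbred. Single-step uses the basic block formula
`H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]` without τ/ω weighting or blending
beyond the G safeguard. The MME carry an overall mean as the only fixed
effect (the simulator generates no systematic environment), shrinkage
λ = (1−h²)/h² with h² supplied by the user, never estimated; every
individual in the relationship matrix receives an EBV, phenotyped or
not. Mass selection sets EBV = own phenotype and excludes unphenotyped
candidates. External evaluation is a text round trip: export chip
dosages + phenotypes, import id/EBV pairs.

The breeding cycle is evaluate → truncate → mate. The evaluation window
defaults to all individuals so far. Candidates are the latest cohort
(discrete generations) or all never-selected individuals (continuous).
Truncation is top-n within sex with ties broken by ascending id —
reproducibility over realism. Mating is hierarchical by default (each
sire serves ⌈n_f/n_m⌉ consecutive dams), or random (dams assigned to
sires uniformly), or assortative (rank-matching on EBV). Offspring sex
is drawn 1:1; offspring are phenotyped at birth, so they are visible to
the next cycle's evaluation. Reported `accuracy` is corr(EBV, true g)
among candidates, a diagnostic the simulator can compute because it
knows g. Optimal-contribution mating and multi-trait evaluation are out
of scope.

## Diagnostics

PCA centers dosages (no variance standardization) and uses SVD with a
deterministic sign convention (largest-|loading| coordinate positive).
GWAS is per-SNP ordinary least squares of phenotype on dosage with
two-sided t tests (n−2 df) and Benjamini-Hochberg q-values; monomorphic
SNPs report effect 0, p = 1. Population-structure correction, when
requested, residualizes the phenotype on the leading dosage PCs before
the scan; the same n−2 df are kept, a negligible approximation at the
sample sizes involved. Mixed-model GWAS and genomic control are out of
scope. Outputs are tables (chrom, bp, effect, se, p, q); plotting is
left to any layer the user prefers.

## Synthetic data

The fixture generator writes valid VCF 4.2 (any even ploidy, optional
X/Y and MT with a tenth of the autosomal SNP count each) plus map,
pedigree, QTN and chip files — every format the package reads is
produced by it. Default founders are unrelated with independent sites
(per-SNP frequencies ~ U(0.05, 0.95)): sufficient for unit-level checks
but without LD, so marker-based prediction of *unphenotyped* individuals
barely works there. The block-LD mode draws founder chromosomes from a
small shared haplotype pool (default 4 haplotypes per block), giving the
strong marker-QTN associations the GP-accuracy checks need. Neither mode
reproduces real LD decay, demography or selection history; passing tests
demonstrate the machinery's correctness, not performance on any real
population — for realistic scenarios, feed real sequence data in.

## Problem sizes and numerics

Test and acceptance workloads are sized to run in seconds: oracle
pedigrees of 5 generations × 4 individuals over 80–100 SNPs (diploid and
tetraploid), heritability calibration on 10,000 base individuals,
selection response at 500 offspring per generation for 5 generations,
GWAS scans of up to 1,000 SNPs × 500 individuals, and 10,000 meioses for
the recombination-rate check. Matrix solves use dense LAPACK routines
(`numpy.linalg`); MME toys are verified against independently assembled
dense systems to 1e-8. All randomness flows through a single
`numpy.random.Generator`: the same seed yields bit-identical populations,
phenotypes and selection decisions.

## Known limitations

No epistasis or imprinting; no mutation; no gene conversion or
multivalents; no pseudo-autosomal region; no crossover interference; no
variance-component estimation; single-trait evaluation only (multi-trait
phenotypes can be simulated, but each evaluation uses one trait); the
plink dialect is intentionally narrow. Polyploid meiosis is the
simplified bivalent model — adequate for comparing GP strategies over a
few generations, not for studying polysomic segregation itself.
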