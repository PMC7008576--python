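"""A five-generation breeding program: mass selection vs GBLUP.

Simulates a trait with 50 QTN (gamma-distributed effects, H2 = 0.5) on a
founder panel with block LD, then runs the evaluate-select-mate cycle
with two evaluation methods and prints the genetic gain per generation.
"""

import tempfile

import numpy as np

from breedsim import (
    Chip, Population, SelectionPlan, build_genome, read_vcf,
    run_cycles, sample_architecture,
)
from breedsim.fixtures import make_fixture

tmp = tempfile.mkdtemp()
paths = make_fixture(tmp, n_founders=60, n_chrom=2, n_snps=400,
                     ld_blocks=20, seed=7)

for method in ("mass", "gblup"):
    founders, meta = read_vcf(paths["vcf"])
    genome = build_genome(meta)
    rng = np.random.default_rng(7)
    pop = Population(genome, founders)
    arch = sample_architecture("random", founders, genome, rng,
                               n_qtn=50, h2=0.5)
    chip = Chip("seq", np.arange(genome.n_snps))  # all SNPs on the array
    plan = SelectionPlan(
        n_generations=5, n_selected_females=15, n_selected_males=5,
        offspring_per_female=8, method=method, h2=0.5,
        chip=chip if method == "gblup" else None,
    )
    summary = run_cycles(pop, plan, arch, rng)
    print(f"\n=== {method} selection ===")
    print(summary.round(2).to_string(index=False))
    gain = summary["mean_g"].iloc[-1] - summary["mean_g"].iloc[0]
    print(f"total genetic gain over 5 generations: {gain:.2f}")

print("\nmean_g rises every generation under both methods; 'accuracy' is")
print("corr(EBV, true g) among candidates — the EBVs used for truncation.")
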