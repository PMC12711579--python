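"""Simulate an F2 population with known crossover truth.

Builds a five-chromosome 30-Mb genome, simulates 300 F2 individuals under
the wild-type-like preset (gamma-renewal interference, shape 5, ~8.4 COs
per individual genome-wide) and prints what the population looks like.
"""

import numpy as np

from meicos import generate_population, uniform_genome
from meicos.simulate import wt_preset

genome = uniform_genome(n_chromosomes=5, chrom_length=30_000_000)
config = wt_preset(genome=genome, n_individuals=300, seed=1)
pop = generate_population(config)

true_total = sum(t.co_positions.size for t in pop.truth)
n_markers = sum(m.size for m in pop.markers.values())
missing = (pop.genotypes["genotype"] == "NA").mean()

print(f"individuals:            {len(pop.individuals)}")
print(f"markers (5 chromosomes): {n_markers} (~50-kb spacing)")
print(f"genotype calls:         {len(pop.genotypes)} ({missing:.1%} missing)")
print(f"true COs:               {true_total} "
      f"({true_total / len(pop.individuals):.2f} per individual)")

# Interference is visible in the truth itself: inter-CO distances on one
# gamete are further apart than random expectation.
gaps = np.concatenate(
    [np.diff(t.co_positions) for t in pop.truth if t.co_positions.size > 1]
)
print(f"median same-gamete inter-CO distance: {np.median(gaps) / 1e6:.1f} Mb")
print("(under strong interference this approaches the chromosome scale)")
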