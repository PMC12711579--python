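"""Call crossovers from marker genotypes and count them per individual.

Simulates a population, converts the marker genotype table into genotype
segments and CO events, and checks the caller against the simulator's
ground truth.
"""

from meicos import (
    call_population,
    generate_population,
    per_individual_counts,
    uniform_genome,
)
from meicos.simulate import wt_preset

genome = uniform_genome()
config = wt_preset(genome=genome, n_individuals=300, seed=2)
pop = generate_population(config)

segments, events = call_population(pop.genotypes, min_support=3)
counts = per_individual_counts(events, pop.individuals, genome)
true_total = sum(t.co_positions.size for t in pop.truth)

print(f"genotype segments: {len(segments)}")
print(f"called COs:        {len(events)} (truth: {true_total})")
print(f"mean COs per individual: {counts['total'].mean():.2f}")
print(f"stacked (two-step) transitions: {int(events['stacked'].sum())}")
print()
print("per-chromosome means:")
print(counts.drop(columns='total').mean().round(2).to_string())
# A CO is bounded by the flanking markers; its midpoint is the position
# used by every downstream analysis.
width = (events["right"] - events["left"]).median() / 1e3
print(f"\nmedian CO resolution (marker interval): {width:.0f} kb")
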