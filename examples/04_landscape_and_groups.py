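"""CO landscapes, arm vs pericentromere counts and group comparisons.

Simulates two genotype groups at different CO intensities, builds 300-kb
window landscapes and the telomere->centromere arm-scaled profile, splits
counts by region, and tests the group difference with rank statistics.
"""

import pandas as pd

from meicos import (
    arm_scaled_profile,
    call_population,
    compare_groups,
    generate_population,
    percent_change_summary,
    region_counts,
    uniform_genome,
    window_co_frequency,
)
from meicos.simulate import clustered_preset, wt_preset

genome = uniform_genome()
tables = []
for label, preset in [("wt", wt_preset), ("mutant", clustered_preset)]:
    pop = generate_population(preset(genome=genome, n_individuals=260, seed=4))
    _, events = call_population(pop.genotypes)
    rc = region_counts(events, genome, pop.individuals)
    rc["group"] = label
    tables.append(rc)

    land = window_co_frequency(events, genome, len(pop.individuals), 300_000)
    prof = arm_scaled_profile(land, genome)
    tel = prof.loc[prof.scaled_bin < 0.25, "mean_freq"].mean()
    cen = prof.loc[prof.scaled_bin > 0.75, "mean_freq"].mean()
    print(f"{label}: mean COs/individual {rc['total'].mean():.2f} "
          f"(arm {rc['arm'].mean():.2f}, pericentromere {rc['pericentromere'].mean():.2f})")
    print(f"  scaled landscape: telomeric quartile {tel:.4f} vs "
          f"centromeric quartile {cen:.4f} COs/individual/300 kb")

counts = pd.concat(tables, ignore_index=True)
report = compare_groups(counts)
print(f"\nKruskal-Wallis on totals: p = {report['kruskal_wallis']['p']:.3g}")
for pair, res in report["dunn_total"].items():
    print(f"Dunn {pair}: adjusted p = {res['p_adjusted']:.3g}")
wil = report["wilcoxon"]["pericentromere"]["wt_vs_mutant"]
print(f"Wilcoxon pericentromere wt vs mutant: adjusted p = {wil['p_adjusted']:.3g}")

# Summary arithmetic in the style of fertility comparisons: a reference
# mean against several group means.
summary = percent_change_summary(52, {"line-a": 32, "line-b": 39, "line-c": 25})
print(f"\npercent-change summary vs reference 52: "
      f"pooled change {summary['pooled_percent_change']:.1f}%")
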