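"""Sliding-window density profiling and constrained-region recovery.

Simulates a gnomAD-like variant table for an 8,778-bp CDS with one
planted 1,500-bp low-density segment (intensity thinned to 10%), runs
the 201-bp sliding-window profiler, calls low-/high-density regions
against an expected-density threshold, and scores how well the called
LDR recovers the planted segment (Jaccard overlap).  Profiles of two
populations are then compared position-by-position as a similarity
percentage.
"""

import numpy as np

from varburden import call_regions, density_profile, profile_similarity
from varburden.simulate import SimulationConfig, simulate_frequency_table

config = SimulationConfig(seed=5, n_variants=2_000,
                          ldr_segments=(((3_000, 4_500), 0.1),))
records, truth = simulate_frequency_table(config)
gene = config.gene
background = config.n_variants / gene.cds_length  # variants per bp

profiles = {}
for pop in ("GLOBAL", "NFE"):
    profile = density_profile(records, gene, pop)
    profiles[pop] = profile.with_threshold(background / 2)

regions = call_regions(profiles["GLOBAL"])
called = regions.label_array() == "LDR"
planted = np.zeros(gene.cds_length, dtype=bool)
planted[3_000:4_500] = True
jaccard = (called & planted).sum() / (called | planted).sum()

print(f"{len(records)} variants on a {gene.cds_length}-bp CDS; "
      f"background density {background:.3f}/bp, threshold {background / 2:.3f}/bp")
print(f"called regions: {[(s, e, l) for s, e, l in regions.regions]}")
print(f"planted LDR [3000, 4500) recovered with Jaccard {jaccard:.3f}")

sim = profile_similarity(regions, call_regions(profiles["NFE"]))
print(f"GLOBAL vs NFE region-label similarity: {sim:.2f}%")
print("A Jaccard near 1 means the constrained segment was located almost "
      "exactly; similarity is the fraction of CDS positions on which two "
      "populations agree about constraint.")
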