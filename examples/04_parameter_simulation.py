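"""Recurrence-parameter simulation and the swap negative control.

Reproduces the two study-level simulations: ranking the 13 (q, z) scoring
configurations by AUC on idealised stemness vs non-stemness module
patterns, and the SGL->DGL swap control showing that mean recurrence FDR
is lowest on the intact stem-cell compendium.
"""

import smap

results = smap.run_param_study(seeds=range(10))
summary = smap.summarize_param_study(results)
print("mean AUC per (q, z) combination over 10 simulated compendia:")
print(summary.to_string(index=False))
print("\nAll q >= 2 configurations separate the planted MM/SM/SS stemness "
      "patterns from TS/NR negatives almost perfectly; q <= 1 pays a clear "
      "penalty because large unrelated modules accumulate spurious counts.")

fixture = smap.synth_compendium(smap.swap_study_config(), seed=7)
curve = smap.swap_experiment(fixture.compendium, fixture.modules,
                             swap_counts=(0, 9, 18, 27, 36), reps=3, seed=7,
                             params=smap.ScoringParams(permutations=300))
print("\nswap control (mean module FDR as SGLs are replaced by DGLs):")
print(curve.to_string(index=False))
print("\nThe intact compendium (0 swaps) has the lowest mean FDR; a roughly "
      "half-and-half mixture erases coherence in both directions and peaks, "
      "and a mostly-DGL compendium partially recovers because differentiated "
      "cells share expression programs of their own.")
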