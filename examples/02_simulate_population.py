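"""Simulate developing populations and compare terminal phenotypes.

Runs 200 individuals in environment E0 under each fitness landscape and
summarizes the terminal distribution of y0-increments: the concave
landscape converges the population (low spread, unimodal), the convex one
splits it toward the two specialized extremes (high spread, bimodality
coefficient above the 5/9 uniform benchmark).
"""

import numpy as np

from devfeedbacks import (
    FitnessSpec,
    ModelConfig,
    distribution_summary,
    sarle_bimodality,
    simulate_population,
    solve,
)

for shape in ("concave", "linear", "convex"):
    config = ModelConfig(
        T=20, q=0.55, fitness=FitnessSpec.from_shape(shape), N=200, seed=42
    )
    _, policy, _ = solve(config)
    result = simulate_population(config, policy)
    term = result.terminal_n0.astype(float)
    b = sarle_bimodality(term)
    summary = distribution_summary(result, (5, 10, 20))
    print(f"{shape:>8}: terminal n0 mean={term.mean():5.2f} sd={term.std(ddof=1):5.2f} "
          f"bimodality b={b:.3f} {'(> 5/9: bimodal-leaning)' if b > 5/9 else '(< 5/9: unimodal-leaning)'}")
    hist = summary.histograms[20]
    print(f"          histogram of terminal n0 (0..20): {hist.tolist()}")
print()
print("Mass piles at both ends (0 and 20) only under the convex landscape:")
print("positive feedback amplifies early stochastic differences in cues into")
print("two divergent developmental trajectories - emergent individuality.")
print("(b estimates at N = 200 are noisy; the concave/convex ordering around")
print("5/9 is the robust quantity, sharp at N = 10,000.)")
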