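"""Phenotypic phase diagram: developmental channeling through (n0, n1) space.

Simulates 10,000 convex-landscape individuals in E0 and prints, for cells
on and near the diagonal, the conditional probability that the next
increment is y0 - the 'flow field' through phenotypic space - plus the mean
developmental path.
"""

import numpy as np

from devfeedbacks import (
    FitnessSpec,
    ModelConfig,
    empirical_mean_path,
    phase_diagram,
    simulate_population,
    solve,
)

config = ModelConfig(T=20, q=0.55, fitness=FitnessSpec.from_shape("convex"), N=10_000, seed=3)
_, policy, _ = solve(config)
result = simulate_population(config, policy)
pd_ = phase_diagram(result)

print("P(next increment is y0 | state), convex landscape, E0 (rows n0, cols n1):")
print("      " + " ".join(f"n1={j:<2}" for j in range(6)))
for n0 in range(8):
    row = []
    for n1 in range(6):
        v = pd_.p_y0[n0, n1]
        row.append(" --- " if np.isnan(v) else f"{v:5.2f}")
    print(f"n0={n0:<2} " + " ".join(row))

path = empirical_mean_path(result)
print()
print(f"mean terminal state: n0={path[-1,0]:.2f}, n1={path[-1,1]:.2f}")
print()
print("Off-diagonal cells are absorbing: once an individual leads by a few")
print("increments in one direction, the probability of continuing that way")
print("approaches 1.  Early divergence is created and then maintained -")
print("the channeling behind the bimodal terminal distribution.")
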