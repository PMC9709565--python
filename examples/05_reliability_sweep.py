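"""Sweep cue reliability: feedback signs are robust, their consequences not.

Solves and simulates every (q, landscape) pair on a reliability grid and
prints the summary table: the threshold trend (feedback sign) per landscape
is constant across informative reliabilities, while the contrast in
population individuality (bimodality b, spread) is starkest when cues are
least informative.
"""

from devfeedbacks import ModelConfig, reliability_sweep

base = ModelConfig(T=20, N=2000, seed=17)
table = reliability_sweep(base, q_grid=(0.5, 0.55, 0.65, 0.75, 0.85, 0.95, 1.0))
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("tau_trend: increasing = negative feedback, decreasing = positive,")
print("flat = none; the sign never changes with q.  At q = 0.5 the concave")
print("population collapses to a single phenotype (sd = 0, b undefined -")
print("conservative bet-hedging) while the convex one splits half/half")
print("between the extremes (diversified bet-hedging).  At q = 1 all")
print("variation vanishes: every individual specializes fully and correctly.")
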