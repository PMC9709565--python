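"""Independent brute-force solvers used as correctness oracles in tests.

Both deliberately avoid the backward-induction machinery: they carry raw
likelihood weights along full cue histories instead of posterior tables and
predictive probabilities, so agreement with the DP solver is a genuine
cross-check of the (t, n0, x) state aggregation and the recursion, not a
tautology.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .core import ModelConfig, fitness_value

__all__ = ["expectimax_oracle", "exhaustive_policy_search"]

_EXPECTIMAX_MAX_T = 12
_EXHAUSTIVE_MAX_T = 3


def expectimax_oracle(config: ModelConfig) -> float:
    """Root value by full-history expectimax, with no state aggregation.

    Enumerates every cue sequence, carrying the unnormalized joint weights
    of (sequence, environment) for both environments, and maximizes over
    the action at every history node.  Maximizing the unnormalized
    conditional expectation is equivalent to maximizing the posterior
    expectation, since the normalizer at a node is positive and common to
    both actions.  Exponential in T; guarded to T <= 12.
    """
    T, q = config.T, config.q
    if T > _EXPECTIMAX_MAX_T:
        raise ValueError(f"expectimax oracle refuses T={T} > {_EXPECTIMAX_MAX_T}")
    spec = config.fitness

    def rec(t: int, n0: int, w0: float, w1: float) -> float:
        # w0/w1: joint weight of (history so far, E0/E1)
        if t == T:
            return w0 * fitness_value(n0, T, spec) + w1 * fitness_value(T - n0, T, spec)
        total = 0.0
        for cue_is_c0 in (True, False):
            nw0 = w0 * (q if cue_is_c0 else 1.0 - q)
            nw1 = w1 * (1.0 - q if cue_is_c0 else q)
            best = max(
                rec(t + 1, n0 + 1, nw0, nw1),  # act y0
                rec(t + 1, n0, nw0, nw1),  # act y1
            )
            total += best
        return total

    return rec(0, 0, config.prior_p0, 1.0 - config.prior_p0)


def exhaustive_policy_search(config: ModelConfig) -> float:
    """Best root value over ALL deterministic state-policies, by enumeration.

    Enumerates every mapping from states (t, n0, x) to {y0, y1} — 2^20
    policies at T = 3 — and evaluates each exactly over all cue sequences
    and both environments.  Independent of the recursion structure
    entirely; guarded to T <= 3.
    """
    T, q, prior = config.T, config.q, config.prior_p0
    if T > _EXHAUSTIVE_MAX_T:
        raise ValueError(f"exhaustive search refuses T={T} > {_EXHAUSTIVE_MAX_T}")

    # Flat index for state (t, n0, x): n0 in 0..t-1, x in 0..t.
    index: dict[tuple[int, int, int], int] = {}
    for t in range(1, T + 1):
        for n0 in range(t):
            for x in range(t + 1):
                index[(t, n0, x)] = len(index)
    n_states = len(index)

    f = np.array([fitness_value(k, T, config.fitness) for k in range(T + 1)])
    pols = np.arange(2**n_states, dtype=np.int64)  # bit s = 1 means y0 at state s
    value = np.zeros(pols.shape, dtype=float)

    for cues in product((1, 0), repeat=T):  # 1 = c0
        w0 = prior * np.prod([q if c else 1.0 - q for c in cues])
        w1 = (1.0 - prior) * np.prod([1.0 - q if c else q for c in cues])
        x = 0
        n0 = np.zeros(pols.shape, dtype=np.int64)
        for t in range(1, T + 1):
            x += cues[t - 1]
            idx = np.array([index[(t, int(k), x)] for k in range(t)])[n0]
            n0 = n0 + ((pols >> idx) & 1)
        value += w0 * f[n0] + w1 * f[T - n0]

    return float(value.max())
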