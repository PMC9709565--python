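"""Finite-horizon backward-induction solver for the developmental policy.

Decision epoch ``t`` (1..T) is the moment just after the t-th cue: the
individual has observed ``t`` cues (``x`` of them c0) and has already made
``t - 1`` increments (``n0`` toward y0).  Beliefs are indexed exactly by the
sufficient statistic ``(t, x)`` — never by floating-point posterior values —
so the state space is the integer grid ``(t, n0, x)`` with ``0 <= n0 <= t-1``
and ``0 <= x <= t``.

Terminal payoff of ending development with ``n0`` y0-increments, having seen
``x`` c0-cues: ``W(n0, x) = p0(T, x) * f(n0) + (1 - p0(T, x)) * f(T - n0)``;
only increments matching the true environment earn fitness.  The recursion
maximizes expected terminal fitness over the two actions, taking the
expectation over the next cue under the posterior predictive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    TIE_TOL,
    Y0,
    Y1,
    ModelConfig,
    cue_predictive,
    fitness_profile,
    posterior_table,
)

__all__ = [
    "ValueTable",
    "PolicyTable",
    "solve",
    "optimal_action",
    "greedy_map_policy",
    "reachable_states",
]


@dataclass(frozen=True)
class ValueTable:
    """Optimal expected terminal fitness per state.

    ``tables[t - 1]`` is the array for decision epoch t, shape (t, t + 1),
    indexed [n0, x].
    """

    T: int
    tables: list[np.ndarray]

    def value(self, t: int, n0: int, x: int) -> float:
        self._check(t, n0, x)
        return float(self.tables[t - 1][n0, x])

    def _check(self, t: int, n0: int, x: int) -> None:
        if not (1 <= t <= self.T and 0 <= n0 <= t - 1 and 0 <= x <= t):
            raise IndexError(f"invalid state (t={t}, n0={n0}, x={x}) for T={self.T}")


@dataclass(frozen=True)
class PolicyTable:
    """Optimal action per state, stored as the value margin of y0 over y1.

    ``delta(t, n0, x) = V(choose y0) - V(choose y1)``; the action is y0 when
    the margin exceeds the tie tolerance, y1 when it falls below its
    negative, and a tie otherwise (resolved by fair coin at simulation
    time).
    """

    T: int
    deltas: list[np.ndarray]
    posterior: list[np.ndarray]  # posterior[t][x] = P(E0 | t cues, x of them c0)

    def delta(self, t: int, n0: int, x: int) -> float:
        self._check(t, n0, x)
        return float(self.deltas[t - 1][n0, x])

    def action(self, t: int, n0: int, x: int) -> str:
        d = self.delta(t, n0, x)
        if d > TIE_TOL:
            return "y0"
        if d < -TIE_TOL:
            return "y1"
        return "tie"

    def action_codes(self, t: int) -> np.ndarray:
        """Array of action codes at epoch t: 0 = y0, 1 = y1, 2 = tie."""
        d = self.deltas[t - 1]
        out = np.full(d.shape, 2, dtype=np.int8)
        out[d > TIE_TOL] = Y0
        out[d < -TIE_TOL] = Y1
        return out

    def _check(self, t: int, n0: int, x: int) -> None:
        if not (1 <= t <= self.T and 0 <= n0 <= t - 1 and 0 <= x <= t):
            raise IndexError(f"invalid state (t={t}, n0={n0}, x={x}) for T={self.T}")


def solve(config: ModelConfig) -> tuple[ValueTable, PolicyTable, float]:
    """Solve the developmental program by backward induction.

    Returns the value table, the policy table, and the root value — the
    expected terminal fitness of an optimally developing individual before
    the first cue, with the first-cue expectation taken under the prior
    predictive.  Deterministic; no RNG is involved.
    """
    T, q = config.T, config.q
    f = fitness_profile(T, config.fitness)
    post = posterior_table(T, q, config.prior_p0)

    values: list[np.ndarray | None] = [None] * T
    deltas: list[np.ndarray | None] = [None] * T

    # Epoch T: the last increment decides the terminal count directly.
    p = post[T][np.newaxis, :]  # shape (1, T+1)
    n0 = np.arange(T)[:, np.newaxis]  # shape (T, 1)
    v_y0 = p * f[n0 + 1] + (1.0 - p) * f[T - n0 - 1]
    v_y1 = p * f[n0] + (1.0 - p) * f[T - n0]
    deltas[T - 1] = v_y0 - v_y1
    values[T - 1] = np.maximum(v_y0, v_y1)

    for t in range(T - 1, 0, -1):
        p = post[t][np.newaxis, :]  # (1, t+1)
        pc0 = p * q + (1.0 - p) * (1.0 - q)  # predictive P(next cue = c0)
        nxt = values[t]  # epoch t+1 table, shape (t+1, t+2)
        # choosing y0 moves to row n0+1; the next cue moves the column.
        v_y0 = pc0 * nxt[1:, 1:] + (1.0 - pc0) * nxt[1:, : t + 1]
        v_y1 = pc0 * nxt[:t, 1:] + (1.0 - pc0) * nxt[:t, : t + 1]
        deltas[t - 1] = v_y0 - v_y1
        values[t - 1] = np.maximum(v_y0, v_y1)

    pc0_root = cue_predictive(config.prior_p0, q)
    root_value = float(pc0_root * values[0][0, 1] + (1.0 - pc0_root) * values[0][0, 0])

    vt = ValueTable(T=T, tables=[np.asarray(v) for v in values])
    pt = PolicyTable(T=T, deltas=[np.asarray(d) for d in deltas], posterior=post)
    return vt, pt, root_value


def optimal_action(
    policy: PolicyTable, t: int, n0: int, x: int, rng: np.random.Generator
) -> int:
    """Look up the optimal action, resolving ties by fair coin.

    Returns the integer action code Y0 or Y1.
    """
    d = policy.delta(t, n0, x)
    if d > TIE_TOL:
        return Y0
    if d < -TIE_TOL:
        return Y1
    return Y0 if rng.random() < 0.5 else Y1


def greedy_map_policy(config: ModelConfig) -> PolicyTable:
    """Maximum-a-posteriori greedy policy, optimal under linear fitness.

    With constant returns the step value decomposes additively across
    timesteps, so choosing the currently more probable environment is
    optimal: y0 iff p0 > 0.5, y1 iff p0 < 0.5, tie at exactly 0.5.  The
    stored margin is ``p0 - 0.5`` (sign-equivalent to the DP value margin).
    """
    if config.fitness.shape != "linear":
        raise ValueError("greedy MAP policy is only optimal for linear fitness")
    T = config.T
    post = posterior_table(T, config.q, config.prior_p0)
    deltas = [
        np.tile(post[t] - 0.5, (t, 1)) for t in range(1, T + 1)
    ]
    return PolicyTable(T=T, deltas=deltas, posterior=post)


def reachable_states(policy: PolicyTable) -> list[np.ndarray]:
    """Boolean mask of states reachable under the policy.

    A state (t, n0, x) is reachable when some cue sequence of positive
    probability, with ties broken either way, leads to it.  Cue sequences
    all have positive probability for q < 1; for q = 1 only the all-c0 and
    all-c1 sequences do, which the forward sweep respects by construction
    only when callers avoid q = 1 (the mask then simply marks
    policy-consistent paths, which is what the analyses need).

    Returns a list indexed by t - 1 of masks shaped like the policy tables.
    """
    T = policy.T
    masks = [np.zeros((t, t + 1), dtype=bool) for t in range(1, T + 1)]
    masks[0][0, :] = True  # before any decision, both first cues occur
    for t in range(1, T):
        codes = policy.action_codes(t)
        cur = masks[t - 1]
        nxt = masks[t]
        for n0 in range(t):
            for x in range(t + 1):
                if not cur[n0, x]:
                    continue
                a = codes[n0, x]
                next_n0s = (n0, n0 + 1) if a == 2 else ((n0 + 1,) if a == Y0 else (n0,))
                for nn in next_n0s:
                    nxt[nn, x] = True
                    nxt[nn, x + 1] = True
        # x advances by the next cue; both cue outcomes have positive
        # probability for q < 1.
    return masks
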