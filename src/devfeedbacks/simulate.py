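"""Forward Monte-Carlo simulation of a developing population.

Every individual starts at the flat prior with zero increments, receives
i.i.d. cues drawn from the true environment (P(c0) = q in E0, 1 - q in E1),
updates its posterior, and takes the policy-optimal increment each timestep,
resolving policy ties by fair coin.  Each individual owns an RNG stream
derived from ``(master seed, individual index)``, so enlarging the
population never reshuffles earlier individuals' draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import C0, C1, TIE_TOL, Y0, Y1, ModelConfig, posterior_table
from .solver import PolicyTable

__all__ = ["IndividualTrajectory", "PopulationResult", "simulate_population", "empirical_mean_path"]


@dataclass(frozen=True)
class IndividualTrajectory:
    """One individual's development: cues, beliefs, actions, and states.

    ``states`` has length T + 1 and walks from (0, 0) to the terminal
    specialization state; step k moves one unit in the direction of
    ``actions[k]``.
    """

    cues: np.ndarray  # (T,) int8, C0/C1
    posteriors: np.ndarray  # (T,) float, P(E0) after each cue
    actions: np.ndarray  # (T,) int8, Y0/Y1
    states: np.ndarray  # (T+1, 2) int, (n0, n1) path


@dataclass(frozen=True)
class PopulationResult:
    """Stacked trajectories of N simulated individuals.

    Row i of each array is individual i.  ``n0_path[:, t]`` is the count of
    y0-increments after t decisions; n1 is recoverable as ``t - n0``.
    """

    config: ModelConfig
    cues: np.ndarray  # (N, T) int8
    posteriors: np.ndarray  # (N, T) float
    actions: np.ndarray  # (N, T) int8
    n0_path: np.ndarray  # (N, T+1) int16

    @property
    def true_env(self) -> str:
        return self.config.true_env

    @property
    def N(self) -> int:
        return self.cues.shape[0]

    @property
    def T(self) -> int:
        return self.cues.shape[1]

    @property
    def terminal_n0(self) -> np.ndarray:
        return self.n0_path[:, -1]

    def trajectory(self, i: int) -> IndividualTrajectory:
        T = self.T
        n0 = self.n0_path[i].astype(int)
        states = np.column_stack([n0, np.arange(T + 1) - n0])
        return IndividualTrajectory(
            cues=self.cues[i],
            posteriors=self.posteriors[i],
            actions=self.actions[i],
            states=states,
        )

    @property
    def trajectories(self) -> Iterator[IndividualTrajectory]:
        return (self.trajectory(i) for i in range(self.N))


def simulate_population(config: ModelConfig, policy: PolicyTable) -> PopulationResult:
    """Simulate N individuals developing under the solved policy.

    Fully reproducible: the same config (including seed) and policy yield a
    bit-identical result.  The policy must have been solved for the same
    (T, q, prior); a horizon mismatch is rejected.
    """
    if policy.T != config.T:
        raise ValueError(
            f"policy horizon T={policy.T} does not match config T={config.T}"
        )
    T, N, q = config.T, config.N, config.q
    p_c0 = q if config.true_env == "E0" else 1.0 - q
    post = posterior_table(T, q, config.prior_p0)
    deltas = policy.deltas

    cues = np.empty((N, T), dtype=np.int8)
    posteriors = np.empty((N, T), dtype=float)
    actions = np.empty((N, T), dtype=np.int8)
    n0_path = np.zeros((N, T + 1), dtype=np.int16)

    for i in range(N):
        rng = np.random.default_rng([config.seed, i])
        is_c0 = rng.random(T) < p_c0
        x = 0
        n0 = 0
        for t in range(1, T + 1):
            if is_c0[t - 1]:
                x += 1
                cues[i, t - 1] = C0
            else:
                cues[i, t - 1] = C1
            posteriors[i, t - 1] = post[t][x]
            d = deltas[t - 1][n0, x]
            if d > TIE_TOL:
                a = Y0
            elif d < -TIE_TOL:
                a = Y1
            else:
                a = Y0 if rng.random() < 0.5 else Y1
            actions[i, t - 1] = a
            if a == Y0:
                n0 += 1
            n0_path[i, t] = n0

    return PopulationResult(
        config=config, cues=cues, posteriors=posteriors, actions=actions, n0_path=n0_path
    )


def empirical_mean_path(result: PopulationResult) -> np.ndarray:
    """Mean specialization state (n0, n1) per timestep, shape (T + 1, 2).

    Coordinates sum to t at every step exactly, because every individual
    makes exactly one increment per timestep.
    """
    if result.N == 0:
        raise ValueError("empty population")
    mean_n0 = result.n0_path.mean(axis=0)
    t = np.arange(result.T + 1)
    return np.column_stack([mean_n0, t - mean_n0])
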