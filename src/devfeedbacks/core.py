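"""Core domain types and belief arithmetic.

The model: an individual develops for ``T`` timesteps in one of two
environmental conditions, ``E0`` or ``E1``, which it cannot observe
directly.  Each timestep it receives a binary cue (``c0`` or ``c1``) that
matches the true environment with reliability ``q``, updates its Bayesian
posterior that the environment is ``E0``, and then commits one irreversible
phenotypic increment toward ``y0`` or ``y1``.  Only increments matching the
true environment count toward terminal fitness, via a landscape
``f(k) = (k/T)**alpha`` whose curvature class (concave / linear / convex)
is the key ecological variable.

This module holds the shared configuration and state types, the fitness
family, and the exact belief arithmetic used by every other module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "C0",
    "C1",
    "Y0",
    "Y1",
    "TIE_TOL",
    "FitnessSpec",
    "ModelConfig",
    "BeliefState",
    "DevelopmentalState",
    "fitness_value",
    "fitness_profile",
    "posterior_from_counts",
    "posterior_table",
    "sequential_update",
    "cue_predictive",
    "load_config",
]

# Integer codes for cues and actions; CSV writers render them as c0/c1, y0/y1.
C0: int = 0
C1: int = 1
Y0: int = 0
Y1: int = 1

#: Absolute tolerance on a value margin below which two actions are a tie.
TIE_TOL: float = 1e-12

Shape = Literal["concave", "convex", "linear"]


@dataclass(frozen=True)
class FitnessSpec:
    """Curvature class and exponent of the terminal fitness landscape.

    The landscape is the normalized power family ``f(k) = (k/T)**alpha``:
    ``alpha < 1`` gives diminishing returns to specialization (concave),
    ``alpha > 1`` accelerating returns (convex), ``alpha = 1`` constant
    returns (linear).
    """

    shape: Shape = "linear"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("concave", "convex", "linear"):
            raise ValueError(f"unknown fitness shape: {self.shape!r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be a positive real, got {self.alpha}")
        if self.shape == "linear" and self.alpha != 1.0:
            raise ValueError("linear fitness requires alpha = 1")
        if self.shape == "concave" and not self.alpha < 1.0:
            raise ValueError("concave fitness requires 0 < alpha < 1")
        if self.shape == "convex" and not self.alpha > 1.0:
            raise ValueError("convex fitness requires alpha > 1")

    @classmethod
    def from_shape(cls, shape: Shape, alpha: float | None = None) -> "FitnessSpec":
        """Build a spec from a shape name with the default exponent.

        Defaults: 0.5 (concave), 1 (linear), 2 (convex).
        """
        if alpha is None:
            alpha = {"concave": 0.5, "linear": 1.0, "convex": 2.0}[shape]
        return cls(shape=shape, alpha=alpha)


@dataclass(frozen=True)
class ModelConfig:
    """All free parameters of one model instance.

    Parameters
    ----------
    T : int
        Developmental horizon, number of cue/decision timesteps.
    q : float
        Cue reliability: probability a cue matches the true environment,
        in [0.5, 1].  0.5 is uninformative, 1 is a perfect cue.
    prior_p0 : float
        Prior probability that the environment is E0, in (0, 1).
    fitness : FitnessSpec
        Terminal fitness landscape.
    N : int
        Population size for forward simulation.
    true_env : {"E0", "E1"}
        The environment individuals actually develop in.
    seed : int
        Master RNG seed; all stochasticity derives from it.
    """

    T: int = 20
    q: float = 0.55
    prior_p0: float = 0.5
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    N: int = 200
    true_env: Literal["E0", "E1"] = "E0"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 1):
            raise ValueError(f"T must be a positive integer, got {self.T}")
        if not (0.5 <= self.q <= 1.0):
            raise ValueError(f"q must lie in [0.5, 1], got {self.q}")
        if not (0.0 < self.prior_p0 < 1.0):
            raise ValueError(f"prior_p0 must lie in (0, 1), got {self.prior_p0}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.true_env not in ("E0", "E1"):
            raise ValueError(f"true_env must be 'E0' or 'E1', got {self.true_env!r}")

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "T": int(self.T),
            "q": float(self.q),
            "prior_p0": float(self.prior_p0),
            "fitness": {"shape": self.fitness.shape, "alpha": float(self.fitness.alpha)},
            "N": int(self.N),
            "true_env": self.true_env,
            "seed": int(self.seed),
        }


@dataclass(frozen=True)
class BeliefState:
    """Informational state: cue counts and the posterior they imply."""

    t_cues: int
    x: int  # number of c0 cues among the t_cues observed
    q: float
    prior_p0: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.t_cues):
            raise ValueError(f"need 0 <= x <= t_cues, got x={self.x}, t_cues={self.t_cues}")

    @property
    def p0(self) -> float:
        return posterior_from_counts(self.t_cues, self.x, self.q, self.prior_p0)


@dataclass(frozen=True)
class DevelopmentalState:
    """Specialization state: increments accrued toward each direction."""

    n0: int
    n1: int

    def __post_init__(self) -> None:
        if self.n0 < 0 or self.n1 < 0:
            raise ValueError("increment counts must be non-negative")

    @property
    def t_dec(self) -> int:
        return self.n0 + self.n1


def fitness_value(k: int, T: int, spec: FitnessSpec) -> float:
    """Terminal fitness of ending development with ``k`` matching increments.

    ``f(k) = (k / T) ** alpha``, normalized so f(0) = 0 and f(T) = 1.
    """
    if not (0 <= k <= T):
        raise ValueError(f"matching count k={k} outside [0, {T}]")
    return float((k / T) ** spec.alpha)


def fitness_profile(T: int, spec: FitnessSpec) -> np.ndarray:
    """Fitness over the full grid k = 0..T as a float array."""
    f = (np.arange(T + 1) / T) ** spec.alpha
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite fitness values")
    return f


def posterior_from_counts(t_cues: int, x: int, q: float, prior_p0: float) -> float:
    """Posterior P(E0) after observing ``x`` c0-cues among ``t_cues`` cues.

    Computed in odds form, ``p0 = 1 / (1 + ((1-prior)/prior) * r**(2x - t))``
    with ``r = (1-q)/q``, which is exact for exchangeable cues and stable at
    large ``t``.  With q = 1 and mixed counts (0 < x < t) the evidence has
    zero likelihood under both environments; such states carry zero
    probability weight everywhere, and 0.5 is returned as a neutral sentinel
    so DP tables stay finite.
    """
    if not (0 <= x <= t_cues):
        raise ValueError(f"need 0 <= x <= t_cues, got x={x}, t_cues={t_cues}")
    if not (0.5 <= q <= 1.0):
        raise ValueError(f"q must lie in [0.5, 1], got {q}")
    if not (0.0 < prior_p0 < 1.0):
        raise ValueError(f"prior must lie in (0, 1), got {prior_p0}")
    if t_cues == 0:
        return prior_p0
    if q == 1.0:
        if x == t_cues:
            return 1.0
        if x == 0:
            return 0.0
        return 0.5  # zero-likelihood state, unreachable
    r = (1.0 - q) / q
    odds_against = (1.0 - prior_p0) / prior_p0 * r ** (2 * x - t_cues)
    return 1.0 / (1.0 + odds_against)


def posterior_table(T: int, q: float, prior_p0: float) -> list[np.ndarray]:
    """Posterior P(E0) for every cue-count state.

    Returns a list indexed by t = 0..T; entry t is the array of posteriors
    over x = 0..t.
    """
    return [
        np.array([posterior_from_counts(t, x, q, prior_p0) for x in range(t + 1)])
        for t in range(T + 1)
    ]


def sequential_update(p0: float, cue: int, q: float) -> float:
    """One-cue Bayes update of the posterior P(E0).

    The likelihood of the observed cue is ``q`` under the environment it
    points to and ``1 - q`` under the other, so ``L = q`` for c0 and
    ``L = 1 - q`` for c1.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if cue not in (C0, C1):
        raise ValueError(f"cue must be C0 (0) or C1 (1), got {cue}")
    if not (0.5 <= q <= 1.0):
        raise ValueError(f"q must lie in [0.5, 1], got {q}")
    L = q if cue == C0 else 1.0 - q
    denom = p0 * L + (1.0 - p0) * (1.0 - L)
    if denom == 0.0:
        return 0.5  # zero-likelihood observation (q = 1 against certainty)
    return p0 * L / denom


def cue_predictive(p0: float, q: float) -> float:
    """Marginal probability that the next cue is c0, given belief ``p0``."""
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    return p0 * q + (1.0 - p0) * (1.0 - q)


_CONFIG_KEYS = {"T", "q", "prior_p0", "fitness", "N", "true_env", "seed"}


def _config_from_dict(raw: dict) -> ModelConfig:
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    fit = kwargs.pop("fitness", None)
    if fit is not None:
        if isinstance(fit, str):
            kwargs["fitness"] = FitnessSpec.from_shape(fit)
        elif isinstance(fit, dict):
            extra = set(fit) - {"shape", "alpha"}
            if extra:
                raise ValueError(f"unknown fitness keys: {sorted(extra)}")
            kwargs["fitness"] = FitnessSpec.from_shape(
                fit.get("shape", "linear"), fit.get("alpha")
            )
        else:
            raise ValueError(f"fitness must be a shape name or mapping, got {fit!r}")
    return ModelConfig(**kwargs)


def load_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from a YAML or JSON file.

    All keys are optional; missing ones take the defaults (T = 20, q = 0.55,
    flat prior, N = 200).  Unknown keys are an error listing the offenders.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return _config_from_dict(raw)
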