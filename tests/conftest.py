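from functools import lru_cache

import pytest

from devfeedbacks import (
    FitnessSpec,
    ModelConfig,
    simulate_population,
    solve,
)

SHAPES = ("concave", "linear", "convex")


@lru_cache(maxsize=None)
def solved(shape: str, q: float = 0.55, T: int = 20):
    """Solved (values, policy, root) at the headline parameters, cached."""
    cfg = ModelConfig(T=T, q=q, fitness=FitnessSpec.from_shape(shape))
    return cfg, *solve(cfg)


@lru_cache(maxsize=None)
def big_population(shape: str, N: int = 10_000, seed: int = 11):
    """A large simulated population in E0 at q = 0.55, T = 20, cached."""
    cfg, _, policy, _ = solved(shape)
    cfg = cfg.with_(N=N, seed=seed, true_env="E0")
    return simulate_population(cfg, policy)


@pytest.fixture(scope="session", params=SHAPES)
def shape(request):
    return request.param
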