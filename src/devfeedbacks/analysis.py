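"""Analyses of behaviour-state feedbacks and their population consequences.

Three derived products diagnose the sign of the feedback between behaviour
(the next increment) and state (increments already accrued):

* **Threshold curves** — the minimum posterior belief in E0 at which a
  further y0 increment is (weakly) optimal, as a function of y0 increments
  already accrued.  A rising curve is a negative feedback (specialization
  self-limits, concave landscapes); a falling curve a positive feedback
  (specialization self-reinforces, convex landscapes); a flat curve severs
  the state-to-behaviour link (linear landscapes).
* **Phase diagrams** — empirical visit counts over the (n0, n1) grid with
  the conditional probability that the next increment is y0, summarizing
  developmental channeling through phenotypic space.
* **Distribution summaries** — moments and Sarle's bimodality coefficient of
  the n0 distribution at chosen timesteps, separating Gaussian-like
  convergence from bimodal divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TIE_TOL, Y0, FitnessSpec, ModelConfig
from .simulate import PopulationResult, simulate_population
from .solver import PolicyTable, reachable_states, solve

__all__ = [
    "ThresholdCurve",
    "PhaseDiagram",
    "DistributionSummary",
    "sarle_bimodality",
    "threshold_curve_from_policy",
    "threshold_curve_from_simulation",
    "epoch_threshold_boundary",
    "phase_diagram",
    "distribution_summary",
    "threshold_trend",
    "reliability_sweep",
]


@dataclass(frozen=True)
class ThresholdCurve:
    """Decision threshold tau(n0) per accrued y0 count, NaN where undefined."""

    tau: np.ndarray  # (T,) float, entry n0 in [0, 1] or NaN
    source: str  # "policy" or "simulation"

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.tau)


@dataclass(frozen=True)
class PhaseDiagram:
    """Visit counts and next-step direction over the (n0, n1) grid.

    ``count[n0, n1]`` is the number of individuals whose path passed through
    the state, over all pre-terminal steps (n0 + n1 < T); ``p_y0`` is the
    conditional probability the next increment was y0, NaN where unvisited.
    """

    count: np.ndarray  # (T, T) int
    p_y0: np.ndarray  # (T, T) float, NaN where count == 0


@dataclass(frozen=True)
class DistributionSummary:
    """Per-timestep histograms and shape statistics of the n0 distribution.

    ``bimodality`` is Sarle's coefficient b; b > 5/9 (the uniform's value)
    leans bimodal.  NaN where the sample is degenerate or too small.
    """

    timesteps: tuple[int, ...]
    histograms: dict[int, np.ndarray]  # timestep -> counts over n0 = 0..T
    moments: pd.DataFrame  # index timestep; mean, sd, skewness, excess_kurtosis, bimodality


def sarle_bimodality(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))).

    g1 is the bias-corrected sample skewness and g2 the bias-corrected
    excess kurtosis.  b equals 5/9 for the uniform distribution and
    approaches 1 for a symmetric two-point distribution.  Returns NaN for
    n < 4 or zero variance.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4 or np.var(values) == 0.0:
        return float("nan")
    g1 = stats.skew(values, bias=False)
    g2 = stats.kurtosis(values, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def threshold_curve_from_policy(
    policy: PolicyTable,
    include_ties: bool = True,
    restrict_reachable: bool = True,
) -> ThresholdCurve:
    """Exact decision-threshold curve from the solved policy.

    For each accrued count n0 = 0..T-1, tau(n0) is the minimum posterior
    P(E0) over states (t, n0, x) at which a further y0 increment is chosen.
    By default ties count as y0-choices (a tie picks y0 with probability
    one half at simulation time) and only policy-reachable states are
    scanned, so this curve is the exact large-population limit of the
    simulation estimator.  Entries with no qualifying state are NaN.
    """
    T = policy.T
    masks = reachable_states(policy) if restrict_reachable else None
    tau = np.full(T, np.nan)
    for t in range(1, T + 1):
        d = policy.deltas[t - 1]
        p = policy.posterior[t]
        chosen = d > TIE_TOL
        if include_ties:
            chosen = chosen | (np.abs(d) <= TIE_TOL)
        if masks is not None:
            chosen = chosen & masks[t - 1]
        for n0 in range(t):
            xs = np.nonzero(chosen[n0])[0]
            if xs.size:
                m = p[xs].min()
                if np.isnan(tau[n0]) or m < tau[n0]:
                    tau[n0] = m
    return ThresholdCurve(tau=tau, source="policy")


def epoch_threshold_boundary(
    policy: PolicyTable, t: int, include_ties: bool = True
) -> np.ndarray:
    """Decision boundary at a single epoch: min y0-posterior per n0.

    Within one epoch the reachable posteriors form a single grid, so this
    slice is free of the odd/even-epoch parity artifacts that can put a
    spurious kink in the epoch-aggregated curve at the last accruable count
    (where only the terminal epoch exists).  Trend signs of the feedback are
    therefore cleanest per epoch; the aggregated curve matches the
    population-level estimator.  Returns an array over n0 = 0..t-1, NaN
    where y0 is never (weakly) chosen.
    """
    d = policy.deltas[t - 1]
    p = policy.posterior[t]
    thr = -TIE_TOL if include_ties else TIE_TOL
    out = np.full(t, np.nan)
    for n0 in range(t):
        xs = np.nonzero(d[n0] > thr)[0]
        if xs.size:
            out[n0] = p[xs].min()
    return out


def threshold_curve_from_simulation(result: PopulationResult) -> ThresholdCurve:
    """Decision-threshold curve estimated from simulated decision events.

    Pools every decision event by the y0 count held at that moment and takes
    the minimum posterior among events where y0 was chosen; NaN where no y0
    choice was observed.  Converges to the policy-exact curve restricted to
    visited states as N grows.
    """
    T = result.T
    n0_at_decision = result.n0_path[:, :-1]  # (N, T): n0 before each decision
    chose_y0 = result.actions == Y0
    tau = np.full(T, np.nan)
    n0s = n0_at_decision[chose_y0].ravel()
    ps = result.posteriors[chose_y0].ravel()
    np.fmin.at(tau, n0s, ps)
    return ThresholdCurve(tau=tau, source="simulation")


def phase_diagram(result: PopulationResult) -> PhaseDiagram:
    """Empirical phenotypic phase diagram of a simulated population.

    Flow conservation holds exactly: the visit count at (n0, n1) equals the
    y0-inflow from (n0-1, n1) plus the y1-inflow from (n0, n1-1), with N at
    the origin.
    """
    T = result.T
    count = np.zeros((T, T), dtype=np.int64)
    y0_out = np.zeros((T, T), dtype=np.int64)
    steps = np.arange(T)
    n0 = result.n0_path[:, :-1].astype(np.int64)  # (N, T), state before step k+1
    n1 = steps[np.newaxis, :] - n0
    np.add.at(count, (n0.ravel(), n1.ravel()), 1)
    chose = (result.actions == Y0).astype(np.int64)
    np.add.at(y0_out, (n0.ravel(), n1.ravel()), chose.ravel())
    with np.errstate(invalid="ignore"):
        p_y0 = np.where(count > 0, y0_out / np.maximum(count, 1), np.nan)
    return PhaseDiagram(count=count, p_y0=p_y0)


def distribution_summary(
    result: PopulationResult, timesteps: tuple[int, ...] = (5, 10, 20)
) -> DistributionSummary:
    """Histograms and moments of the y0-count distribution at chosen times."""
    T = result.T
    bad = [t for t in timesteps if not (0 <= t <= T)]
    if bad:
        raise ValueError(f"timesteps {bad} outside [0, {T}]")
    histograms: dict[int, np.ndarray] = {}
    rows = []
    for t in timesteps:
        vals = result.n0_path[:, t].astype(float)
        histograms[t] = np.bincount(result.n0_path[:, t], minlength=T + 1)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        degenerate = np.var(vals) == 0.0
        rows.append(
            {
                "timestep": t,
                "mean": float(vals.mean()),
                "sd": sd,
                "skewness": float("nan") if degenerate else float(stats.skew(vals, bias=False)),
                "excess_kurtosis": float("nan")
                if degenerate
                else float(stats.kurtosis(vals, fisher=True, bias=False)),
                "bimodality": sarle_bimodality(vals),
            }
        )
    moments = pd.DataFrame(rows).set_index("timestep")
    return DistributionSummary(timesteps=tuple(timesteps), histograms=histograms, moments=moments)


def threshold_trend(curve: ThresholdCurve, flat_tol: float = 1e-9) -> str:
    """Classify a threshold curve as increasing, decreasing, flat, or mixed.

    The sign of the curve is the sign of the behaviour-state feedback:
    increasing = negative feedback, decreasing = positive feedback, flat =
    no feedback.  Only defined entries are compared.
    """
    tau = curve.tau[curve.defined()]
    if tau.size < 2:
        return "flat"
    d = np.diff(tau)
    if np.all(np.abs(d) <= flat_tol):
        return "flat"
    if np.all(d >= -flat_tol):
        return "increasing"
    if np.all(d <= flat_tol):
        return "decreasing"
    return "mixed"


def reliability_sweep(
    base: ModelConfig,
    q_grid: tuple[float, ...] = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0),
    shapes: tuple[str, ...] = ("concave", "linear", "convex"),
) -> pd.DataFrame:
    """Solve and simulate across a cue-reliability grid for each landscape.

    Returns one row per (q, shape) with the DP root value, the terminal-n0
    standard deviation, Sarle's b, and the threshold-curve trend.  Each
    row's simulation seed is derived deterministically from the master seed
    and the row index, so the whole table is reproducible from ``base.seed``.
    """
    rows = []
    idx = 0
    for q in q_grid:
        for shape in shapes:
            seed = int(
                np.random.SeedSequence([base.seed, idx]).generate_state(1)[0] % 2**31
            )
            cfg = base.with_(q=q, fitness=FitnessSpec.from_shape(shape), seed=seed)
            _, policy, root = solve(cfg)
            result = simulate_population(cfg, policy)
            terminal = result.terminal_n0.astype(float)
            curve = threshold_curve_from_policy(policy)
            rows.append(
                {
                    "q": q,
                    "shape": shape,
                    "root_value": root,
                    "sd": float(np.std(terminal, ddof=1)),
                    "b": sarle_bimodality(terminal),
                    "tau_trend": threshold_trend(curve),
                }
            )
            idx += 1
    return pd.DataFrame(rows)
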