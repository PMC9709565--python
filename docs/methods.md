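# Methods

## Model

An individual develops for `T` discrete timesteps in a fixed, hidden
environmental condition, E0 or E1.  Within each timestep the order of
events is: cue, belief update, choice.  The cue is binary and matches the
true environment with reliability `q ∈ [0.5, 1]`; cues are i.i.d. given
the environment (no autocorrelation).  The choice is an irreversible unit
increment toward one of two specializations, y0 or y1.  Fitness accrues
only at the end of development, from the count `k` of increments matching
the true environment, through the normalized power landscape

    f(k) = (k / T)^α,        f(0) = 0,  f(T) = 1,

with α = 0.5 (concave, diminishing returns), 1 (linear) or 2 (convex,
accelerating returns) as shape defaults; α is a free parameter within each
curvature class.  Normalization to [0, 1] is a convenience: the optimal
policy is invariant to positive affine rescaling of `f`, so only the
curvature class carries scientific content.  There are no intermediate
payoffs.

Defaults mirror the headline setting: `T = 20`, `q = 0.55`, flat prior
`P(E0) = 0.5`, populations of 200 (trajectory analyses) or 10,000
(threshold estimation).

## Belief arithmetic

With `x` c0-cues among `t` observed, the posterior is carried in odds form

    p0(t, x) = 1 / (1 + ((1 − prior)/prior) · r^(2x − t)),   r = (1 − q)/q,

which is exact (cues are exchangeable: only the counts matter) and stable
at large `t`.  The one-cue sequential update `p0 → p0·L / (p0·L +
(1−p0)(1−L))` with `L = q` for c0 is algebraically identical to the count
form; numerically the probability-space fold saturates once the belief
rounds to 1.0 in float64 (posterior odds beyond ~1e12), after which it
cannot walk back.  The tests therefore assert exact agreement (1e-12) in
the regime where odds along the path stay representable (q ≤ 0.8 at the
model horizon, any prior in [0.05, 0.95]); for q near 1 the fold's error
after a strong evidence swing can reach ~1e-10.  All internal computation
(solver, simulator, analyses) uses the count form and never folds, so this
limitation is confined to the convenience `sequential_update` API.

At `q = 1` a state with mixed cue counts has zero likelihood under both
environments; its posterior is set to 0.5 as a neutral sentinel.  Such
states carry zero probability weight in the recursion and are never
visited in simulation.

## Solver

Decision epoch `t ∈ 1..T` has `t` cues observed and `t − 1` increments
made, so the state is the integer triple `(t, n0, x)` — a sufficient
statistic; beliefs are never discretized or indexed by floating-point
values.  Backward induction:

    V(T, n0, x) = max_a W(n0 + [a = y0], x),
    W(m, x)     = p0(T, x) f(m) + (1 − p0(T, x)) f(T − m),
    V(t, n0, x) = max_a E_c [ V(t+1, n0 + [a = y0], x + [c = c0]) ],

with the next-cue expectation under the posterior predictive
`P(c0) = p0 q + (1 − p0)(1 − q)`.  The root value takes the first-cue
expectation at the prior.  The solve is vectorized per epoch and RNG-free.

**Ties.**  The policy stores the value margin `Δ = V(y0) − V(y1)`; an
action is a tie when `|Δ| ≤ 1e-12`.  Ties are resolved by fair coin at
simulation time, not frozen into the policy: with a flat prior the first
decision under `q = 0.5` is a tie, and a deterministic tie-break would
destroy the model's left/right symmetry in simulated populations.  The
1e-12 tolerance sits far above the ~1e-16 rounding noise of the recursion
and far below the smallest genuine margins observed (~1e-3 at `q = 0.55`).

**Correctness oracles** (test-only, separate arithmetic path): a
full-history expectimax that enumerates every cue sequence carrying raw
likelihood weights (no posterior tables, no state aggregation; guarded to
T ≤ 12), and an exhaustive enumeration of all 2^20 deterministic
state-policies at T ≤ 3 evaluated exactly over all sequences × both
environments.  DP, expectimax and exhaustive search agree to 1e-12 across
the small-horizon grid, which certifies both the recursion and the
sufficiency of `(t, n0, x)`.

## Simulation

Each individual draws its own RNG stream `default_rng([master_seed, i])`,
so results are bit-reproducible and enlarging the population never
reshuffles earlier individuals' draws.  Cues are drawn i.i.d. from the
true environment; actions are policy lookups with coin-flip ties.  The
simulator emulates exactly the stated world of the model — it adds no
observation noise, individual heterogeneity, or environmental change — so
a green distribution test establishes a property of the optimal program
under the model's assumptions, not of any real developmental system.

## Analyses

**Threshold curves.**  `tau(n0)` is the minimum posterior at which a
further y0 increment is chosen, per y0 count already accrued, aggregated
over epochs by the minimum.  Two estimators are provided: policy-exact and
simulation-based (minimum posterior among observed y0 choices, the
large-population estimator).  The policy-exact curve counts tie states as
y0-choices (a tie chooses y0 half the time in simulation) and restricts to
policy-reachable states, making it the exact `N → ∞` limit of the
simulation estimator.  Aggregating across epochs mixes posterior grids of
different parities (`2x − t` is even or odd with `t`); at `n0 = T − 1`,
where only the terminal epoch exists, this can put a spurious kink in the
aggregated curve at coarse grids (high `q`).  `epoch_threshold_boundary`
exposes the per-epoch decision boundary, which lives on a single grid and
is free of the artifact; feedback-sign (trend) checks across reliabilities
use it.

**Phase diagrams.**  Exact empirical visit counts over `(n0, n1)` with the
conditional probability of a next y0 step; flow conservation (visits =
y0-inflow + y1-inflow, origin = N) holds by construction and is asserted.

**Distribution summaries.**  Histograms and moments of `n0` at chosen
timesteps plus Sarle's bimodality coefficient

    b = (g1² + 1) / (g2 + 3(n−1)² / ((n−2)(n−3))),

with bias-corrected sample skewness g1 and excess kurtosis g2.  b = 5/9
for a uniform sample, → 1 for a symmetric two-point split, and is NaN for
n < 4 or zero variance.  A degenerate (zero-variance) population is the
perfectly-unimodal limit; where a contrast b(convex) − b(concave) is
formed across a reliability grid and the concave population is degenerate
(it is, at q = 0.5: every individual ends at exactly T/2), the degenerate
term is treated as 0.  The histogram variable is `n0`; in E0 the correctly
specialized mode sits at high `n0`, so the linear landscape's long tail
toward unspecialized phenotypes appears as *negative* skewness of `n0`
(the mirror-image orientation of plotting the error axis).

**Reliability sweep.**  One solve + simulate per `(q, shape)` with
per-row seeds derived from the master seed by `SeedSequence([seed, row])`.

## Pipeline and serialization

`run_solve`, `run_pipeline`, `run_figures` and `run_sweep` write headered
CSVs in fixed column order and deterministic row order (t, then n0, then
x), JSON for scalar summaries, and a manifest with the config echo,
derived seeds and SHA-256 checksums of every file.  Policy and value files
are seed-independent (the DP is RNG-free); identical seeds reproduce
identical bytes.  Configs load from YAML or JSON with all keys optional;
unknown keys raise an error listing the offenders.

## Known limitations

- Two environments, unit irreversible increments, no intermediate payoff,
  no frequency dependence or between-individual interaction: the model's
  scope, not an implementation shortcut.
- `sequential_update` saturates in float64 under extreme cumulative
  evidence (see Belief arithmetic); use the count form for long
  high-reliability sequences.
- The aggregated threshold curve inherits posterior-grid parity artifacts
  at its last point for coarse grids; per-epoch boundaries are the clean
  diagnostic.
- The exact parametric constants of the landscape family are a modelling
  choice; results are reported per curvature class, which is the level at
  which the conclusions hold.
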