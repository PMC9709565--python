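"""Feedback analyses: thresholds, phase diagrams, distributions, sweeps."""

import numpy as np
import pytest

from devfeedbacks import (
    FitnessSpec,
    ModelConfig,
    distribution_summary,
    epoch_threshold_boundary,
    phase_diagram,
    reliability_sweep,
    sarle_bimodality,
    simulate_population,
    solve,
    threshold_curve_from_policy,
    threshold_curve_from_simulation,
    threshold_trend,
)

from conftest import big_population, solved


class TestThresholdCurves:
    def test_linear_curve_is_flat_at_one_half(self):
        """No feedback under constant returns: the threshold never depends
        on accrued state."""
        _, _, policy, _ = solved("linear")
        curve = threshold_curve_from_policy(policy)
        assert np.allclose(curve.tau, 0.5, atol=1e-9)

    def test_concave_curve_rises_convex_falls(self):
        """Negative feedback (concave) raises the bar for further
        specialization; positive feedback (convex) lowers it."""
        _, _, pol_cc, _ = solved("concave")
        _, _, pol_cv, _ = solved("convex")
        assert threshold_trend(threshold_curve_from_policy(pol_cc)) == "increasing"
        assert threshold_trend(threshold_curve_from_policy(pol_cv)) == "decreasing"

    def test_simulation_curve_matches_policy_curve_on_visited_states(self, shape):
        """The empirical estimator equals the policy-exact curve restricted
        to the states the simulation actually visited, up to one step of the
        posterior grid (slack only for tie states whose coin never fell y0)."""
        from devfeedbacks import C0, TIE_TOL

        cfg, _, policy, _ = solved(shape)
        result = big_population(shape)
        sim = threshold_curve_from_simulation(result)
        T = cfg.T
        n0_at = result.n0_path[:, :-1]
        xcum = np.cumsum(result.cues == C0, axis=1)
        restricted = np.full(T, np.nan)
        for t in range(1, T + 1):
            visited = np.zeros((t, t + 1), dtype=bool)
            visited[n0_at[:, t - 1], xcum[:, t - 1]] = True
            weakly_y0 = policy.deltas[t - 1] > -TIE_TOL
            p = policy.posterior[t]
            for n0 in range(t):
                xs = np.nonzero(visited[n0] & weakly_y0[n0])[0]
                if xs.size:
                    m = p[xs].min()
                    if np.isnan(restricted[n0]) or m < restricted[n0]:
                        restricted[n0] = m
        grid = np.unique(np.concatenate(policy.posterior))
        for n0 in np.nonzero(sim.defined())[0]:
            lo = restricted[n0]
            assert not np.isnan(lo)
            assert sim.tau[n0] >= lo - 1e-12
            above = grid[grid > lo + 1e-12]
            ceiling = above[0] if above.size else 1.0
            assert sim.tau[n0] <= ceiling + 1e-12

    def test_all_y1_population_leaves_curve_undefined(self):
        """An individual who never chose y0 contributes no threshold events."""
        cfg = ModelConfig(T=6, q=0.9, fitness=FitnessSpec.from_shape("linear"),
                          N=1, seed=0, true_env="E1")
        _, policy, _ = solve(cfg)
        result = simulate_population(cfg, policy)
        if np.all(result.actions == 1):  # all y1 under strong E1 cues
            sim = threshold_curve_from_simulation(result)
            assert not sim.defined().any()

    def test_perfect_cues_single_path(self):
        """q = 1 in E0 forces one path; tau is the visited posterior (1.0)."""
        cfg = ModelConfig(T=8, q=1.0, fitness=FitnessSpec.from_shape("linear"), N=5, seed=1)
        _, policy, _ = solve(cfg)
        result = simulate_population(cfg, policy)
        sim = threshold_curve_from_simulation(result)
        assert np.all(sim.tau[sim.defined()] == 1.0)

    def test_epoch_boundaries_monotone_within_epoch(self, shape):
        """Per-epoch decision boundaries carry the clean feedback sign."""
        _, _, policy, _ = solved(shape)
        expect = {"concave": 1, "convex": -1, "linear": 0}[shape]
        for t in range(2, 21):
            b = epoch_threshold_boundary(policy, t)
            b = b[~np.isnan(b)]
            d = np.diff(b)
            if expect == 1:
                assert np.all(d >= -1e-9)
            elif expect == -1:
                assert np.all(d <= 1e-9)
            else:
                assert np.all(np.abs(d) <= 1e-9)


class TestPhaseDiagram:
    def test_flow_conservation(self, shape):
        """Visits at (n0, n1) = y0-inflow + y1-inflow, with N at the origin."""
        result = big_population(shape)
        pd_ = phase_diagram(result)
        T = result.T
        count, p_y0 = pd_.count, pd_.p_y0
        assert count[0, 0] == result.N
        y0_out = np.where(count > 0, np.round(p_y0 * count), 0).astype(int)
        for n0 in range(T):
            for n1 in range(T - n0):
                if n0 == 0 and n1 == 0:
                    continue
                if n0 + n1 >= T:
                    continue
                inflow = 0
                if n0 > 0:
                    inflow += y0_out[n0 - 1, n1]
                if n1 > 0:
                    inflow += count[n0, n1 - 1] - y0_out[n0, n1 - 1]
                assert count[n0, n1] == inflow, (n0, n1)

    def test_defined_probabilities_in_unit_interval(self, shape):
        pd_ = phase_diagram(big_population(shape))
        vals = pd_.p_y0[pd_.count > 0]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.isnan(pd_.p_y0[pd_.count == 0]).all()

    def test_perfect_cues_spine(self):
        cfg = ModelConfig(T=10, q=1.0, fitness=FitnessSpec.from_shape("convex"), N=20, seed=4)
        _, policy, _ = solve(cfg)
        result = simulate_population(cfg, policy)
        pd_ = phase_diagram(result)
        visited = np.argwhere(pd_.count > 0)
        assert np.all(visited[:, 1] == 0)  # only the (n0, 0) spine
        assert np.all(pd_.p_y0[pd_.count > 0] == 1.0)

    def test_convex_early_divergence_is_maintained(self):
        """Once a few steps ahead, convex developers almost surely continue:
        visited cells with n0 >= n1 + 4 have mean P(y0) > 0.9."""
        pd_ = phase_diagram(big_population("convex"))
        n0g, n1g = np.nonzero(pd_.count)
        sel = n0g >= n1g + 4
        assert sel.any()
        assert np.nanmean(pd_.p_y0[n0g[sel], n1g[sel]]) > 0.9


class TestDistributionSummary:
    def test_histogram_mass_and_moments(self, shape):
        result = big_population(shape)
        summary = distribution_summary(result, (5, 10, 20))
        for t in (5, 10, 20):
            assert summary.histograms[t].sum() == result.N
        m = summary.moments
        assert set(m.columns) == {"mean", "sd", "skewness", "excess_kurtosis", "bimodality"}
        assert np.all(m["bimodality"].dropna() > 0)

    def test_degenerate_population_flagged(self):
        cfg = ModelConfig(T=6, q=1.0, fitness=FitnessSpec.from_shape("linear"), N=10, seed=0)
        _, policy, _ = solve(cfg)
        result = simulate_population(cfg, policy)
        summary = distribution_summary(result, (6,))
        assert summary.moments.loc[6, "sd"] == 0.0
        assert np.isnan(summary.moments.loc[6, "bimodality"])

    def test_timestep_out_of_range_rejected(self):
        result = big_population("linear")
        with pytest.raises(ValueError):
            distribution_summary(result, (25,))


class TestSarleBimodality:
    def test_uniform_benchmark(self):
        """A uniform sample sits at the 5/9 benchmark (closed-form moments)."""
        rng = np.random.default_rng(0)
        b = sarle_bimodality(rng.uniform(size=200_000))
        assert b == pytest.approx(5.0 / 9.0, abs=0.01)

    def test_two_point_limit(self):
        """Half the mass at each extreme: minimal kurtosis pushes b to 1."""
        vals = np.array([0.0] * 5000 + [20.0] * 5000)
        assert sarle_bimodality(vals) == pytest.approx(1.0, abs=1e-3)

    def test_small_or_degenerate_samples_are_nan(self):
        assert np.isnan(sarle_bimodality(np.array([1.0, 2.0, 3.0])))
        assert np.isnan(sarle_bimodality(np.full(100, 7.0)))

    def test_normal_sample_below_uniform_benchmark(self):
        rng = np.random.default_rng(1)
        assert sarle_bimodality(rng.normal(size=100_000)) < 5.0 / 9.0


@pytest.fixture(scope="module")
def sweep():
    base = ModelConfig(T=20, N=2000, seed=17)
    return reliability_sweep(base, q_grid=(0.5, 0.55, 0.75, 1.0))


class TestReliabilitySweep:
    def test_perfect_cues_collapse_variation(self, sweep):
        rows = sweep[sweep.q == 1.0]
        assert len(rows) == 3
        assert np.all(rows["sd"] == 0.0)

    def test_trend_signs_constant_across_reliabilities(self, sweep):
        """Feedback signs are a property of the landscape, not of q."""
        informative = sweep[(sweep.q > 0.5) & (sweep.q < 1.0)]
        by_shape = {s: set(g["tau_trend"]) for s, g in informative.groupby("shape")}
        assert by_shape["concave"] == {"increasing"}
        assert by_shape["convex"] == {"decreasing"}
        assert by_shape["linear"] == {"flat"}

    def test_individuality_contrast_starkest_at_maximum_uncertainty(self, sweep):
        """b(convex) - b(concave) peaks at q = 0.5, where the concave
        population is fully degenerate (treated as the unimodal limit b = 0)
        and the convex one splits between the two extremes."""
        contrast = {}
        for q, grp in sweep[sweep.q < 1.0].groupby("q"):
            bc = grp[grp["shape"] == "convex"]["b"].iloc[0]
            ba = grp[grp["shape"] == "concave"]["b"].iloc[0]
            contrast[q] = bc - (0.0 if np.isnan(ba) else ba)
        assert max(contrast, key=contrast.get) == 0.5

    def test_reproducible_from_master_seed(self):
        base = ModelConfig(T=10, N=200, seed=23)
        a = reliability_sweep(base, q_grid=(0.55, 0.8))
        b = reliability_sweep(base, q_grid=(0.55, 0.8))
        assert a.equals(b)
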