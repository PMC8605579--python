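"""Discrete-event evaluation, policy comparison, sensitivity, Pareto."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import overbook as ob

from conftest import two_resource_config


def run(limits, model, case_study, seed=0, weeks=20, season="winter", days=5):
    sim = ob.SimulationConfig(
        weeks=weeks, days_per_week=days, seed=seed, season=season
    )
    return ob.simulate_weeks(
        limits, model, sim, case_study.config, case_study.schedule
    )


class TestSimulateWeeks:
    def test_no_cancellation_no_cost_is_deterministic(self):
        config = two_resource_config(prices=(7.0, 11.0), K=(5, 5))
        schedule = ob.OverageCostSchedule()
        sim = ob.SimulationConfig(weeks=4, days_per_week=3, seed=0)
        ev = ob.simulate_weeks((2, 3), 0.0, sim, config, schedule)
        expected = 3 * (2 * 7.0 + 3 * 11.0)
        np.testing.assert_allclose(ev.weekly_net_rewards, expected)
        np.testing.assert_array_equal(ev.weekly_consumers_served, 3 * 5)

    def test_certain_cancellation_serves_nobody(self, case_study):
        ev = run((0, 24, 2, 2), 1.0, case_study)
        np.testing.assert_array_equal(ev.weekly_net_rewards, 0.0)
        np.testing.assert_array_equal(ev.weekly_consumers_served, 0)

    def test_mean_shows_match_exact_pmf(self, case_study):
        """Simulated per-set weekly shows agree with days * E[X_j] from the
        exact Poisson-binomial under the same cluster mix, to 3 MC SEs."""
        limits = (0, 30, 3, 3)
        ev = run(limits, case_study.cluster_model, case_study, weeks=60)
        sub = case_study.cluster_model.conditional({"season": "winter"})
        shares = sub["bookings"] / sub["bookings"].sum()
        mean_rate = float(shares @ sub["rate"])
        for j, nj in enumerate(limits):
            exact_mean = 5 * nj * (1 - mean_rate)
            sims = ev.weekly_shows_per_set[:, j]
            se = sims.std(ddof=1) / np.sqrt(len(sims))
            assert abs(sims.mean() - exact_mean) <= 3 * se + 1e-9

    def test_bit_reproducible_given_seed(self, case_study):
        a = run((0, 30, 3, 3), case_study.cluster_model, case_study, seed=9)
        b = run((0, 30, 3, 3), case_study.cluster_model, case_study, seed=9)
        np.testing.assert_array_equal(a.weekly_net_rewards, b.weekly_net_rewards)
        np.testing.assert_array_equal(
            a.weekly_overage_levels, b.weekly_overage_levels
        )

    def test_weekly_reward_is_revenue_minus_cost(self, case_study):
        ev = run((0, 36, 3, 3), case_study.cluster_model, case_study)
        np.testing.assert_allclose(
            ev.weekly_net_rewards, ev.weekly_revenue - ev.weekly_overage_costs
        )
        cap = 5 * sum(ev.limits)
        assert (ev.weekly_consumers_served <= cap).all()

    def test_infeasible_limits_rejected_when_space_given(self, case_study):
        sim = ob.SimulationConfig(weeks=2, seed=0, season="winter")
        with pytest.raises(ValueError, match="feasible"):
            ob.simulate_weeks(
                (40, 40, 9, 9),
                case_study.cluster_model,
                sim,
                case_study.config,
                case_study.schedule,
                space=case_study.search_space("OU"),
            )

    def test_stochastic_demand_caps_at_limits(self, case_study):
        sim = ob.SimulationConfig(
            weeks=10, seed=1, season="winter",
            demand_mode="stochastic", arrival_rates=(1.0, 50.0, 1.0, 1.0),
        )
        ev = ob.simulate_weeks(
            (2, 10, 2, 2), case_study.cluster_model, sim,
            case_study.config, case_study.schedule,
        )
        assert (ev.weekly_shows_per_set[:, 1] <= 5 * 10).all()


class TestOveragePercentage:
    def test_weekly_ratio(self, case_study):
        ev = run((0, 36, 3, 3), case_study.cluster_model, case_study)
        pct = ob.overage_percentage(ev)
        manual = ev.weekly_overage_levels.sum(axis=1) / ev.weekly_consumers_served
        np.testing.assert_allclose(pct, manual)

    def test_zero_overage_gives_zero(self, case_study):
        ev = run((0, 20, 2, 2), 0.0, case_study)
        np.testing.assert_array_equal(ob.overage_percentage(ev), 0.0)

    def test_zero_served_week_reports_zero(self, case_study):
        ev = run((0, 24, 2, 2), 1.0, case_study, weeks=2)
        np.testing.assert_array_equal(ob.overage_percentage(ev), 0.0)


def evaluation_from(rewards, label):
    n = len(rewards)
    return ob.PolicyEvaluation(
        policy_label=label,
        limits=(),
        weekly_net_rewards=np.asarray(rewards, dtype=float),
        weekly_revenue=np.asarray(rewards, dtype=float),
        weekly_overage_costs=np.zeros(n),
        weekly_consumers_served=np.ones(n, dtype=int),
        weekly_overage_levels=np.zeros((n, 1), dtype=int),
        weekly_shows_per_set=np.zeros((n, 1), dtype=int),
    )


class TestComparePolicies:
    def test_identical_groups_not_distinguishable(self):
        vals = np.array([5.0, 6.0, 7.0, 8.0])
        table = ob.compare_policies(
            [evaluation_from(vals, "a"), evaluation_from(vals, "b")]
        )
        assert table["p_value"].iloc[0] > 0.99

    def test_huge_separation_is_significant(self):
        rng = np.random.default_rng(0)
        a = evaluation_from(rng.normal(0, 1, 40), "a")
        b = evaluation_from(rng.normal(100, 1, 40), "b")
        table = ob.compare_policies([a, b])
        assert table["p_value"].iloc[0] < 0.001

    def test_matches_independent_tukey_implementation(self):
        """Cross-check against statsmodels' studentized-range procedure on a
        fixed three-group dataset."""
        rng = np.random.default_rng(7)
        groups = [rng.normal(mu, 1.0, 15) for mu in (0.0, 0.6, 1.5)]
        ours = ob.compare_policies(
            [evaluation_from(g, f"g{i}") for i, g in enumerate(groups)]
        )
        data = np.concatenate(groups)
        labels = np.repeat([f"g{i}" for i in range(3)], 15)
        sm_res = pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            ours["p_value"].to_numpy(), sm_res.pvalues, atol=1e-4
        )

    def test_needs_two_groups_of_equal_length(self):
        with pytest.raises(ValueError):
            ob.compare_policies([evaluation_from([1.0, 2.0], "a")])
        with pytest.raises(ValueError):
            ob.compare_policies(
                [evaluation_from([1.0, 2.0], "a"), evaluation_from([1.0], "b")]
            )


@pytest.fixture(scope="module")
def policies(case_study):
    return {
        "NO": (case_study.search_space("NO"), case_study.policy("NO")),
        "OU": (case_study.search_space("OU"), case_study.policy("OU")),
    }


@pytest.fixture(scope="module")
def reoptimized(policies, case_study):
    return ob.sensitivity_analysis(
        [1, 2, 4], "reoptimize", policies, case_study.config,
        case_study.schedule,
    )


class TestSensitivityAnalysis:
    def test_no_policy_unaffected_by_multipliers(self, reoptimized):
        no = reoptimized[reoptimized["policy"] == "NO"]
        assert no["limits"].nunique() == 1
        assert no["expected_net_reward"].nunique() == 1

    def test_multiplier_one_reproduces_baseline(self, reoptimized, policies, case_study):
        space, policy = policies["OU"]
        baseline = ob.complete_search(
            space, policy, case_study.config, case_study.schedule
        )
        row = reoptimized[
            (reoptimized["policy"] == "OU") & (reoptimized["multiplier"] == 1)
        ].iloc[0]
        assert tuple(row["limits"]) == baseline.optimal_limits
        assert row["expected_net_reward"] == pytest.approx(
            baseline.expected_net_reward
        )

    def test_rewards_and_total_limits_nonincreasing_in_cost(self, reoptimized):
        ou = reoptimized[reoptimized["policy"] == "OU"].sort_values("multiplier")
        assert (ou["expected_net_reward"].diff().dropna() <= 1e-9).all()
        totals = ou["limits"].map(sum)
        assert (totals.diff().dropna() <= 0).all()

    def test_underestimate_mode_keeps_baseline_limits(self, policies, case_study):
        table = ob.sensitivity_analysis(
            [1, 3], "underestimate", policies, case_study.config,
            case_study.schedule,
        )
        ou = table[table["policy"] == "OU"]
        assert ou["limits"].nunique() == 1
        rewards = ou.sort_values("multiplier")["expected_net_reward"]
        assert rewards.iloc[1] <= rewards.iloc[0]

    def test_invalid_inputs_rejected(self, policies, case_study):
        with pytest.raises(ValueError):
            ob.sensitivity_analysis(
                [], "reoptimize", policies, case_study.config, case_study.schedule
            )
        with pytest.raises(ValueError):
            ob.sensitivity_analysis(
                [0.5], "reoptimize", policies, case_study.config,
                case_study.schedule,
            )


class TestParetoFrontier:
    def frame(self, points):
        return pd.DataFrame(
            [
                {"limits": (i,), "expected_net_reward": r, "overage_pct": p}
                for i, (r, p) in enumerate(points)
            ]
        )

    def test_dominated_point_removed(self):
        frontier, _ = ob.pareto_frontier(self.frame([(10, 0.05), (8, 0.06)]))
        assert len(frontier) == 1
        assert frontier["expected_net_reward"].iloc[0] == 10

    def test_mutually_nondominated_points_all_retained(self):
        frontier, _ = ob.pareto_frontier(
            self.frame([(10, 0.08), (9, 0.05), (8, 0.02)])
        )
        assert len(frontier) == 3

    def test_matches_quadratic_oracle_on_random_cloud(self):
        rng = np.random.default_rng(4)
        pts = list(zip(rng.normal(size=60), rng.random(60)))
        frontier, _ = ob.pareto_frontier(self.frame(pts))
        kept = set(frontier["limits"])
        for i, (ri, pi_) in enumerate(pts):
            dominated = any(
                rj > ri and pj < pi_ for j, (rj, pj) in enumerate(pts) if j != i
            )
            assert ((i,) in kept) == (not dominated)

    def test_constrained_best_within_bound(self):
        frontier, best = ob.pareto_frontier(
            self.frame([(10, 0.12), (9, 0.06), (7, 0.01)]), max_overage_pct=0.07
        )
        assert best["expected_net_reward"] == 9

    def test_reward_maximizer_always_on_frontier(self, case_study):
        res = ob.complete_search(
            case_study.search_space("NO"),
            case_study.policy("NO"),
            case_study.config.with_no_overbooking(),
            case_study.schedule,
        )
        frontier, _ = ob.pareto_frontier(res.evaluations)
        assert res.optimal_limits in set(frontier["limits"])
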