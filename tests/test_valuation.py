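"""State valuation: discounting primitives, value iteration, MVT limit."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

from foragefit.task import (
    FORAGING_EXPERIMENTS,
    ForagingEnvironment,
    SemiMarkovChain,
    SemiMarkovState,
    StateDurations,
    enumerate_chains,
    itc_environment,
)
from foragefit.valuation import (
    BASE_BETA,
    ValuationSpec,
    apply_subjective_cost,
    constant_sensitivity_values,
    discounted_state_reward,
    distort_time,
    muagent_bank,
    mvt_prediction,
    one_trial_itc_values,
    optimal_harvests,
    reward_utility,
    state_discount,
    value_iteration,
)


def rate_oracle(env: ForagingEnvironment, durations: StateDurations, n_max: int = 30):
    """Brute-force long-run reward-rate maximization over leave-after-m
    policies (m harvests per patch type, m >= 0), the undiscounted MVT
    reference for value iteration at beta = .001."""
    types = env.start_volumes_ul
    handling = durations.handling_s if durations.handling_s is not None else env.pre_reward_delay_s
    best_rate, best = -1.0, None
    for ms in itertools.product(range(n_max + 1), repeat=len(types)):
        reward = time = 0.0
        for v0, m in zip(types, ms):
            for i in range(m):
                vol = max(0.0, v0 - i * env.depletion_ul_per_harvest)
                if env.iti_rule == "fill_to_harvest_time":
                    time += env.harvest_time_s
                else:
                    time += (
                        durations.decision_s
                        + handling
                        + durations.consumption_time(vol)
                        + env.fixed_post_delay_s
                    )
                reward += vol
            time += env.travel_time_s
        rate = reward / time
        if rate > best_rate:
            best_rate, best = rate, ms
    return dict(zip(types, best)), best_rate


class TestPrimitives:
    def test_discounted_reward_limit_and_zero(self):
        assert discounted_state_reward(2.0, 5.0, 1e-9) == pytest.approx(10.0)
        assert discounted_state_reward(0.0, 7.0, 0.3) == 0.0

    def test_discounted_reward_matches_quadrature(self):
        # r * integral_0^T exp(-beta t) dt
        for r, t, b in [(1.0, 10.0, 0.1), (3.5, 4.0, 0.7)]:
            expected = r * quad(lambda u: math.exp(-b * u), 0, t)[0]
            assert discounted_state_reward(r, t, b) == pytest.approx(expected, rel=1e-10)

    def test_discounted_reward_requires_positive_beta(self):
        with pytest.raises(ValueError):
            discounted_state_reward(1.0, 1.0, 0.0)

    def test_state_discount(self):
        assert state_discount(0.0, 0.5) == 1.0
        assert state_discount(10.0, 0.1) == pytest.approx(math.exp(-1))
        assert state_discount(1e6, 1.0) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "r,eta,form,expected",
        [(100.0, 1.0, "power", 100.0), (100.0, 0.5, "power", 10.0), (100.0, 0.5, "crra", 18.0)],
    )
    def test_reward_utility(self, r, eta, form, expected):
        assert reward_utility(r, eta, form) == pytest.approx(expected)

    def test_utility_errors(self):
        with pytest.raises(ValueError):
            reward_utility(0.0, 1.5, "crra")
        with pytest.raises(ValueError):
            reward_utility(10.0, 1.0, "crra")

    @pytest.mark.parametrize(
        "t,alpha,variant,expected",
        [(12.0, 0.5, "post_linear", 6.0), (16.0, 0.5, "post_power", 4.0), (4.0, 1.5, "pre_linear", 6.0), (9.0, 1.0, "post_linear", 9.0)],
    )
    def test_distort_time(self, t, alpha, variant, expected):
        assert distort_time(t, alpha, variant) == pytest.approx(expected)

    def test_distort_time_range_errors(self):
        with pytest.raises(ValueError):
            distort_time(5.0, 1.4, "post_linear")
        with pytest.raises(ValueError):
            distort_time(5.0, 0.7, "pre_linear")

    def test_apply_subjective_cost(self):
        assert apply_subjective_cost(5.0, 0.0) == 5.0
        assert apply_subjective_cost(5.0, 1.0) == 4.0
        with pytest.raises(ValueError):
            apply_subjective_cost(5.0, -1.0)


class TestMuAgents:
    def test_exact_half_at_unit_kt(self):
        for k in (0.2, 1.0, 3.0):
            bank = muagent_bank(k)
            assert bank.discount(1.0 / k) == pytest.approx(0.5, abs=1e-12)

    def test_zero_delay(self):
        assert muagent_bank(2.0).discount(0.0) == pytest.approx(1.0)

    def test_tracks_hyperbolic(self):
        # closed form of the full mixture: E[exp(-beta t)] over Exp(1/k) = 1/(1+kt);
        # the 10-point quantile bank stays within 2 percentage points of
        # discount everywhere, and within 2% relative error up to kt = 5
        # (the tail deviation grows to ~4.5% relative by kt = 10)
        k = 1.0
        bank = muagent_bank(k)
        kt = np.linspace(0.0, 10.0, 101)
        hyp = 1 / (1 + kt)
        assert np.abs(bank.discount(kt / k) - hyp).max() < 0.02
        near = kt <= 5.0
        rel = np.abs(bank.discount(kt[near] / k) - hyp[near]) / hyp[near]
        assert rel.max() < 0.02

    def test_rates_are_exponential_quantiles(self):
        bank = muagent_bank(0.5)
        q = (np.arange(10) + 0.5) / 10
        np.testing.assert_allclose(bank.betas_i, -0.5 * np.log1p(-q))
        assert np.all(np.diff(bank.betas_i) > 0)


def _self_loop_chain(reward_per_cycle: float, gamma: float) -> SemiMarkovChain:
    """One decision whose stay action loops back on itself; per-cycle
    discounted reward and discount chosen analytically."""
    beta = 1.0
    t_cycle = -math.log(gamma) / beta
    rate = reward_per_cycle * beta / (1 - gamma) / 1.0  # so R(stay) = reward_per_cycle
    states = {
        "dec_1": SemiMarkovState(
            "dec_1", "decision", 0.0, successors={"stay": "reward_1", "leave": "travel"},
            is_decision=True,
        ),
        "reward_1": SemiMarkovState(
            "reward_1", "reward", t_cycle, reward_rate_ul_per_s=rate * 1.0 / t_cycle * t_cycle / t_cycle,
            successors={"advance": "dec_1"},
        ),
        "travel": SemiMarkovState("travel", "travel", 1e3, successors={"advance": "__next_patch__"}),
    }
    # fix the reward rate so the discounted in-state reward equals reward_per_cycle
    r_needed = reward_per_cycle * beta / (1 - math.exp(-beta * t_cycle))
    states["reward_1"] = SemiMarkovState(
        "reward_1", "reward", t_cycle, reward_rate_ul_per_s=r_needed,
        successors={"advance": "dec_1"},
    )
    return SemiMarkovChain(
        chain_id="loop", kind="foraging", states=states,
        first_decision="dec_1", decision_ids=["dec_1"], meta={"patch_type": 0},
    )


class TestValueIteration:
    def test_geometric_self_loop(self):
        # V = R / (1 - gamma) = 1 / 0.5 = 2 with a worthless leave option
        chain = _self_loop_chain(1.0, 0.5)
        table = value_iteration([chain], ValuationSpec("disc_exp", beta=1.0))
        assert table.v["loop"][0] == pytest.approx(2.0, rel=1e-9)

    def test_toy_patch_mvt(self):
        # per-harvest rewards 10, 7, 4, 1 uL over 10 s, travel 10 s:
        # leave-after-m rates 0.5, 0.567, 0.525, 0.44 -> 2 harvests
        env = ForagingEnvironment((10,), 3, 0, 10, 10)
        fast = StateDurations(decision_s=1.0, consumption_ul_per_s=1e9)
        chains = enumerate_chains(env, fast)
        assert mvt_prediction(chains) == {10: 2}
        oracle, _ = rate_oracle(env, fast, n_max=8)
        assert oracle == {10: 2}

    def test_longer_travel_weakly_more_harvests(self, durations):
        short = mvt_prediction(
            enumerate_chains(FORAGING_EXPERIMENTS["travel_time"]["10s"], durations)
        )
        long = mvt_prediction(
            enumerate_chains(FORAGING_EXPERIMENTS["travel_time"]["30s"], durations)
        )
        for ptype in short:
            assert long[ptype] >= short[ptype]

    def test_larger_patches_weakly_more_harvests(self, travel_chains):
        pred = mvt_prediction(travel_chains)
        assert pred[60] <= pred[90] <= pred[120]

    def test_subjective_cost_increases_predicted_harvests(self, travel_chains):
        base = value_iteration(travel_chains, ValuationSpec("cost", cost_c=0.0))
        costly = value_iteration(travel_chains, ValuationSpec("cost", cost_c=500.0))
        h0 = optimal_harvests(base, travel_chains)
        h1 = optimal_harvests(costly, travel_chains)
        assert all(h1[p] >= h0[p] for p in h0)
        assert any(h1[p] > h0[p] for p in h0)

    @pytest.mark.parametrize(
        "spec",
        [
            ValuationSpec("mvt"),
            ValuationSpec("cost", cost_c=200.0),
            ValuationSpec("util_crra", eta=0.6),
            ValuationSpec("pre_del", alpha=1.6),
            ValuationSpec("post_del_pwr", alpha=0.6),
            ValuationSpec("disc_hyp", k_hyp=0.4),
            ValuationSpec("disc_cs", beta=0.2, alpha=0.7),
            ValuationSpec("disc_quasi", beta=0.5, delta=0.005, omega=0.3),
        ],
        ids=lambda s: s.variant,
    )
    def test_anchored_matches_sweep(self, spec, durations):
        chains = enumerate_chains(FORAGING_EXPERIMENTS["depletion_rate"]["8uL"], durations)
        fast = value_iteration(chains, spec)
        slow = value_iteration(chains, spec, method="sweep", tol=1e-10)
        assert fast.q_leave == pytest.approx(slow.q_leave, rel=1e-6)
        np.testing.assert_allclose(
            fast.q_stay["patch_90"], slow.q_stay["patch_90"], rtol=1e-6
        )

    def test_itc_anchored_matches_sweep(self, itc_chains):
        spec = ValuationSpec("disc_quasi", beta=0.5, delta=0.005, omega=0.3)
        fast = value_iteration(itc_chains, spec)
        slow = value_iteration(itc_chains, spec, method="sweep", tol=1e-9)
        cid = itc_chains[-1].chain_id
        assert fast.gate_value == pytest.approx(slow.gate_value, rel=1e-6)
        np.testing.assert_allclose(
            fast.q_ll[cid][10:], slow.q_ll[cid][10:], rtol=1e-6
        )

    def test_sweep_residuals_shrink(self, durations):
        chains = enumerate_chains(FORAGING_EXPERIMENTS["depletion_rate"]["16uL"], durations)
        table = value_iteration(
            chains, ValuationSpec("disc_exp", beta=0.1), method="sweep", tol=1e-8
        )
        res = table.residuals
        burn = 20
        assert np.all(np.diff(res[burn:]) <= 1e-12)

    def test_chain_order_invariance(self, travel_chains):
        spec = ValuationSpec("disc_exp", beta=0.05)
        a = value_iteration(travel_chains, spec)
        b = value_iteration(travel_chains[::-1], spec)
        assert a.q_leave == pytest.approx(b.q_leave, rel=1e-9)

    def test_table_invariant_v_is_max(self, travel_chains):
        table = value_iteration(travel_chains, ValuationSpec("disc_exp", beta=0.1))
        table.validate()

    def test_quasi_is_convex_combination(self, travel_chains):
        spec = ValuationSpec("disc_quasi", beta=0.5, delta=0.01, omega=0.4)
        table = value_iteration(travel_chains, spec)
        lo_t, hi_t = table.components
        for cid in table.q_stay:
            lo = np.minimum(lo_t.q_stay[cid], hi_t.q_stay[cid])
            hi = np.maximum(lo_t.q_stay[cid], hi_t.q_stay[cid])
            assert np.all(table.q_stay[cid] >= lo - 1e-9)
            assert np.all(table.q_stay[cid] <= hi + 1e-9)

    def test_quasi_boundary_weight_equals_exponential(self, travel_chains):
        quasi = value_iteration(
            travel_chains, ValuationSpec("disc_quasi", beta=0.3, delta=0.01, omega=1.0)
        )
        expo = value_iteration(travel_chains, ValuationSpec("disc_exp", beta=0.3))
        assert quasi.q_leave == pytest.approx(expo.q_leave, rel=1e-9)
        np.testing.assert_allclose(
            quasi.q_stay["patch_90"], expo.q_stay["patch_90"], rtol=1e-9
        )

    def test_constant_sensitivity_alpha_one_equals_exponential(self, travel_chains):
        cs = constant_sensitivity_values(travel_chains, beta=0.2, alpha=1.0)
        ex = value_iteration(travel_chains, ValuationSpec("disc_exp", beta=0.2))
        assert cs.q_leave == pytest.approx(ex.q_leave, rel=1e-9)


class TestOneTrialValues:
    def test_closed_forms(self):
        hyp = ValuationSpec("disc_hyp", k_hyp=1.0, horizon="one_trial")
        assert one_trial_itc_values(40, 1, hyp) == pytest.approx(20.0)
        quasi = ValuationSpec(
            "disc_quasi", beta=1.0, delta=0.01, omega=0.5, horizon="one_trial"
        )
        assert one_trial_itc_values(40, 1, quasi) == pytest.approx(27.1586, abs=1e-3)
        cs = ValuationSpec("disc_cs", beta=0.2, alpha=0.5, horizon="one_trial")
        assert one_trial_itc_values(1, 8, cs) == pytest.approx(
            math.exp(-0.2 * math.sqrt(8)), rel=1e-9
        )

    def test_tiny_rate_approaches_reward(self):
        spec = ValuationSpec("disc_exp", beta=1e-9, horizon="one_trial")
        assert one_trial_itc_values(40, 6, spec) == pytest.approx(40.0)

    def test_requires_one_trial_horizon(self):
        with pytest.raises(ValueError):
            one_trial_itc_values(40, 1, ValuationSpec("disc_exp", beta=0.1))


class TestSpecValidation:
    def test_quasi_requires_beta_above_delta(self):
        with pytest.raises(ValueError):
            ValuationSpec("disc_quasi", beta=0.01, delta=0.5, omega=0.5)

    def test_unused_parameters_rejected(self):
        with pytest.raises(ValueError):
            ValuationSpec("disc_exp", beta=0.1, eta=0.5)

    def test_required_parameters_enforced(self):
        with pytest.raises(ValueError):
            ValuationSpec("disc_cs", beta=0.1)
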