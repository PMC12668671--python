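"""Decision-problem structure: actions, transitions, hazard composition."""

import numpy as np
import pytest

from riskexplore import Action, EnvConstants, HazardBelief, Loc, PhysicalState
from riskexplore.environment import available_actions, state_reward, transition_distribution
from riskexplore.hazard import BetaParam
from riskexplore.pool import PoolState

from conftest import make_belief


class TestAvailableActions:
    def test_nest_offers_three_choices(self):
        acts = available_actions(PhysicalState(Loc.NEST, 0))
        assert acts == (Action.STAY_NEST, Action.APPROACH_CAUTIOUS, Action.APPROACH_CONFIDENT)

    def test_first_object_turn_forces_stay(self):
        # bouts last at least 2 turns: retreat only opens up from tau = 2
        assert available_actions(PhysicalState(Loc.CAUTIOUS_OBJECT, 1)) == (Action.STAY_OBJECT,)

    @pytest.mark.parametrize("tau", [2, 3])
    def test_mid_bout_choice(self, tau):
        acts = available_actions(PhysicalState(Loc.CONFIDENT_OBJECT, tau))
        assert acts == (Action.STAY_OBJECT, Action.RETREAT)

    def test_fourth_turn_forces_retreat(self):
        assert available_actions(PhysicalState(Loc.CAUTIOUS_OBJECT, 4)) == (Action.RETREAT,)

    def test_dead_is_absorbing(self):
        assert available_actions(PhysicalState(Loc.DEAD, 0)) == ()

    def test_detect_states_are_chance_nodes(self):
        with pytest.raises(ValueError, match="chance"):
            available_actions(PhysicalState(Loc.CAUTIOUS_DETECT, 2))


class TestTransitions:
    def test_probabilities_sum_to_one_everywhere(self, uniform_belief, fresh_pool, env):
        cases = [
            (PhysicalState(Loc.NEST, 0), Action.STAY_NEST),
            (PhysicalState(Loc.NEST, 0), Action.APPROACH_CAUTIOUS),
            (PhysicalState(Loc.NEST, 0), Action.APPROACH_CONFIDENT),
            (PhysicalState(Loc.CAUTIOUS_OBJECT, 1), Action.STAY_OBJECT),
            (PhysicalState(Loc.CAUTIOUS_OBJECT, 2), Action.RETREAT),
            (PhysicalState(Loc.CONFIDENT_OBJECT, 3), Action.STAY_OBJECT),
            (PhysicalState(Loc.RETREAT, 0), None),
            (PhysicalState(Loc.CAUTIOUS_DETECT, 2), None),
            (PhysicalState(Loc.CONFIDENT_DETECT, 3), None),
        ]
        for s, a in cases:
            outs = transition_distribution(s, a, uniform_belief, fresh_pool, env)
            assert sum(o.prob for o in outs) == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_hazard_stay_is_effectively_deterministic(self, fresh_pool, env):
        # pseudocounts must stay positive, so h = 0 is a limit: the safe
        # branch carries all but a vanishing sliver of mass
        belief = HazardBelief((BetaParam(1e-12, 1), BetaParam(1e-12, 1), BetaParam(1e-12, 1)))
        outs = transition_distribution(
            PhysicalState(Loc.CAUTIOUS_OBJECT, 1), Action.STAY_OBJECT, belief, fresh_pool, env
        )
        safe = next(o for o in outs if o.state == PhysicalState(Loc.CAUTIOUS_OBJECT, 2))
        assert safe.prob == pytest.approx(1.0, abs=1e-11)

    def test_first_stay_detect_probability_equals_mu2(self, fresh_pool, env):
        belief = make_belief((0.5, 0.3, 0.3))
        outs = transition_distribution(
            PhysicalState(Loc.CONFIDENT_OBJECT, 1), Action.STAY_OBJECT, belief, fresh_pool, env
        )
        detect = next(o for o in outs if o.state.loc is Loc.CONFIDENT_DETECT)
        assert detect.prob == pytest.approx(0.5)

    def test_conditional_increments_compose_to_cumulative_hazard(self, fresh_pool, env):
        # chaining the per-turn conditional detect probabilities along the
        # safe branch reproduces 1 - survival = h(tau)
        belief = make_belief((0.3, 0.25, 0.2))
        h4 = belief.hazard(4)
        s = PhysicalState(Loc.CAUTIOUS_OBJECT, 1)
        bel, pool = belief, fresh_pool
        survive = 1.0
        for _ in range(3):
            outs = transition_distribution(s, Action.STAY_OBJECT, bel, pool, env)
            safe = next(o for o in outs if o.state.loc is s.loc)
            detect_p = 1.0 - safe.prob
            survive *= 1.0 - detect_p
            s, bel, pool = safe.state, safe.belief, safe.pool
        assert 1.0 - survive == pytest.approx(h4, abs=1e-12)

    def test_detect_resolution_probabilities(self, uniform_belief, fresh_pool, env):
        outs = transition_distribution(
            PhysicalState(Loc.CONFIDENT_DETECT, 2), None, uniform_belief, fresh_pool, env
        )
        dead = next(o for o in outs if o.state.loc is Loc.DEAD)
        nest = next(o for o in outs if o.state.loc is Loc.NEST)
        assert dead.prob == pytest.approx(env.p1)
        assert dead.reward == env.dying_cost
        assert nest.prob == pytest.approx(1 - env.p1)

    def test_travel_cost_on_approach_and_retreat_edges(self, uniform_belief, fresh_pool, env):
        outs = transition_distribution(
            PhysicalState(Loc.NEST, 0), Action.APPROACH_CAUTIOUS, uniform_belief, fresh_pool, env
        )
        assert outs[0].reward == env.travel_cost
        outs = transition_distribution(
            PhysicalState(Loc.CAUTIOUS_OBJECT, 2), Action.RETREAT, uniform_belief, fresh_pool, env
        )
        assert outs[0].reward == env.travel_cost

    def test_safe_branch_updates_branch_belief_only(self, uniform_belief, fresh_pool, env):
        outs = transition_distribution(
            PhysicalState(Loc.CAUTIOUS_OBJECT, 1), Action.STAY_OBJECT, uniform_belief, fresh_pool, env
        )
        safe = next(o for o in outs if o.state.loc is Loc.CAUTIOUS_OBJECT)
        assert safe.belief.param(2).b == 2
        assert uniform_belief.param(2).b == 1  # input untouched

    def test_invalid_action_rejected(self, uniform_belief, fresh_pool, env):
        with pytest.raises(ValueError):
            transition_distribution(
                PhysicalState(Loc.NEST, 0), Action.RETREAT, uniform_belief, fresh_pool, env
            )
        with pytest.raises(ValueError):
            transition_distribution(
                PhysicalState(Loc.CAUTIOUS_DETECT, 2), Action.STAY_OBJECT,
                uniform_belief, fresh_pool, env,
            )


class TestRewardsAndConstants:
    def test_object_reward_is_the_exploration_bonus(self, fresh_pool):
        cau, con = fresh_pool.omegas
        r = state_reward(PhysicalState(Loc.CONFIDENT_OBJECT, 2), fresh_pool)
        assert r == pytest.approx(con * fresh_pool.g + 0.5)
        assert state_reward(PhysicalState(Loc.NEST, 0), fresh_pool) == 0.0

    def test_constant_invariants_enforced(self):
        with pytest.raises(ValueError):
            EnvConstants(p1=0.3, p2=0.6)
        with pytest.raises(ValueError):
            EnvConstants(dying_cost=-0.01, travel_cost=-0.5)
        with pytest.raises(ValueError):
            EnvConstants(gamma=1.5)
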