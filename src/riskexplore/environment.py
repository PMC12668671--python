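"""The discrete decision problem: states, actions, rewards and transitions.

Four real states -- nest, cautious object, confident object, retreat -- and
three imagined ones -- cautious detect, confident detect, dead.  The agent
leaves the nest with a cautious or confident approach (the type is fixed for
the whole bout), stays at the object for 2-4 turns, and retreats to the
nest.  Detection and death never happen in reality; they exist only inside
planning, where staying one more turn at the object risks detection with
the survival-conditional hazard increment, and a detected agent fails to
escape with probability p1 (confident) or p2 < p1 (cautious).

Epistemic uncertainty enters only through the posterior-predictive hazard:
the per-turn conditional detection probability for the stay from tau to
tau+1 is

    dh = [h(tau+1) - h(tau)] / [1 - h(tau)] = E[theta_{tau+1}],

the posterior mean of the next noisy-or cause.  Returning to the nest
resets tau (the hazard restarts each bout); what persists is the belief.

Rewards: the object states pay the imagined exploration bonus as a
state-dependent reward; travel costs sit on the approach and retreat edges,
and the dying cost on the transition into the absorbing dead state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import NamedTuple

from .hazard import MAX_TAU, HazardBelief
from .pool import CAUTIOUS, CONFIDENT, K_DEFAULT, R_DEFAULT, PoolState, imagined_reward

__all__ = [
    "Loc",
    "Action",
    "PhysicalState",
    "EnvConstants",
    "Outcome",
    "available_actions",
    "state_reward",
    "transition_distribution",
]


class Loc(IntEnum):
    NEST = 0
    CAUTIOUS_OBJECT = 1
    CONFIDENT_OBJECT = 2
    RETREAT = 3
    CAUTIOUS_DETECT = 4
    CONFIDENT_DETECT = 5
    DEAD = 6


OBJECT_LOCS = (Loc.CAUTIOUS_OBJECT, Loc.CONFIDENT_OBJECT)
DETECT_LOCS = (Loc.CAUTIOUS_DETECT, Loc.CONFIDENT_DETECT)

#: Object/detect location -> approach type.
APPROACH_OF = {
    Loc.CAUTIOUS_OBJECT: CAUTIOUS,
    Loc.CONFIDENT_OBJECT: CONFIDENT,
    Loc.CAUTIOUS_DETECT: CAUTIOUS,
    Loc.CONFIDENT_DETECT: CONFIDENT,
}


class Action(IntEnum):
    """Agent actions; the enum order is the planner's tie-break order."""

    STAY_NEST = 0
    APPROACH_CAUTIOUS = 1
    APPROACH_CONFIDENT = 2
    STAY_OBJECT = 3
    RETREAT = 4


class PhysicalState(NamedTuple):
    """Location plus turns-at-object tau this bout (0 away from the object)."""

    loc: Loc
    tau: int


@dataclass(frozen=True)
class EnvConstants:
    """Fixed environment constants.

    travel_cost, dying_cost, p1, p2 and gamma are free constants of the
    decision problem (not estimates of anything); the defaults were chosen
    so that cautious approach strictly dominates confident approach under a
    high hazard belief while all three phenotypes remain reachable within
    the fitted parameter ranges.  All are config-overridable.
    """

    travel_cost: float = -0.8
    dying_cost: float = -10.0
    p1: float = 0.6  # failed escape from confident detect
    p2: float = 0.3  # failed escape from cautious detect
    gamma: float = 0.98
    r_const: float = R_DEFAULT
    k_const: float = K_DEFAULT

    def __post_init__(self) -> None:
        if not self.p2 < self.p1:
            raise ValueError(f"p2 < p1 required, got p1={self.p1}, p2={self.p2}")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not self.dying_cost < self.travel_cost <= 0.0:
            raise ValueError("dying_cost < travel_cost <= 0 required")


def available_actions(s: PhysicalState) -> tuple[Action, ...]:
    """Actions at a real state.

    The first object turn (tau = 1, the approach itself) forces a stay so
    that every bout lasts at least 2 turns; tau = 4 forces retreat.  The
    retreat state and the dead state offer no choices; imagined detect
    states are chance nodes and raise.
    """
    if s.loc is Loc.NEST:
        return (Action.STAY_NEST, Action.APPROACH_CAUTIOUS, Action.APPROACH_CONFIDENT)
    if s.loc in OBJECT_LOCS:
        if s.tau >= MAX_TAU:
            return (Action.RETREAT,)
        if s.tau == 1:
            return (Action.STAY_OBJECT,)
        return (Action.STAY_OBJECT, Action.RETREAT)
    if s.loc in (Loc.RETREAT, Loc.DEAD):
        return ()
    raise ValueError(f"imagined state {s.loc.name} is a chance node, not a decision state")


def state_reward(s: PhysicalState, pool: PoolState) -> float:
    """Deterministic state-dependent reward: the exploration bonus at the object."""
    if s.loc in OBJECT_LOCS:
        return imagined_reward(pool, APPROACH_OF[s.loc])
    return 0.0


class Outcome(NamedTuple):
    """One branch of a transition: probability, edge reward, successor payload."""

    prob: float
    reward: float
    state: PhysicalState
    belief: HazardBelief
    pool: PoolState


def _pool_location(loc: Loc) -> str:
    if loc is Loc.CAUTIOUS_OBJECT:
        return "cautious_object"
    if loc is Loc.CONFIDENT_OBJECT:
        return "confident_object"
    return "elsewhere"


def transition_distribution(
    s: PhysicalState,
    a: Action | None,
    belief: HazardBelief,
    pool: PoolState,
    env: EnvConstants,
) -> list[Outcome]:
    """Distribution over (successor, edge reward, updated belief and pool).

    For real decision states ``a`` must be one of :func:`available_actions`;
    for chance states (retreat, detect, dead) ``a`` must be None.  The pool
    steps according to the location the agent occupied this turn, and the
    belief updates along safe-continuation branches (Bayes-adaptive: each
    branch carries its own posterior).
    """
    from .pool import step_pool  # local import avoids a cycle in type-only tools

    loc, tau = s
    if loc is Loc.DEAD:
        if a is not None:
            raise ValueError("dead state admits no actions")
        return [Outcome(1.0, 0.0, s, belief, pool)]

    if loc in DETECT_LOCS:
        if a is not None:
            raise ValueError("detect states are chance nodes, not decision states")
        p_die = env.p1 if loc is Loc.CONFIDENT_DETECT else env.p2
        next_pool = step_pool(pool, "elsewhere")
        return [
            Outcome(p_die, env.dying_cost, PhysicalState(Loc.DEAD, 0), belief, next_pool),
            Outcome(1.0 - p_die, 0.0, PhysicalState(Loc.NEST, 0), belief, next_pool),
        ]

    if loc is Loc.RETREAT:
        if a is not None:
            raise ValueError("retreat admits no actions (forced return to nest)")
        return [Outcome(1.0, 0.0, PhysicalState(Loc.NEST, 0), belief, step_pool(pool, "elsewhere"))]

    if a not in available_actions(s):
        raise ValueError(f"action {a} not available in state {s}")

    if loc is Loc.NEST:
        next_pool = step_pool(pool, "elsewhere")
        if a is Action.STAY_NEST:
            return [Outcome(1.0, 0.0, PhysicalState(Loc.NEST, 0), belief, next_pool)]
        obj = Loc.CAUTIOUS_OBJECT if a is Action.APPROACH_CAUTIOUS else Loc.CONFIDENT_OBJECT
        return [Outcome(1.0, env.travel_cost, PhysicalState(obj, 1), belief, next_pool)]

    # object states
    next_pool = step_pool(pool, _pool_location(loc))
    if a is Action.RETREAT:
        return [Outcome(1.0, env.travel_cost, PhysicalState(Loc.RETREAT, 0), belief, next_pool)]
    # stay: survival-conditional hazard increment for turn tau+1
    dh = belief.mean(tau + 1)
    detect = Loc.CAUTIOUS_DETECT if loc is Loc.CAUTIOUS_OBJECT else Loc.CONFIDENT_DETECT
    outcomes = []
    if dh > 0.0:
        outcomes.append(Outcome(dh, 0.0, PhysicalState(detect, tau + 1), belief, next_pool))
    if dh < 1.0:
        outcomes.append(
            Outcome(
                1.0 - dh,
                0.0,
                PhysicalState(loc, tau + 1),
                belief.observe_safe_turn(tau + 1),
                next_pool,
            )
        )
    return outcomes
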