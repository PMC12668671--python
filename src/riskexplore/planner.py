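"""Receding-horizon tree search with nested-CVaR Bellman backups.

The agent plans over hyperstates (physical state, hazard belief,
exploration pool) at a static risk level alpha, backing values up with

    V(s) = r(s) + max_a  gamma * min_{xi in U(alpha)} sum_i xi_i p_i z_i,

where z_i = edge reward + V(successor_i), p_i are the posterior-expected
transition probabilities, and U(alpha) = { xi : 0 <= xi_i <= 1/alpha,
sum_i xi_i p_i = 1 } is the CVaR risk envelope.  The inner minimization has
the classic sorted-greedy solution: pile distorted mass 1/alpha onto the
worst outcomes first.  alpha = 1 recovers the risk-neutral Bayes-adaptive
expectimax.  The distortion is applied at every backup stage (nested,
time-consistent CVaR), and only to realizable transition outcomes weighted
by their expected probabilities -- epistemic uncertainty generates risk only
through those probabilities.

Belief and pool advance along imagined branches exactly as they would in
reality (branch-local copies), so depth-5 search covers one complete
nest -> object -> nest cycle, and leaves are valued at 0.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .environment import (
    Action,
    EnvConstants,
    Loc,
    PhysicalState,
    available_actions,
    state_reward,
    transition_distribution,
)
from .hazard import HazardBelief
from .pool import PoolState

__all__ = ["HyperState", "cvar_distort", "RecedingHorizonPlanner", "plan"]

DEFAULT_DEPTH = 5

#: Fixed tie-break order for action selection (reproducibility).
TIE_BREAK_ORDER = (
    Action.STAY_NEST,
    Action.APPROACH_CAUTIOUS,
    Action.APPROACH_CONFIDENT,
    Action.STAY_OBJECT,
    Action.RETREAT,
)


class HyperState(NamedTuple):
    """Planner node payload: physical state, belief, pool, risk level."""

    physical: PhysicalState
    belief: HazardBelief
    pool: PoolState
    alpha: float


def cvar_distort(
    values: Sequence[float], probs: Sequence[float], alpha: float
) -> tuple[float, np.ndarray]:
    """Solve the inner CVaR minimization over the risk envelope.

    Sorts outcomes ascending by value and greedily assigns distortion weight
    xi = 1/alpha to the worst outcomes until probability mass alpha is
    exhausted (fractionally on the pivot outcome).  Returns the distorted
    value and the per-outcome weights xi (0 <= xi <= 1/alpha,
    sum xi*p = 1).  At alpha = 1 this is the plain expectation.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if values.shape != probs.shape or values.ndim != 1:
        raise ValueError("values and probs must be 1-d and the same length")
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")
    order = np.argsort(values, kind="stable")
    q = np.zeros_like(probs)
    remaining = alpha
    for i in order:
        take = min(probs[i], remaining)
        q[i] = take / alpha
        remaining -= take
        if remaining <= 1e-15:
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(probs > 0.0, q / probs, 0.0)
    return float(q @ values), xi


def _cvar2(v_bad: float, v_good: float, p_bad: float, alpha: float) -> float:
    # two-outcome fast path with v_bad <= v_good
    if p_bad >= alpha:
        return v_bad
    q = p_bad / alpha
    return q * v_bad + (1.0 - q) * v_good


class RecedingHorizonPlanner:
    """Depth-limited nested-CVaR planner over hyperstates.

    One instance per agent configuration; values are memoized across calls
    keyed on the full hyperstate, which makes repeated steady-state
    decisions in long simulations cheap.
    """

    def __init__(self, env: EnvConstants, alpha: float, depth: int = DEFAULT_DEPTH):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if not (0.0 < alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
        self.env = env
        self.alpha = alpha
        self.depth = depth
        self._memo: dict = {}

    # -- value recursion ----------------------------------------------

    def _key(self, s: PhysicalState, belief: HazardBelief, pool: PoolState, d: int):
        p2, p3, p4 = belief.params
        return (s.loc, s.tau, p2.a, p2.b, p3.a, p3.b, p4.a, p4.b, pool.g, d)

    def value(
        self, s: PhysicalState, belief: HazardBelief, pool: PoolState, d: int | None = None
    ) -> float:
        """nCVaR value of a hyperstate with d backup stages remaining."""
        if d is None:
            d = self.depth
        if s.loc is Loc.DEAD:
            return 0.0
        if s.loc in (Loc.CAUTIOUS_DETECT, Loc.CONFIDENT_DETECT):
            # Imagined chance nodes resolve even at the horizon edge: the
            # dying cost must never be truncated away, or marginal approach
            # values inflate at shallow depths and the planner procrastinates.
            key = self._key(s, belief, pool, max(d, 0))
            cached = self._memo.get(key)
            if cached is not None:
                return cached
            v = self.env.gamma * self._chance_value(s, belief, pool, max(d, 0))
            self._memo[key] = v
            return v
        if d <= 0:
            return 0.0
        key = self._key(s, belief, pool, d)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        r = state_reward(s, pool)
        if s.loc is Loc.RETREAT:
            v = r + self.env.gamma * self._chance_value(s, belief, pool, d)
        else:
            best = -np.inf
            for a in available_actions(s):
                best = max(best, self._branch_value(s, a, belief, pool, d))
            v = r + best
        self._memo[key] = v
        return v

    def _chance_value(self, s, belief, pool, d) -> float:
        outs = transition_distribution(s, None, belief, pool, self.env)
        if len(outs) == 1:
            o = outs[0]
            return o.reward + self.value(o.state, o.belief, o.pool, d - 1)
        z = [o.reward + self.value(o.state, o.belief, o.pool, d - 1) for o in outs]
        p = [o.prob for o in outs]
        if z[0] <= z[1]:
            return _cvar2(z[0], z[1], p[0], self.alpha)
        return _cvar2(z[1], z[0], p[1], self.alpha)

    def _branch_value(self, s, a, belief, pool, d) -> float:
        """gamma-discounted distorted backup of taking action a (excludes r(s))."""
        outs = transition_distribution(s, a, belief, pool, self.env)
        if len(outs) == 1:
            o = outs[0]
            return self.env.gamma * (o.reward + self.value(o.state, o.belief, o.pool, d - 1))
        z = [o.reward + self.value(o.state, o.belief, o.pool, d - 1) for o in outs]
        p = [o.prob for o in outs]
        if z[0] <= z[1]:
            distorted = _cvar2(z[0], z[1], p[0], self.alpha)
        else:
            distorted = _cvar2(z[1], z[0], p[1], self.alpha)
        return self.env.gamma * distorted

    # -- action selection ---------------------------------------------

    def plan(self, s: PhysicalState, belief: HazardBelief, pool: PoolState) -> Action:
        """Best action at a real decision state; fixed tie-break order."""
        acts = available_actions(s)
        if not acts:
            raise ValueError(f"state {s} admits no actions")
        if len(acts) == 1:
            return acts[0]
        best_a, best_v = None, -np.inf
        for a in TIE_BREAK_ORDER:
            if a not in acts:
                continue
            v = self._branch_value(s, a, belief, pool, self.depth)
            if v > best_v:
                best_a, best_v = a, v
        return best_a

    def action_values(
        self, s: PhysicalState, belief: HazardBelief, pool: PoolState
    ) -> dict[Action, float]:
        """Q-values (relative to the common state reward) for debugging dumps."""
        r = state_reward(s, pool)
        return {
            a: r + self._branch_value(s, a, belief, pool, self.depth)
            for a in available_actions(s)
        }


def plan(h: HyperState, depth: int = DEFAULT_DEPTH, env: EnvConstants | None = None) -> Action:
    """One-shot planning at a hyperstate (convenience wrapper)."""
    planner = RecedingHorizonPlanner(env or EnvConstants(), h.alpha, depth)
    return planner.plan(h.physical, h.belief, h.pool)
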