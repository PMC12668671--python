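"""Roll the planner out in the real, predator-free environment.

Reality only ever takes the no-detection branch: the imagined predator
never appears, so every bout completes safely and the persistent hazard
belief shrinks by one safe-bout update per completed bout.  Within a bout
the agent's current belief already reflects the turns it has survived so
far (the incremental per-turn form of the same update), which is what the
planner conditions on.  Everything is deterministic given the parameters:
the environment is observation-deterministic and ties are broken in a
fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .environment import (
    Action,
    EnvConstants,
    Loc,
    OBJECT_LOCS,
    PhysicalState,
    available_actions,
)
from .hazard import MAX_TAU, MIN_TAU, HazardBelief, beta_from_mean_var
from .planner import DEFAULT_DEPTH, RecedingHorizonPlanner
from .pool import CAUTIOUS, CONFIDENT, PoolState, step_pool

__all__ = ["AgentParams", "TurnRecord", "Trajectory", "Bout", "simulate", "parse_bouts"]

DEFAULT_N_TURNS = 200  # 2 turns = 1 min, so 200 turns ~ the 100 min session


@dataclass(frozen=True)
class AgentParams:
    """The nine fitted parameters of one agent.

    Hazard prior means and variances for tau = 2, 3, 4 (each variance must
    lie strictly inside (0, mu - mu^2)); the static CVaR risk level alpha in
    (0, 1]; the initial exploration pool g0 > 0; and the per-turn linear
    forgetting rate f >= 0.
    """

    mu2: float
    mu3: float
    mu4: float
    v2: float
    v3: float
    v4: float
    alpha: float
    g0: float
    f: float

    def __post_init__(self) -> None:
        for tau, (mu, v) in zip((2, 3, 4), self.hazard_prior_moments()):
            beta_from_mean_var(mu, v)  # raises with the violated bound
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.g0 <= 0:
            raise ValueError(f"G0 must be positive, got {self.g0}")
        if self.f < 0:
            raise ValueError(f"forgetting rate must be non-negative, got {self.f}")

    def hazard_prior_moments(self):
        return ((self.mu2, self.v2), (self.mu3, self.v3), (self.mu4, self.v4))

    def prior_belief(self) -> HazardBelief:
        return HazardBelief.from_mean_var(
            (self.mu2, self.mu3, self.mu4), (self.v2, self.v3, self.v4)
        )

    def initial_pool(self, env: EnvConstants | None = None) -> PoolState:
        env = env or EnvConstants()
        return PoolState.initial(self.g0, self.f, r_const=env.r_const, k_const=env.k_const)

    def as_vector(self) -> list[float]:
        return [self.mu2, self.mu3, self.mu4, self.v2, self.v3, self.v4, self.alpha, self.g0, self.f]

    @classmethod
    def from_vector(cls, vec) -> "AgentParams":
        return cls(*map(float, vec))


@dataclass(frozen=True)
class TurnRecord:
    turn: int
    loc: Loc
    tau: int
    action: Action | None
    g: float


@dataclass
class Bout:
    """One object visit: first object turn, length in turns, approach type."""

    start: int
    length: int
    approach: str  # 'cautious' | 'confident'


@dataclass
class Trajectory:
    """A simulated state/action sequence plus the final belief."""

    records: list[TurnRecord]
    params: AgentParams | None = None
    final_belief: HazardBelief | None = None
    bouts: list[Bout] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "turn": [r.turn for r in self.records],
                "state": [r.loc.name.lower() for r in self.records],
                "tau": [r.tau for r in self.records],
                "action": [r.action.name.lower() if r.action is not None else "" for r in self.records],
                "G": [r.g for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(
    params: AgentParams,
    n_turns: int = DEFAULT_N_TURNS,
    env: EnvConstants | None = None,
    depth: int = DEFAULT_DEPTH,
) -> Trajectory:
    """Simulate ``n_turns`` of real behavior under one parameter set.

    At every real decision point the receding-horizon planner picks the
    action; forced moves (first object turn, retreat at tau = 4, the
    retreat state itself) are taken directly.  The trajectory is bitwise
    reproducible: there is no randomness anywhere in the loop.
    """
    env = env or EnvConstants()
    planner = RecedingHorizonPlanner(env, params.alpha, depth)
    belief = params.prior_belief()
    pool = params.initial_pool(env)
    s = PhysicalState(Loc.NEST, 0)
    records: list[TurnRecord] = []
    decision_cache: dict = {}

    for t in range(n_turns):
        acts = available_actions(s)
        if not acts:  # retreat: forced return
            action = None
        elif len(acts) == 1:
            action = acts[0]
        else:
            key = planner._key(s, belief, pool, depth)
            action = decision_cache.get(key)
            if action is None:
                action = planner.plan(s, belief, pool)
                decision_cache[key] = action
        records.append(TurnRecord(t, s.loc, s.tau, action, pool.g))

        # real transition: always the safe branch
        if s.loc is Loc.NEST:
            pool = step_pool(pool, "elsewhere")
            if action is Action.STAY_NEST:
                s = PhysicalState(Loc.NEST, 0)
            elif action is Action.APPROACH_CAUTIOUS:
                s = PhysicalState(Loc.CAUTIOUS_OBJECT, 1)
            else:
                s = PhysicalState(Loc.CONFIDENT_OBJECT, 1)
        elif s.loc in OBJECT_LOCS:
            pool = step_pool(
                pool,
                "cautious_object" if s.loc is Loc.CAUTIOUS_OBJECT else "confident_object",
            )
            if action is Action.STAY_OBJECT:
                belief = belief.observe_safe_turn(s.tau + 1)
                s = PhysicalState(s.loc, s.tau + 1)
            else:  # retreat ends the bout; belief already reflects all safe turns
                s = PhysicalState(Loc.RETREAT, 0)
        else:  # retreat state
            pool = step_pool(pool, "elsewhere")
            s = PhysicalState(Loc.NEST, 0)

    traj = Trajectory(records=records, params=params, final_belief=belief)
    traj.bouts = parse_bouts(traj)
    return traj


def parse_bouts(traj: Trajectory) -> list[Bout]:
    """Extract ordered, non-overlapping bouts from a trajectory.

    Each maximal run of object states is one bout; the approach type is read
    from the approach action that opened it.  Raises if an object state is
    not preceded by an approach (malformed trajectory).
    """
    bouts: list[Bout] = []
    records = traj.records
    i = 0
    while i < len(records):
        r = records[i]
        if r.loc in OBJECT_LOCS:
            if r.tau == 1:
                if i > 0 and records[i - 1].action not in (
                    Action.APPROACH_CAUTIOUS,
                    Action.APPROACH_CONFIDENT,
                ):
                    raise ValueError(f"object state at turn {r.turn} not preceded by an approach")
            elif not bouts or i == 0 or records[i - 1].loc != r.loc:
                raise ValueError(f"object state at turn {r.turn} does not continue a bout")
            j = i
            while j < len(records) and records[j].loc is r.loc:
                j += 1
            approach = CAUTIOUS if r.loc is Loc.CAUTIOUS_OBJECT else CONFIDENT
            bouts.append(Bout(start=r.turn, length=j - i, approach=approach))
            i = j
        else:
            i += 1
    return bouts
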