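"""Heuristic exploration-bonus pool.

A depletable, linearly regenerating resource G(t) stands in for the
informational value of the novel object.  While at the object the agent
imagines harvesting reward proportional to the remaining pool,

    r_hat_approach = omega_approach * G(t),

which depletes the pool geometrically, G(t+1) = (1 - omega) G(t); everywhere
the pool regenerates linearly at the forgetting rate f, clamped at its
initial value G0.  Confident approach harvests (and depletes) faster than
cautious approach: omega_confident = R / G0, omega_cautious = K *
omega_confident with R = 1.1 and K = 0.89.  A Beta-like reward pseudocount
term n1/(n1+n0) is carried for completeness but never changes here because
no real reward is ever delivered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "R_DEFAULT",
    "K_DEFAULT",
    "OMEGA_MAX",
    "PoolState",
    "depletion_rates",
    "imagined_reward",
    "step_pool",
]

R_DEFAULT = 1.1
K_DEFAULT = 0.89

# The depletion formulas presuppose G0 > R; for extreme prior draws with
# tiny G0 the confident rate is capped just below 1 to keep depletion
# well-defined.
OMEGA_MAX = 0.999

CAUTIOUS = "cautious"
CONFIDENT = "confident"


def depletion_rates(g0: float, r: float = R_DEFAULT, k: float = K_DEFAULT) -> tuple[float, float]:
    """Return (omega_cautious, omega_confident) for an initial pool G0."""
    if g0 <= 0:
        raise ValueError(f"G0 must be positive, got {g0}")
    omega_confident = min(r / g0, OMEGA_MAX)
    return k * omega_confident, omega_confident


@dataclass(frozen=True, slots=True)
class PoolState:
    """Exploration pool level plus its fixed dynamics parameters.

    Value object: :func:`step_pool` returns new states, so planner branches
    can deplete the pool independently of reality.
    """

    g: float
    g0: float
    f: float
    n1: float = 1.0
    n0: float = 1.0
    r_const: float = R_DEFAULT
    k_const: float = K_DEFAULT

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValueError(f"G0 must be positive, got {self.g0}")
        if not -1e-12 <= self.g <= self.g0 * (1 + 1e-12):
            raise ValueError(f"G must lie in [0, G0]={self.g0}, got {self.g}")
        if self.f < 0:
            raise ValueError(f"forgetting rate must be non-negative, got {self.f}")
        if self.n1 + self.n0 <= 0:
            raise ValueError("reward pseudocounts must have positive sum")

    @classmethod
    def initial(cls, g0: float, f: float, **kw) -> "PoolState":
        return cls(g=g0, g0=g0, f=f, **kw)

    @property
    def omegas(self) -> tuple[float, float]:
        return depletion_rates(self.g0, self.r_const, self.k_const)

    def omega(self, approach: str) -> float:
        cau, con = self.omegas
        if approach == CAUTIOUS:
            return cau
        if approach == CONFIDENT:
            return con
        raise ValueError(f"unknown approach type {approach!r}")


def imagined_reward(pool: PoolState, approach: str) -> float:
    """Per-turn imagined reward at the object: omega*G plus the reward belief."""
    return pool.omega(approach) * pool.g + pool.n1 / (pool.n1 + pool.n0)


def step_pool(pool: PoolState, location: str) -> PoolState:
    """Advance the pool by one turn spent at ``location``.

    ``location`` is ``'cautious_object'``, ``'confident_object'`` or
    ``'elsewhere'``.  At an object state the pool first depletes at the
    approach's rate, then regenerates by f, then clamps at G0; elsewhere it
    only regenerates.
    """
    if location == "elsewhere":
        g = pool.g
    elif location == "cautious_object":
        g = (1.0 - pool.omega(CAUTIOUS)) * pool.g
    elif location == "confident_object":
        g = (1.0 - pool.omega(CONFIDENT)) * pool.g
    else:
        raise ValueError(f"unknown location {location!r}")
    return replace(pool, g=min(g + pool.f, pool.g0))
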