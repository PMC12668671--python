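"""Independent reference implementations used only as test oracles.

Each oracle deliberately avoids the code path it checks: the CVaR
distortion is solved as an explicit linear program over the risk envelope,
the noisy-or posterior predictive is obtained by grid integration of the
per-cause Beta posteriors, and the planner is re-derived as a plain
(memo-free) recursion that uses the LP distortion at every stage.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.stats import beta as beta_dist

from riskexplore.environment import (
    EnvConstants,
    Loc,
    PhysicalState,
    available_actions,
    state_reward,
    transition_distribution,
)


def cvar_lp(values, probs, alpha: float) -> tuple[float, np.ndarray]:
    """CVaR inner minimization as an LP over the envelope constraints.

    minimize sum_i xi_i p_i v_i subject to 0 <= xi_i <= 1/alpha and
    sum_i xi_i p_i = 1.
    """
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    res = linprog(
        c=probs * values,
        A_eq=[probs],
        b_eq=[1.0],
        bounds=[(0.0, 1.0 / alpha)] * len(values),
        method="highs",
    )
    if not res.success:  # pragma: no cover - the LP is always feasible
        raise RuntimeError(f"LP failed: {res.message}")
    return float(res.fun), res.x


def hazard_predictive_grid(
    prior_pseudocounts: dict[int, tuple[float, float]],
    safe_bout_lengths: list[int],
    tau: int,
    n_grid: int = 20001,
) -> float:
    """Posterior-predictive hazard by numerical integration.

    Each cause theta_j (j = 2..4) has an independent Beta prior; a safe bout
    of length L contributes a likelihood factor (1 - theta_j) for every
    j <= L.  The predictive detection probability after tau turns is
    1 - prod_j E_post[1 - theta_j].
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    survival = 1.0
    for j in range(2, tau + 1):
        a0, b0 = prior_pseudocounts[j]
        n_j = sum(1 for length in safe_bout_lengths if length >= j)
        pdf = beta_dist.pdf(grid, a0, b0)
        like = (1.0 - grid) ** n_j
        post = pdf * like
        expect_1m = np.trapezoid(post * (1.0 - grid), grid) / np.trapezoid(post, grid)
        survival *= expect_1m
    return 1.0 - survival


def plan_value_oracle(
    s: PhysicalState,
    belief,
    pool,
    alpha: float,
    depth: int,
    env: EnvConstants | None = None,
) -> float:
    """Memo-free nested-CVaR tree value with the LP distortion at each stage.

    Mirrors the planner's stage semantics (leaf value 0 at real states;
    imagined detect nodes resolve even with the depth budget exhausted) but
    shares none of its implementation beyond the environment model.
    """
    env = env or EnvConstants()

    def distorted(outs, d):
        z = np.array([o.reward + recurse(o.state, o.belief, o.pool, d) for o in outs])
        p = np.array([o.prob for o in outs])
        if len(outs) == 1:
            return float(z[0])
        val, _ = cvar_lp(z, p, alpha)
        return val

    def recurse(state, bel, pl, d):
        if state.loc is Loc.DEAD:
            return 0.0
        if state.loc in (Loc.CAUTIOUS_DETECT, Loc.CONFIDENT_DETECT):
            outs = transition_distribution(state, None, bel, pl, env)
            return env.gamma * distorted(outs, max(d, 0) - 1)
        if d <= 0:
            return 0.0
        r = state_reward(state, pl)
        if state.loc is Loc.RETREAT:
            outs = transition_distribution(state, None, bel, pl, env)
            return r + env.gamma * distorted(outs, d - 1)
        best = -np.inf
        for a in available_actions(state):
            outs = transition_distribution(state, a, bel, pl, env)
            best = max(best, env.gamma * distorted(outs, d - 1))
        return r + best

    return recurse(s, belief, pool, depth)
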