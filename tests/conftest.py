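import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riskexplore import EnvConstants, HazardBelief
from riskexplore.hazard import BetaParam
from riskexplore.pool import PoolState

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def env():
    return EnvConstants()


@pytest.fixture
def uniform_belief():
    """Beta(1, 1) on every hazard cause."""
    return HazardBelief((BetaParam(1, 1), BetaParam(1, 1), BetaParam(1, 1)))


@pytest.fixture
def fresh_pool():
    return PoolState.initial(g0=20.0, f=0.1)


def make_belief(means, spread=0.5):
    """Belief with given cause means and variance a fixed fraction of the bound."""
    from riskexplore import beta_from_mean_var

    return HazardBelief(tuple(beta_from_mean_var(m, spread * (m - m * m)) for m in means))


def random_hyperstate(rng: np.random.Generator, env: EnvConstants):
    """Random small hyperstate for planner/oracle comparisons."""
    from riskexplore import Loc, PhysicalState

    means = rng.uniform(0.05, 0.6, size=3)
    spreads = rng.uniform(0.1, 0.8, size=3)
    belief = HazardBelief(
        tuple(
            BetaParam(*_ab(m, s))
            for m, s in zip(means, spreads)
        )
    )
    g0 = rng.uniform(5.0, 40.0)
    pool = PoolState(g=rng.uniform(0.2, 1.0) * g0, g0=g0, f=rng.uniform(0.0, 0.5))
    options = [(Loc.NEST, 0), (Loc.CAUTIOUS_OBJECT, 1), (Loc.CAUTIOUS_OBJECT, 2),
               (Loc.CONFIDENT_OBJECT, 2), (Loc.CONFIDENT_OBJECT, 3), (Loc.RETREAT, 0)]
    loc, tau = options[rng.integers(len(options))]
    alpha = rng.uniform(0.1, 1.0)
    return PhysicalState(Loc(loc), int(tau)), belief, pool, float(alpha)


def _ab(mu, spread):
    v = spread * (mu - mu * mu)
    common = (mu * mu - mu + v) / v
    return -mu * common, (mu - 1.0) * common
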