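"""Likelihood-free fitting of the nine agent parameters by ABC-SMC.

The agent's behavior statistics have no tractable likelihood, so parameters
are fitted by Approximate Bayesian Computation with Sequential Monte Carlo
(the Toni et al. particle scheme): populations of weighted parameter
particles are filtered through a shrinking acceptance threshold on a
normalized L1 distance between simulated and observed statistic vectors,

    d(x, x0) = (1/n) * sum_i |x_i - x0_i| / C_i(x_i),

where the normalizer depends on the statistic kind, evaluated at the
simulated value: durations use the constant 4.0 s; transition times use
min(30, 10 + 0.8*max(x-5, 0)); frequency ratios use
min(20, 2 + (18/19)*max(x-1, 0)).  The piecewise-linear caps stop extreme
values from dominating the distance.

The threshold schedule is adaptive -- epsilon_t is the 30th percentile of
the previous population's distances -- with uniform priors, a diagonal
Gaussian perturbation kernel whose per-dimension bandwidth follows the
Silverman rule, and importance weights w ~ prior(theta) / sum_j w_j
K(theta | theta_j).  Simulation itself is deterministic, so all randomness
lives in the particle sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .environment import EnvConstants
from .phases import StatVector, model_statistics
from .planner import DEFAULT_DEPTH
from .simulate import DEFAULT_N_TURNS, AgentParams, simulate

__all__ = [
    "distance",
    "silverman_bandwidth",
    "PriorRanges",
    "Population",
    "ABCSMC",
    "run_abcsmc",
]

PARAM_NAMES = ("mu2", "mu3", "mu4", "v2", "v3", "v4", "alpha", "g0", "f")


# ---------------------------------------------------------------------------
# distance


def _normalizer(kind: str, x: float) -> float:
    if kind == "duration":
        return 4.0
    if kind == "time":
        return min(30.0, 10.0 + 0.8 * max(x - 5.0, 0.0))
    if kind == "ratio":
        return min(20.0, 2.0 + (18.0 / 19.0) * max(x - 1.0, 0.0))
    raise ValueError(f"unknown statistic kind {kind!r}")


def distance(x: StatVector, x0: StatVector) -> float:
    """Normalized L1 distance between simulated (x) and observed (x0) statistics.

    Asymmetric by design: the normalizer is evaluated at the simulated
    value.  Both vectors must belong to the same group.
    """
    if x.group != x0.group:
        raise ValueError(f"statistic groups differ: {x.group} vs {x0.group}")
    terms = [
        abs(xi - x0i) / _normalizer(kind, xi)
        for xi, x0i, kind in zip(x.values, x0.values, x.kinds)
    ]
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# kernel bandwidth


def silverman_bandwidth(particles: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Per-dimension Silverman kernel scales 0.9 * min(sd, IQR/1.34) * B^(-1/5).

    Degenerate dimensions (zero spread) are floored at a small positive
    epsilon so the perturbation kernel stays proper.
    """
    x = np.asarray(particles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (B, d) array with at least 2 particles")
    b = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25], axis=0))
    scale = 0.9 * np.minimum(sd, iqr / 1.34) * b ** (-0.2)
    return np.maximum(scale, floor)


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorRanges:
    """Uniform prior ranges for the nine fitted parameters.

    Hazard means are uniform on ``mu``; each variance is uniform on
    (0, mu - mu^2) conditionally on its mean, which is the full admissible
    Beta-variance range.
    """

    mu: tuple[float, float] = (0.01, 0.99)
    alpha: tuple[float, float] = (0.05, 1.0)
    g0: tuple[float, float] = (2.0, 40.0)
    f: tuple[float, float] = (0.0, 2.0)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        mus = rng.uniform(*self.mu, size=3)
        vs = rng.uniform(0.0, mus - mus**2)
        return np.array([
            *mus, *vs,
            rng.uniform(*self.alpha),
            rng.uniform(*self.g0),
            rng.uniform(*self.f),
        ])

    def in_support(self, theta: np.ndarray) -> bool:
        mus, vs = theta[0:3], theta[3:6]
        if np.any(mus < self.mu[0]) or np.any(mus > self.mu[1]):
            return False
        if np.any(vs <= 0.0) or np.any(vs >= mus - mus**2):
            return False
        a, g0, f = theta[6], theta[7], theta[8]
        return (
            self.alpha[0] <= a <= self.alpha[1]
            and self.g0[0] <= g0 <= self.g0[1]
            and self.f[0] <= f <= self.f[1]
        )

    def logpdf(self, theta: np.ndarray) -> float:
        if not self.in_support(theta):
            return -np.inf
        mus = theta[0:3]
        # conditional density of each variance is 1/(mu - mu^2); the
        # constant factors of the uniform ranges cancel in the weights
        return float(-np.sum(np.log(mus - mus**2)))


# ---------------------------------------------------------------------------
# populations


@dataclass
class Population:
    """One ABC-SMC generation: weighted particles with their distances."""

    generation: int
    epsilon: float
    particles: np.ndarray  # (B, 9)
    weights: np.ndarray
    distances: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=list(PARAM_NAMES))
        df["weight"] = self.weights
        df["distance"] = self.distances
        df["generation"] = self.generation
        return df


# ---------------------------------------------------------------------------
# the sampler


class ABCSMC(BaseEstimator):
    """ABC-SMC sampler for the risk-sensitive exploration agent.

    scikit-learn style estimator: hyperparameters in ``__init__``,
    :meth:`fit` consumes an observed :class:`StatVector` and exposes the
    posterior populations as fitted attributes.

    Parameters
    ----------
    n_populations : generations to run (the full protocol uses 30).
    population_size : particles per generation (the full protocol uses 100).
    quantile : percentile of the previous generation's distances used as
        the next acceptance threshold.
    priors : uniform prior ranges; defaults to :class:`PriorRanges`.
    n_turns, depth : simulation length and planning horizon per particle.
    env : environment constants shared by all particles.
    max_proposals_per_particle : retry budget per accepted particle in a
        generation; a stalled generation ends the run early with the
        populations collected so far.
    min_acceptance : acceptance-rate floor below which the run stops early.
    random_state : seed or Generator for all sampling.

    Attributes
    ----------
    populations_ : list of :class:`Population`, one per completed generation.
    posterior_ : DataFrame of the final population (one particle per row).
    epsilons_ : the realized threshold schedule.
    n_generations_ : number of completed generations.
    stalled_ : True if the run ended early for lack of acceptances.
    """

    def __init__(
        self,
        n_populations: int = 30,
        population_size: int = 100,
        quantile: float = 30.0,
        priors: PriorRanges | None = None,
        n_turns: int = DEFAULT_N_TURNS,
        depth: int = DEFAULT_DEPTH,
        env: EnvConstants | None = None,
        max_proposals_per_particle: int = 50,
        min_acceptance: float = 0.005,
        random_state=None,
    ):
        self.n_populations = n_populations
        self.population_size = population_size
        self.quantile = quantile
        self.priors = priors
        self.n_turns = n_turns
        self.depth = depth
        self.env = env
        self.max_proposals_per_particle = max_proposals_per_particle
        self.min_acceptance = min_acceptance
        self.random_state = random_state

    # -- simulation ----------------------------------------------------

    def _simulate_distance(self, theta: np.ndarray, observed: StatVector) -> float:
        """Distance of one particle; infinite when the phase structure differs."""
        params = AgentParams.from_vector(theta)
        stats, _ = model_statistics(
            simulate(params, n_turns=self.n_turns, env=self.env or EnvConstants(), depth=self.depth)
        )
        if stats is None or stats.group != observed.group:
            return np.inf
        return distance(stats, observed)

    # -- fitting -------------------------------------------------------

    def fit(self, observed: StatVector, y=None) -> "ABCSMC":
        priors = self.priors or PriorRanges()
        rng = np.random.default_rng(
            check_random_state(self.random_state).randint(2**31)
            if not isinstance(self.random_state, np.random.Generator)
            else self.random_state
        )
        b = self.population_size
        budget = self.max_proposals_per_particle * b

        populations: list[Population] = []
        epsilons: list[float] = []
        self.stalled_ = False

        # generation 0: rejection sampling from the prior, keeping particles
        # whose simulated phase structure matches the observed group
        particles, dists = [], []
        tries = 0
        while len(particles) < b and tries < budget:
            theta = priors.sample(rng)
            tries += 1
            d = self._simulate_distance(theta, observed)
            if np.isfinite(d):
                particles.append(theta)
                dists.append(d)
        if len(particles) < 2:
            raise RuntimeError(
                "ABC-SMC could not initialize: almost no prior draw reproduces the "
                f"observed {observed.group} phase structure ({len(particles)}/{tries} draws)"
            )
        particles = np.array(particles)
        dists = np.array(dists)
        weights = np.full(len(particles), 1.0 / len(particles))
        epsilon = np.inf
        populations.append(Population(0, epsilon, particles, weights, dists))

        for t in range(1, self.n_populations):
            prev = populations[-1]
            epsilon = min(
                float(np.percentile(prev.distances, self.quantile)),
                epsilons[-1] if epsilons else np.inf,
            )
            epsilons.append(epsilon)
            sigma = silverman_bandwidth(prev.particles)
            new_particles, new_dists, new_weights = [], [], []
            tries = 0
            while len(new_particles) < b and tries < budget:
                tries += 1
                j = rng.choice(len(prev.particles), p=prev.weights)
                theta = prev.particles[j] + rng.normal(0.0, sigma)
                if not priors.in_support(theta):
                    continue
                d = self._simulate_distance(theta, observed)
                if not d <= epsilon:
                    continue
                # Toni et al. importance weight
                log_k = -0.5 * np.sum(((theta - prev.particles) / sigma) ** 2, axis=1)
                denom = float(np.sum(prev.weights * np.exp(log_k - log_k.max())))
                w = np.exp(priors.logpdf(theta) - log_k.max()) / denom
                new_particles.append(theta)
                new_dists.append(d)
                new_weights.append(w)
            if len(new_particles) < 2 or len(new_particles) / max(tries, 1) < self.min_acceptance:
                self.stalled_ = True
                break
            particles = np.array(new_particles)
            weights = np.array(new_weights)
            weights = weights / weights.sum()
            populations.append(
                Population(t, epsilon, particles, weights, np.array(new_dists))
            )

        self.populations_ = populations
        self.epsilons_ = epsilons[: len(populations) - 1]
        self.n_generations_ = len(populations)
        self.posterior_ = populations[-1].to_dataframe()
        return self

    def all_populations_dataframe(self) -> pd.DataFrame:
        return pd.concat([p.to_dataframe() for p in self.populations_], ignore_index=True)


def run_abcsmc(observed: StatVector, priors: PriorRanges | None = None, **config) -> list[Population]:
    """Functional wrapper: run the sampler and return its populations."""
    sampler = ABCSMC(priors=priors, **config)
    sampler.fit(observed)
    return sampler.populations_
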