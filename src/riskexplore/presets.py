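"""Reference agent configurations for the three phenotypes.

These parameter sets were chosen, once, by pilot simulation so that each
realizes its phenotype under the default environment constants:

* ``BRAVE`` -- flexible, lower-mean hazard prior and risk-neutral alpha = 1:
  a short cautious phase, a persistent switch to confident approach
  (t1 < t2) and an eventual frequency slowdown as the bonus pool depletes.
* ``INTERMEDIATE`` -- flexible prior with a fast-forgetting, large pool:
  switches to confident approach but never slows down (no peak-to-steady
  transition within a 200-turn session).
* ``TIMID`` -- higher-mean, inflexible (low-variance) hazard prior and
  alpha < 1: only short cautious bouts, an early peak-to-steady slowdown,
  and zero confident bouts.

They are fixtures of the model's behavioral repertoire, not fits to any
animal.
"""

from .simulate import AgentParams

__all__ = ["BRAVE_PARAMS", "INTERMEDIATE_PARAMS", "TIMID_PARAMS", "PHENOTYPE_PARAMS"]


def _v(mu: float, frac: float) -> float:
    # variance as a fraction of its Beta upper bound mu - mu^2
    return frac * (mu - mu * mu)


BRAVE_PARAMS = AgentParams(
    mu2=0.2, mu3=0.1, mu4=0.1,
    v2=_v(0.2, 0.7), v3=_v(0.1, 0.5), v4=_v(0.1, 0.5),
    alpha=1.0, g0=30.0, f=0.1,
)

INTERMEDIATE_PARAMS = AgentParams(
    mu2=0.3, mu3=0.06, mu4=0.06,
    v2=_v(0.3, 0.5), v3=_v(0.06, 0.5), v4=_v(0.06, 0.5),
    alpha=1.0, g0=40.0, f=0.3,
)

TIMID_PARAMS = AgentParams(
    mu2=0.25, mu3=0.35, mu4=0.35,
    v2=_v(0.25, 0.03), v3=_v(0.35, 0.03), v4=_v(0.35, 0.03),
    alpha=0.9, g0=32.0, f=0.05,
)

PHENOTYPE_PARAMS = {
    "brave": BRAVE_PARAMS,
    "intermediate": INTERMEDIATE_PARAMS,
    "timid": TIMID_PARAMS,
}
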