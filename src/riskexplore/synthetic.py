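"""Synthetic minute-resolution bout records and model-derived fit targets.

Stand-ins for deposited animal data: boxcar-shaped phase profiles for the
three phenotypes with additive truncated Gaussian noise, plus targets
obtained by simulating a known agent configuration (for parameter-recovery
studies).  The archetype numbers sketch typical open-field novel-object
sessions (100 min, percent approach times of tens of percent, bout
durations under 4 s, a few bouts per minute); they are fixtures, not
measurements.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .environment import EnvConstants
from .phases import BRAVE, INTERMEDIATE, TIMID, MinuteRecord, StatVector, model_statistics
from .simulate import DEFAULT_N_TURNS, AgentParams, simulate

__all__ = ["ArchetypeSpec", "generate_minute_record", "generate_model_target", "ARCHETYPES"]

DEFAULT_MINUTES = 100  # the 200-turn session at 2 turns per minute


@dataclass
class ArchetypeSpec:
    """Ground-truth phase structure of one synthetic animal.

    Transition times in minutes; levels in percent time; durations in
    seconds; frequencies in bouts/min.  Phases are, per group:
    brave cautious/peak/steady, intermediate cautious/confident, timid
    peak/steady (both cautious).  ``noise_sd`` holds per-channel Gaussian
    noise standard deviations (keys: pct, duration, frequency).
    """

    group: str
    t1: float | None
    t2: float | None
    levels_cautious: tuple[float, ...]
    levels_confident: tuple[float, ...]
    durations: tuple[float, ...]
    frequencies: tuple[float, ...]
    noise_sd: dict = field(default_factory=lambda: {"pct": 0.0, "duration": 0.0, "frequency": 0.0})
    n_minutes: int = DEFAULT_MINUTES

    def __post_init__(self) -> None:
        n_phases = {BRAVE: 3, INTERMEDIATE: 2, TIMID: 2}.get(self.group)
        if n_phases is None:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("levels_cautious", "levels_confident", "durations", "frequencies"):
            if len(getattr(self, name)) != n_phases:
                raise ValueError(f"{name} must have {n_phases} entries for group {self.group}")
        if self.group == TIMID:
            if any(v != 0 for v in self.levels_confident):
                raise ValueError("timid archetypes have no confident approach")
            if self.t1 is not None:
                raise ValueError("timid archetypes have no cautious-to-confident transition")
            if self.t2 is None:
                raise ValueError("timid archetypes need the peak-to-steady transition t2")
        elif self.group == INTERMEDIATE:
            if self.t2 is not None:
                raise ValueError("intermediate archetypes have no peak-to-steady transition")
            if self.t1 is None:
                raise ValueError("intermediate archetypes need t1")
        else:
            if self.t1 is None or self.t2 is None or not self.t1 < self.t2:
                raise ValueError("brave archetypes need t1 < t2")
        for t in (self.t1, self.t2):
            if t is not None and not 0 < t < self.n_minutes:
                raise ValueError("transition times must lie inside the session")

    @property
    def change_points(self) -> list[int]:
        return [int(t) for t in (self.t1, self.t2) if t is not None]

    def ground_truth_statistics(self) -> StatVector:
        """The statistic vector a noiseless record of this spec must yield."""
        d, f = self.durations, self.frequencies
        if self.group == BRAVE:
            values = [self.t1, self.t2, d[0], d[1], f[1] / f[2]]
        elif self.group == INTERMEDIATE:
            values = [self.t1, d[0], d[1], max(f[0] / f[1], 1.0)]
        else:
            values = [self.t2, d[0], d[1], f[0] / f[1]]
        return StatVector(group=self.group, values=np.array(values, dtype=float))

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _piecewise(points: list[int], levels, n: int) -> np.ndarray:
    out = np.empty(n)
    bounds = [0, *points, n]
    for lo, hi, level in zip(bounds[:-1], bounds[1:], levels):
        out[lo:hi] = level
    return out


def generate_minute_record(
    spec: ArchetypeSpec, seed: int | None = None
) -> MinuteRecord:
    """Render an archetype into a minute-resolution record.

    Channels are boxcar profiles given by the spec's phase levels with
    additive Gaussian noise, truncated to valid ranges (percentages to
    [0, 100] with cautious + confident <= 100; durations and frequencies to
    non-negative values).  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_minutes
    pts = spec.change_points
    g_cau = _piecewise(pts, spec.levels_cautious, n)
    g_con = _piecewise(pts, spec.levels_confident, n)
    dur = _piecewise(pts, spec.durations, n)
    freq = _piecewise(pts, spec.frequencies, n)

    sd = spec.noise_sd
    if sd.get("pct", 0.0) > 0:
        g_cau = g_cau + rng.normal(0.0, sd["pct"], n)
        g_con = np.where(g_con > 0, g_con + rng.normal(0.0, sd["pct"], n), g_con)
        g_cau = np.clip(g_cau, 0.0, 100.0)
        g_con = np.clip(g_con, 0.0, 100.0)
        over = g_cau + g_con - 100.0
        g_con = np.where(over > 0, g_con - over, g_con)
    if sd.get("duration", 0.0) > 0:
        dur = np.clip(dur + rng.normal(0.0, sd["duration"], n), 0.0, None)
    if sd.get("frequency", 0.0) > 0:
        freq = np.clip(freq + rng.normal(0.0, sd["frequency"], n), 0.0, None)
    return MinuteRecord(
        pct_cautious=g_cau, pct_confident=g_con, duration_s=dur, bouts_per_min=freq
    )


def generate_model_target(
    theta: AgentParams,
    n_turns: int = DEFAULT_N_TURNS,
    env: EnvConstants | None = None,
    depth: int = 5,
) -> StatVector:
    """Simulate a known configuration and return its statistics as a fit target.

    The simulator is deterministic, so repeated calls give identical
    targets; a degenerate trajectory (no usable phases) raises.
    """
    stats, phases = model_statistics(simulate(theta, n_turns=n_turns, env=env, depth=depth))
    if stats is None:
        raise ValueError(
            f"configuration produced a degenerate ({phases.group}) trajectory with no statistics"
        )
    return stats


# Default archetypes sketching the three phenotypes (fixtures only).
ARCHETYPES = {
    BRAVE: ArchetypeSpec(
        group=BRAVE, t1=12.0, t2=35.0,
        levels_cautious=(30.0, 0.0, 0.0),
        levels_confident=(0.0, 60.0, 20.0),
        durations=(1.0, 3.0, 3.0),
        frequencies=(5.0, 6.0, 2.0),
    ),
    INTERMEDIATE: ArchetypeSpec(
        group=INTERMEDIATE, t1=20.0, t2=None,
        levels_cautious=(25.0, 0.0),
        levels_confident=(0.0, 40.0),
        durations=(1.0, 2.5),
        frequencies=(4.0, 4.0),
    ),
    TIMID: ArchetypeSpec(
        group=TIMID, t1=None, t2=25.0,
        levels_cautious=(25.0, 8.0),
        levels_confident=(0.0, 0.0),
        durations=(1.5, 0.75),
        frequencies=(4.0, 1.5),
    ),
}
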