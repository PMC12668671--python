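"""Phase abstraction and fitted statistics for animal records and model runs.

Minute-resolution bout records (percent time in cautious/confident approach,
mean bout duration, bouts per minute) are abstracted into piecewise-constant
behavioral phases by boxcar (two-level step) fits, animals are classified
into brave / intermediate / timid groups, and a small group-specific vector
of statistics is extracted for likelihood-free fitting:

* brave (3 phases): cautious -> confident-peak -> confident-steady; fitted
  statistics are the two transition times, the cautious and peak-confident
  durations and the peak/steady frequency ratio (5 values);
* intermediate (2 phases): cautious -> confident, no peak-to-steady split;
  transition time, both durations, and max(f_cau/f_con, 1) (4 values) --
  the ratio is clamped because pool depletion can only ever slow bouts down;
* timid (2 phases): cautious-peak -> cautious-steady, never confident;
  transition time, both durations, and the peak/steady frequency ratio
  (4 values).

Model trajectories are mapped into the same space: the cautious-to-confident
transition is the first confident bout, the peak-to-steady transition is the
first time the agent waits more than one consecutive turn at the nest, and
units are converted at 2 turns per minute and 0.75 + 1.5*(d-2) seconds per
bout of d turns (so agent durations span 0.75-3.75 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import CAUTIOUS, CONFIDENT
from .simulate import Trajectory, parse_bouts

__all__ = [
    "TURNS_PER_MINUTE",
    "MinuteRecord",
    "PhaseSummary",
    "StatVector",
    "turns_to_minutes",
    "duration_to_seconds",
    "map_units",
    "fit_boxcar",
    "classify_group",
    "extract_statistics",
    "summarize_record",
    "model_statistics",
]

TURNS_PER_MINUTE = 2.0

BRAVE = "brave"
INTERMEDIATE = "intermediate"
TIMID = "timid"

#: statistic kinds drive the fitting distance normalization
TIME, DURATION, RATIO = "time", "duration", "ratio"

STAT_LAYOUT = {
    BRAVE: (
        ("t_cautious_to_confident", TIME),
        ("t_peak_to_steady", TIME),
        ("d_cautious", DURATION),
        ("d_peak_confident", DURATION),
        ("f_peak_over_steady", RATIO),
    ),
    INTERMEDIATE: (
        ("t_cautious_to_confident", TIME),
        ("d_cautious", DURATION),
        ("d_confident", DURATION),
        ("f_cautious_over_confident", RATIO),
    ),
    TIMID: (
        ("t_peak_to_steady", TIME),
        ("d_cautious_peak", DURATION),
        ("d_cautious_steady", DURATION),
        ("f_peak_over_steady", RATIO),
    ),
}


# ---------------------------------------------------------------------------
# unit mappings


def turns_to_minutes(turns: float) -> float:
    """Agent turns -> experiment minutes (2 turns per minute)."""
    return turns / TURNS_PER_MINUTE


def duration_to_seconds(d_agent: float) -> float:
    """Agent bout duration (turns at the object) -> animal seconds.

    Linear on the realizable range [2, 4]: 2 turns -> 0.75 s, 4 -> 3.75 s.
    """
    if not 2.0 <= d_agent <= 4.0:
        raise ValueError(f"agent bout duration must lie in [2, 4] turns, got {d_agent}")
    return 0.75 + 1.5 * (d_agent - 2.0)


def map_units(turns: float | None = None, d_agent: float | None = None):
    """Convenience dispatcher: map turns to minutes and/or duration to seconds."""
    out = []
    if turns is not None:
        out.append(turns_to_minutes(turns))
    if d_agent is not None:
        out.append(duration_to_seconds(d_agent))
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# containers


RECORD_COLUMNS = ("minute", "pct_cautious", "pct_confident", "duration_s", "bouts_per_min")


@dataclass
class MinuteRecord:
    """Minute-resolution bout summary of one animal (or one synthetic one)."""

    pct_cautious: np.ndarray
    pct_confident: np.ndarray
    duration_s: np.ndarray
    bouts_per_min: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (
            self.pct_cautious, self.pct_confident, self.duration_s, self.bouts_per_min)]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all channels must have equal length")
        self.pct_cautious, self.pct_confident, self.duration_s, self.bouts_per_min = arrays
        if np.any(self.pct_cautious < 0) or np.any(self.pct_confident < 0):
            raise ValueError("percentages must be non-negative")
        if np.any(self.pct_cautious + self.pct_confident > 100.0 + 1e-9):
            raise ValueError("cautious + confident percent time cannot exceed 100")

    def __len__(self) -> int:
        return len(self.pct_cautious)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": np.arange(len(self)),
                "pct_cautious": self.pct_cautious,
                "pct_confident": self.pct_confident,
                "duration_s": self.duration_s,
                "bouts_per_min": self.bouts_per_min,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MinuteRecord":
        df = pd.read_csv(path)
        missing = set(RECORD_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"record CSV missing columns: {sorted(missing)}")
        df = df.sort_values("minute")
        return cls(
            pct_cautious=df["pct_cautious"].to_numpy(float),
            pct_confident=df["pct_confident"].to_numpy(float),
            duration_s=df["duration_s"].to_numpy(float),
            bouts_per_min=df["bouts_per_min"].to_numpy(float),
        )


@dataclass
class PhaseSummary:
    """Segmented behavioral phases with per-phase averaged statistics.

    Transition times are in minutes; durations in seconds; frequencies in
    bouts per minute.  ``degenerate`` marks a record/trajectory with no
    usable phase structure (e.g. an agent that never leaves the nest), which
    cannot be fitted.
    """

    group: str
    t1: float | None = None  # cautious -> confident (brave, intermediate)
    t2: float | None = None  # peak -> steady (brave, timid)
    durations: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "group": self.group,
                "t1": self.t1,
                "t2": self.t2,
                "durations": self.durations,
                "frequencies": self.frequencies,
                "levels": self.levels,
                "degenerate": self.degenerate,
            }
        )


@dataclass
class StatVector:
    """Group-specific fitted statistics in the shared model/animal space."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in STAT_LAYOUT:
            raise ValueError(f"unknown group {self.group!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(STAT_LAYOUT[self.group]),):
            raise ValueError(
                f"{self.group} statistics need {len(STAT_LAYOUT[self.group])} entries, "
                f"got shape {self.values.shape}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in STAT_LAYOUT[self.group])

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(kind for _, kind in STAT_LAYOUT[self.group])

    def as_dict(self) -> dict:
        return dict(zip(self.names, map(float, self.values)))

    def to_json(self) -> str:
        return json.dumps({"group": self.group, **self.as_dict()})


# ---------------------------------------------------------------------------
# boxcar segmentation


def fit_boxcar(series) -> tuple[int | None, float, float]:
    """Least-squares two-level step fit by exhaustive change-point search.

    Returns ``(change_point, level_before, level_after)`` where the first
    segment is ``series[:change_point]``.  A series with no improving split
    (constant, up to numerical noise) returns ``(None, mean, mean)``.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("boxcar fit needs at least 2 points")
    n = y.size
    total_mean = y.mean()
    sse_const = float(((y - total_mean) ** 2).sum())
    # prefix sums give O(n) evaluation of all candidate splits
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    best_k, best_sse = None, sse_const
    for k in range(1, n):
        s1, s2 = c1[k - 1], c1[-1] - c1[k - 1]
        q1, q2 = c2[k - 1], c2[-1] - c2[k - 1]
        sse = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    if best_k is None:
        return None, float(total_mean), float(total_mean)
    return best_k, float(y[:best_k].mean()), float(y[best_k:].mean())


# ---------------------------------------------------------------------------
# group classification (animal records)

CLASSIFY_WINDOW = 10  # minutes


def classify_group(record: MinuteRecord) -> str:
    """Classify an animal by its confident-approach dynamics.

    No confident approach at all -> timid.  Otherwise compute the ratio y of
    confident approach time in the first 10 minutes after confident onset to
    that in the last 10 minutes of the session; y > 1 (approach decays from
    a peak) -> brave, y <= 1 -> intermediate.
    """
    n = len(record)
    if n < 2 * CLASSIFY_WINDOW:
        raise ValueError(
            f"record must span at least {2 * CLASSIFY_WINDOW} minutes to classify, got {n}"
        )
    g_con = record.pct_confident
    if g_con.sum() == 0.0:
        return TIMID
    onset = int(np.argmax(g_con > 0.0))
    first = g_con[onset : onset + CLASSIFY_WINDOW].sum()
    last = g_con[n - CLASSIFY_WINDOW :].sum()
    if last == 0.0:
        return BRAVE  # confident approach vanished entirely: extreme peak/steady drop
    return BRAVE if first / last > 1.0 else INTERMEDIATE


# ---------------------------------------------------------------------------
# statistics extraction


def extract_statistics(phases: PhaseSummary) -> StatVector:
    """Build the group-specific statistic vector from a phase summary."""
    if phases.degenerate:
        raise ValueError("degenerate phase summary has no statistics")
    g = phases.group
    d, f = phases.durations, phases.frequencies

    def need(container, key, what):
        if key not in container or container[key] is None:
            raise ValueError(f"missing {what} for phase {key!r} in {g} summary")
        return container[key]

    if g == BRAVE:
        if phases.t1 is None or phases.t2 is None:
            raise ValueError("brave summary requires both transition times t1 and t2")
        values = [
            phases.t1,
            phases.t2,
            need(d, "cautious", "duration"),
            need(d, "confident_peak", "duration"),
            need(f, "confident_peak", "frequency") / need(f, "confident_steady", "frequency"),
        ]
    elif g == INTERMEDIATE:
        if phases.t1 is None:
            raise ValueError("intermediate summary requires transition time t1")
        values = [
            phases.t1,
            need(d, "cautious", "duration"),
            need(d, "confident", "duration"),
            max(need(f, "cautious", "frequency") / need(f, "confident", "frequency"), 1.0),
        ]
    elif g == TIMID:
        if phases.t2 is None:
            raise ValueError("timid summary requires transition time t2")
        values = [
            phases.t2,
            need(d, "cautious_peak", "duration"),
            need(d, "cautious_steady", "duration"),
            need(f, "cautious_peak", "frequency") / need(f, "cautious_steady", "frequency"),
        ]
    else:  # pragma: no cover - guarded by PhaseSummary construction
        raise ValueError(f"unknown group {g!r}")
    return StatVector(group=g, values=np.array(values))


def _phase_means(record: MinuteRecord, lo: int, hi: int) -> tuple[float, float]:
    if hi <= lo:
        raise ValueError(f"empty phase window [{lo}, {hi})")
    return (
        float(record.duration_s[lo:hi].mean()),
        float(record.bouts_per_min[lo:hi].mean()),
    )


def summarize_record(record: MinuteRecord) -> tuple[StatVector, PhaseSummary]:
    """Segment an animal record into phases and extract its statistics.

    The group decides which boxcar fits to run: the cautious curve yields
    the cautious-to-confident transition (its collapse) for brave and
    intermediate animals and the peak-to-steady transition for timid ones;
    for brave animals the confident curve after t1 yields the second
    transition.  Phase levels are segment means.
    """
    n = len(record)
    group = classify_group(record)
    durations, freqs, levels = {}, {}, {}
    if group == TIMID:
        k, before, after = fit_boxcar(record.pct_cautious)
        if k is None:
            return (
                None,
                PhaseSummary(group=TIMID, degenerate=True),
            )
        d_p, f_p = _phase_means(record, 0, k)
        d_s, f_s = _phase_means(record, k, n)
        durations = {"cautious_peak": d_p, "cautious_steady": d_s}
        freqs = {"cautious_peak": f_p, "cautious_steady": f_s}
        levels = {"cautious_peak": before, "cautious_steady": after}
        phases = PhaseSummary(group=TIMID, t2=float(k), durations=durations,
                              frequencies=freqs, levels=levels)
    else:
        k1, g_cau_i, g_cau_s = fit_boxcar(record.pct_cautious)
        if k1 is None:
            raise ValueError("no cautious-to-confident transition found in cautious curve")
        if group == INTERMEDIATE:
            d_c, f_c = _phase_means(record, 0, k1)
            d_k, f_k = _phase_means(record, k1, n)
            durations = {"cautious": d_c, "confident": d_k}
            freqs = {"cautious": f_c, "confident": f_k}
            levels = {"cautious": g_cau_i, "confident": float(record.pct_confident[k1:].mean())}
            phases = PhaseSummary(group=INTERMEDIATE, t1=float(k1), durations=durations,
                                  frequencies=freqs, levels=levels)
        else:
            k2rel, g_con_p, g_con_s = fit_boxcar(record.pct_confident[k1:])
            if k2rel is None:
                raise ValueError("no peak-to-steady transition found in confident curve")
            k2 = k1 + k2rel
            d_c, f_c = _phase_means(record, 0, k1)
            d_p, f_p = _phase_means(record, k1, k2)
            d_s, f_s = _phase_means(record, k2, n)
            durations = {"cautious": d_c, "confident_peak": d_p, "confident_steady": d_s}
            freqs = {"cautious": f_c, "confident_peak": f_p, "confident_steady": f_s}
            levels = {"cautious": g_cau_i, "confident_peak": g_con_p, "confident_steady": g_con_s}
            phases = PhaseSummary(group=BRAVE, t1=float(k1), t2=float(k2),
                                  durations=durations, frequencies=freqs, levels=levels)
    return extract_statistics(phases), phases


# ---------------------------------------------------------------------------
# model statistics


def _first_nest_wait(traj: Trajectory, after_turn: int, bout_starts) -> int | None:
    """First turn from which the agent waits >1 consecutive turn at the nest.

    Only waits the agent actually returns from count: a trailing nest run at
    the session end is censoring, not a peak-to-steady transition.
    """
    run_start, run_len = None, 0
    for r in traj.records:
        if r.turn <= after_turn:
            continue
        if r.loc.name == "NEST":
            if run_len == 0:
                run_start = r.turn
            run_len += 1
            if run_len == 2 and any(s > run_start for s in bout_starts):
                return run_start
        else:
            run_len = 0
    return None


def _phase_stats(bouts, all_starts, sel) -> tuple[float | None, float | None]:
    """Mean duration (seconds) and frequency (bouts/min) over selected bouts.

    The phase frequency is the inverse mean start-to-start period between
    consecutive bouts of the phase; a phase holding a single bout falls back
    to that bout's period to its (global) successor, so sparse phases stay
    measurable.
    """
    chosen = [b for b in bouts if sel(b)]
    if not chosen:
        return None, None
    d = duration_to_seconds(float(np.mean([b.length for b in chosen])))
    starts = [b.start for b in chosen]
    if len(starts) >= 2:
        mean_period = float(np.mean(np.diff(starts)))
    else:
        later = [s for s in all_starts if s > starts[0]]
        if not later:
            return d, None
        mean_period = float(later[0] - starts[0])
    return d, TURNS_PER_MINUTE / mean_period  # bouts per minute


def model_statistics(traj: Trajectory) -> tuple[StatVector | None, PhaseSummary]:
    """Map a simulated trajectory into the shared statistic space.

    Group assignment is structural: confident bouts plus a post-transition
    slowdown make a brave run; confident bouts without one, an intermediate
    run; cautious-only runs with a slowdown, a timid run.  A run with no
    bouts, or without the phase structure its group requires (e.g. too few
    bouts to measure a per-phase frequency), is flagged degenerate --
    maximally timid, but unusable for fitting.
    """
    bouts = traj.bouts if traj.bouts else parse_bouts(traj)
    if bouts and traj.records and traj.records[-1].loc.name.endswith("OBJECT"):
        bouts = bouts[:-1]  # final bout censored by the session end
    if not bouts:
        return None, PhaseSummary(group=TIMID, degenerate=True)
    starts = [b.start for b in bouts]

    t1_turn = next((b.start for b in bouts if b.approach == CONFIDENT), None)
    first_end = bouts[0].start + bouts[0].length

    def finalize(group, t1, t2, durations, freqs):
        if any(v is None for v in durations.values()) or any(v is None for v in freqs.values()):
            return None, PhaseSummary(group=group, degenerate=True,
                                      t1=t1, t2=t2)
        phases = PhaseSummary(
            group=group,
            t1=None if t1 is None else turns_to_minutes(t1),
            t2=None if t2 is None else turns_to_minutes(t2),
            durations=durations,
            frequencies=freqs,
        )
        return extract_statistics(phases), phases

    if t1_turn is None:
        t2_turn = _first_nest_wait(traj, first_end, starts)
        if t2_turn is None:
            # single-phase cautious run: no transition to fit
            return None, PhaseSummary(group=TIMID, degenerate=True)
        d_p, f_p = _phase_stats(bouts, starts, lambda b: b.start < t2_turn)
        d_s, f_s = _phase_stats(bouts, starts, lambda b: b.start >= t2_turn)
        return finalize(
            TIMID, None, t2_turn,
            {"cautious_peak": d_p, "cautious_steady": d_s},
            {"cautious_peak": f_p, "cautious_steady": f_s},
        )

    t2_turn = _first_nest_wait(traj, t1_turn, starts)
    if t2_turn is None:
        d_c, f_c = _phase_stats(bouts, starts, lambda b: b.start < t1_turn)
        d_k, f_k = _phase_stats(bouts, starts, lambda b: b.start >= t1_turn)
        return finalize(
            INTERMEDIATE, t1_turn, None,
            {"cautious": d_c, "confident": d_k},
            {"cautious": f_c, "confident": f_k},
        )

    d_c, f_c = _phase_stats(bouts, starts, lambda b: b.start < t1_turn)
    d_p, f_p = _phase_stats(bouts, starts, lambda b: t1_turn <= b.start < t2_turn)
    d_s, f_s = _phase_stats(bouts, starts, lambda b: b.start >= t2_turn)
    return finalize(
        BRAVE, t1_turn, t2_turn,
        {"cautious": d_c, "confident_peak": d_p, "confident_steady": d_s},
        {"cautious": f_c, "confident_peak": f_p, "confident_steady": f_s},
    )
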