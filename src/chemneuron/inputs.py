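"""Stochastic bolus schedules: the neuron's input spike trains.

Each input spike is a *bolus*: at the spike time a reservoir of ``size``
precursor molecules is connected to the system and releases input molecules
at rate ``release_rate``.  Uncorrelated channels emit Poisson trains
(exponential waiting times with mean ``1/f_i``); temporally correlated
channels form a chain in which every leader event spawns a follower event
after a lag ``delta + xi`` with Gaussian jitter ``xi ~ N(0, jitter_var)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import InvalidSpecError

__all__ = [
    "BolusEvent",
    "TaskSpec",
    "InputSchedule",
    "generate_schedule",
    "make_fb_task",
    "make_tc_task",
]


@dataclass(frozen=True)
class BolusEvent:
    """A timed injection.

    Normally addressed by 1-based ``channel`` (the engine maps it to the
    channel's precursor species); ``species`` overrides the mapping to inject
    into an arbitrary named species (used e.g. for the periodic garbage-
    collector replenishment of the DNA circuit).  ``size`` is an integer
    molecule count in stochastic mode and may be fractional in concentration
    mode.
    """

    channel: int          # 1-based channel index (0 allowed with species=)
    time: float
    size: float
    release_rate: float
    species: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidSpecError("event time must be >= 0")
        if self.size <= 0:
            raise InvalidSpecError("bolus size must be > 0")
        if self.release_rate <= 0:
            raise InvalidSpecError("release_rate must be > 0")
        if self.species is None and self.channel < 1:
            raise InvalidSpecError("channel must be >= 1 (or set species=)")


@dataclass(frozen=True)
class TaskSpec:
    """Statistical description of an input-pattern task.

    ``correlation_chain`` lists channels whose events are chained in temporal
    order; all other channels (and the chain's first element) fire
    independently at their own frequency.
    """

    N: int
    frequencies: tuple[float, ...]
    correlation_chain: tuple[int, ...] = ()
    delta: float = 0.0
    jitter_var: float = 0.0
    horizon: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(self.frequencies))
        object.__setattr__(self, "correlation_chain",
                           tuple(self.correlation_chain))
        if len(self.frequencies) != self.N:
            raise InvalidSpecError("frequencies must have length N")
        if any(f <= 0 for f in self.frequencies):
            raise InvalidSpecError("frequencies must be > 0")
        chain = self.correlation_chain
        if len(set(chain)) != len(chain):
            raise InvalidSpecError("correlation_chain channels must be distinct")
        if any(c < 1 or c > self.N for c in chain):
            raise InvalidSpecError("correlation_chain channels must lie in 1..N")
        if len(chain) == 1:
            raise InvalidSpecError(
                "a single-element correlation chain is degenerate; use ()")
        if self.delta < 0 or self.jitter_var < 0:
            raise InvalidSpecError("delta and jitter_var must be >= 0")
        if self.horizon <= 0:
            raise InvalidSpecError("horizon must be > 0")


@dataclass
class InputSchedule:
    """A time-ordered realization of bolus events."""

    events: list[BolusEvent]
    task: TaskSpec | None = None

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            self.events = sorted(self.events, key=lambda e: (e.time, e.channel))

    def __len__(self) -> int:
        return len(self.events)

    def channel_times(self, channel: int) -> np.ndarray:
        return np.array([e.time for e in self.events if e.channel == channel])

    def shifted(self, offset: float) -> "InputSchedule":
        return InputSchedule(
            [replace(e, time=e.time + offset) for e in self.events], self.task)

    def concat(self, other: "InputSchedule") -> "InputSchedule":
        return InputSchedule(list(self.events) + list(other.events), self.task)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [e.time for e in self.events],
                "channel": [e.channel for e in self.events],
                "size": [e.size for e in self.events],
                "release_rate": [e.release_rate for e in self.events],
                "species": [e.species or "" for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InputSchedule":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        events = []
        for r in df.itertuples():
            species = getattr(r, "species", "") or None
            if isinstance(species, float):  # NaN from an empty cell
                species = None
            size = float(r.size)
            if size == int(size):
                size = int(size)
            events.append(BolusEvent(int(r.channel), float(r.time), size,
                                     float(r.release_rate), species))
        return cls(events)


def generate_schedule(task: TaskSpec, size: int, release_rate: float) -> InputSchedule:
    """Realize a task as a concrete schedule (deterministic given the seed).

    Follower events are generated per leader event with lag
    ``max(0, delta + xi)`` and dropped if they fall beyond the horizon.
    """
    rng = np.random.default_rng(task.seed)
    chain = task.correlation_chain
    followers = set(chain[1:])
    times: dict[int, np.ndarray] = {}
    # independent renewal trains (including the chain leader), drawn in
    # channel order so the realization is reproducible
    for ch in range(1, task.N + 1):
        if ch in followers:
            continue
        f = task.frequencies[ch - 1]
        n_guess = max(16, int(task.horizon * f * 1.5 + 10 * np.sqrt(task.horizon * f)))
        gaps = rng.exponential(1.0 / f, size=n_guess)
        t = np.cumsum(gaps)
        while t[-1] < task.horizon:
            extra = rng.exponential(1.0 / f, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        times[ch] = t[t <= task.horizon]
    # chained followers inherit the leader's renewal statistics
    for prev, ch in zip(chain, chain[1:]):
        lead = times[prev]
        if task.jitter_var > 0:
            xi = rng.normal(0.0, np.sqrt(task.jitter_var), size=lead.size)
        else:
            xi = np.zeros(lead.size)
        lag = np.maximum(0.0, task.delta + xi)
        t = lead + lag
        times[ch] = t[t <= task.horizon]
    events = [
        BolusEvent(ch, float(t), size, release_rate)
        for ch, ts in times.items()
        for t in ts
    ]
    events.sort(key=lambda e: (e.time, e.channel))
    return InputSchedule(events, task)


def make_fb_task(variant: int, f_high: float, f_low: float, N: int,
                 horizon: float = 1000.0, seed: int = 0) -> TaskSpec:
    """Frequency-bias task: the first ``variant`` channels fire at ``f_high``,
    the remaining ones at ``f_low``; no temporal correlations."""
    if not (1 <= variant < N):
        raise InvalidSpecError("FB variant must satisfy 1 <= variant < N")
    freqs = tuple(f_high if i < variant else f_low for i in range(N))
    return TaskSpec(N=N, frequencies=freqs, horizon=horizon, seed=seed)


def make_tc_task(variant: int, f: float, delta: float, jitter_var: float,
                 N: int, horizon: float = 1000.0, seed: int = 0) -> TaskSpec:
    """Temporal-correlation task: channels 1..variant form an ascending chain
    (1 leads, each next follows after ``delta`` + jitter); all channels fire
    at the same frequency ``f``."""
    if variant < 2:
        raise InvalidSpecError("TC variant must be >= 2 (a chain needs 2 channels)")
    if variant > N:
        raise InvalidSpecError("TC variant must be <= N")
    return TaskSpec(
        N=N,
        frequencies=tuple(f for _ in range(N)),
        correlation_chain=tuple(range(1, variant + 1)),
        delta=delta,
        jitter_var=jitter_var,
        horizon=horizon,
        seed=seed,
    )
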