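"""Simulation engine: exact SSA, deterministic ODE, and the Hill shortcut.

All three entry points take a :class:`~chemneuron.models.ReactionNetwork`
and an :class:`~chemneuron.inputs.InputSchedule` of timed boli and return a
:class:`Trajectory` sampled on a fixed grid.

The Hill shortcut replaces the explicit receptor chain by its quasi-steady
ultrasensitive response: reactions carrying a ``modifier`` use the virtual
catalyst abundance ``E_total * B**m / (theta**m + B**m)`` instead of an
explicit chain-state count.  This trades exactness of the chain kinetics for
speed while preserving the sigmoidal activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._kernels import run_ssa
from .inputs import InputSchedule
from .models import ReactionNetwork

__all__ = ["Trajectory", "HillParams", "simulate_ssa", "simulate_ode",
           "simulate_hill"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class HillParams:
    """Parameters of the quasi-steady activation response.

    The active-signal level used as catalyst abundance is
    ``e_total * B**m / (theta**m + B**m)``.
    """

    m: int
    theta: float
    e_total: float
    b_species: str = "B"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("Hill threshold theta must be > 0")
        if self.m < 1:
            raise ValueError("Hill cooperativity m must be >= 1")

    def active_fraction(self, b: float) -> float:
        b = float(b)
        if b <= 0:
            return 0.0
        # ratio form avoids overflow of b**m for steep exponents
        log_ratio = self.m * (np.log(self.theta) - np.log(b))
        if log_ratio > 700:
            return 0.0
        return 1.0 / (1.0 + np.exp(log_ratio))


@dataclass
class Trajectory:
    """Time-stamped species counts from a single simulation run."""

    times: np.ndarray
    counts: np.ndarray            # shape (len(times), n_species)
    species: list[str]
    mode: str
    seed: int | None = None
    grid: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.times) <= 0):
            raise SimulationError("trajectory times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def window(self, t0: float, t1: float) -> "Trajectory":
        sel = (self.times >= t0) & (self.times <= t1)
        if not np.any(sel):
            raise ValueError(f"window [{t0}, {t1}] outside trajectory")
        return Trajectory(self.times[sel], self.counts[sel], self.species,
                          self.mode, self.seed, self.grid)

    def time_average(self, name: str) -> float:
        return float(np.mean(self[name]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path, every: int = 1) -> None:
        self.to_frame().iloc[::every].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str = "csv") -> "Trajectory":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        times = df.pop("time").to_numpy()
        return cls(times, df.to_numpy(), list(df.columns), mode)


# ---------------------------------------------------------------------------
# network compilation
# ---------------------------------------------------------------------------

def _make_grid(horizon: float, grid: float) -> np.ndarray:
    if horizon <= 0 or grid <= 0:
        raise ValueError("horizon and grid must be > 0")
    n = int(round(horizon / grid))
    times = np.linspace(0.0, n * grid, n + 1)
    if times[-1] < horizon - 1e-12:
        times = np.append(times, horizon)
    times[-1] = horizon
    return times


def _compile(network: ReactionNetwork, hill: HillParams | None):
    network.validate()
    names = network.species_names()
    index = {n: i for i, n in enumerate(names)}
    n_r = len(network.reactions)
    n_s = len(names)
    rate = np.zeros(n_r)
    r1 = np.full(n_r, -1, dtype=np.int64)
    r2 = np.full(n_r, -1, dtype=np.int64)
    same = np.zeros(n_r, dtype=np.uint8)
    stoich = np.zeros((n_r, n_s), dtype=np.int64)
    hill_src = np.full(n_r, -1, dtype=np.int64)
    hill_m = np.ones(n_r)
    hill_theta = np.ones(n_r)
    hill_scale = np.ones(n_r)
    for k, r in enumerate(network.reactions):
        rate[k] = r.rate_constant
        if len(r.reactants) >= 1:
            r1[k] = index[r.reactants[0]]
        if len(r.reactants) == 2:
            if r.reactants[0] == r.reactants[1]:
                same[k] = 1
            else:
                r2[k] = index[r.reactants[1]]
        for sp in r.reactants:
            stoich[k, index[sp]] -= 1
        for sp in r.products:
            stoich[k, index[sp]] += 1
        if r.modifier is not None:
            if hill is None:
                raise SimulationError(
                    f"reaction {r.label!r} carries modifier {r.modifier!r}; "
                    "supply HillParams (use simulate_hill)")
            hill_src[k] = index[hill.b_species]
            hill_m[k] = float(hill.m)
            hill_theta[k] = hill.theta
            hill_scale[k] = hill.e_total
    return names, index, rate, r1, r2, same, stoich, hill_src, hill_m, \
        hill_theta, hill_scale


def _compile_events(network: ReactionNetwork, schedule: InputSchedule,
                    index: dict[str, int], precursor_prefix: str):
    ev_time, ev_sp, ev_size = [], [], []
    for e in schedule.events:
        name = e.species if e.species is not None else f"{precursor_prefix}{e.channel}"
        if name not in index:
            raise SimulationError(
                f"schedule event (channel {e.channel}) has no species "
                f"{name!r} in the network")
        ev_time.append(e.time)
        ev_sp.append(index[name])
        ev_size.append(e.size)
    order = np.argsort(np.asarray(ev_time, dtype=float), kind="stable")
    return (np.asarray(ev_time, dtype=float)[order],
            np.asarray(ev_sp, dtype=np.int64)[order],
            np.asarray(ev_size, dtype=float)[order])


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def simulate_ssa(network: ReactionNetwork, schedule: InputSchedule,
                 horizon: float, seed: int, grid: float,
                 hill: HillParams | None = None,
                 precursor_prefix: str = "I_",
                 use_numba: bool = True) -> Trajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Scheduled boli add ``size`` copies of the channel's precursor species
    atomically at the event time; the pending reaction time is redrawn, which
    preserves exactness of the algorithm.
    """
    (names, index, rate, r1, r2, same, stoich, hill_src, hill_m, hill_theta,
     hill_scale) = _compile(network, hill)
    ev_time, ev_sp, ev_size = _compile_events(network, schedule, index,
                                              precursor_prefix)
    times = _make_grid(horizon, grid)
    x0 = np.asarray(np.rint(network.initial_counts()), dtype=np.int64)
    if np.any(x0 < 0):
        raise SimulationError("negative initial counts")
    counts = run_ssa(x0, rate, r1, r2, same, stoich,
                     hill_src, hill_m, hill_theta, hill_scale,
                     ev_time, ev_sp,
                     np.asarray(np.rint(ev_size), dtype=np.int64), times,
                     int(seed) & 0x7FFFFFFF, use_numba=use_numba)
    mode = "ssa" if hill is None else "ssa-hill"
    return Trajectory(times, counts, names, mode, seed, grid)


def simulate_ode(network: ReactionNetwork, schedule: InputSchedule,
                 horizon: float, grid: float, rtol: float = 1e-6,
                 atol: float = 1e-9, hill: HillParams | None = None,
                 precursor_prefix: str = "I_") -> Trajectory:
    """Deterministic mass-action rate equations (fluid limit).

    Bolus events are state jumps; integration proceeds piecewise between
    event times with a stiff-capable integrator (LSODA).
    """
    (names, index, rate, r1, r2, same, stoich, hill_src, hill_m, hill_theta,
     hill_scale) = _compile(network, hill)
    ev_time, ev_sp, ev_size = _compile_events(network, schedule, index,
                                              precursor_prefix)
    times = _make_grid(horizon, grid)
    n_r = rate.shape[0]
    st = stoich.T.astype(float)

    def rhs(t, y):
        flux = rate.copy()
        for k in range(n_r):
            i1 = r1[k]
            if i1 >= 0:
                if same[k]:
                    flux[k] *= 0.5 * y[i1] * y[i1]
                else:
                    flux[k] *= y[i1]
                    i2 = r2[k]
                    if i2 >= 0:
                        flux[k] *= y[i2]
            h = hill_src[k]
            if h >= 0:
                b = max(y[h], 0.0)
                if b > 0:
                    flux[k] *= hill_scale[k] / (
                        1.0 + (hill_theta[k] / b) ** hill_m[k])
                else:
                    flux[k] = 0.0
        return st @ flux

    y = np.asarray(network.initial_counts(), dtype=float)
    out = np.zeros((times.size, y.size))
    eps = 1e-9 * max(1.0, horizon)
    # segment boundaries: event times in (0, horizon], plus the horizon
    bounds = sorted({float(t) for t in ev_time if 0.0 < t <= horizon} | {horizon})
    ei = 0
    n_e = ev_time.size
    while ei < n_e and ev_time[ei] <= 0.0:
        y[ev_sp[ei]] += ev_size[ei]
        ei += 1
    gi = 0
    if times[0] <= eps:  # grid origin reports the post-injection state
        out[0] = y
        gi = 1
    t0 = 0.0
    for t1 in bounds:
        interior = times[(times > t0 + eps) & (times < t1 - eps)]
        pts = np.concatenate([[t0], interior, [t1]])
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=pts,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(
                f"ODE integrator failed near t = {sol.t[-1] if sol.t.size else t0}"
                f": {sol.message}")
        ys = sol.y.T
        out[gi: gi + interior.size] = ys[1:-1]
        gi += interior.size
        y = ys[-1].copy()
        t0 = t1
        while ei < n_e and ev_time[ei] <= t1 + eps:
            y[ev_sp[ei]] += ev_size[ei]
            ei += 1
        # a grid point coinciding with the boundary reports the post-jump state
        if gi < times.size and abs(times[gi] - t1) <= eps:
            out[gi] = y
            gi += 1
    if gi < times.size:
        out[gi:] = y
    return Trajectory(times, np.maximum(out, 0.0), names, "ode", None, grid)


def simulate_hill(network: ReactionNetwork, schedule: InputSchedule,
                  hill: HillParams, horizon: float, seed: int, grid: float,
                  mode: str = "ssa", **kw) -> Trajectory:
    """Simulate a chain-free network with the Hill activation shortcut."""
    if mode == "ssa":
        return simulate_ssa(network, schedule, horizon, seed, grid,
                            hill=hill, **kw)
    if mode == "ode":
        return simulate_ode(network, schedule, horizon, grid, hill=hill, **kw)
    raise ValueError("mode must be 'ssa' or 'ode'")
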