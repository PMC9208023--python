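"""Learning statistics and sweep protocols.

The neuron's interpretable output is the vector of steady-state weights
``H_1..H_N``.  This module computes their time averages, the normalized
weight profile, and the *index of dispersion* (standard deviation divided by
mean — the coefficient of variation across channels), which measures how
strongly the neuron discriminates between input channels; plus the protocol
drivers for coincidence-window, bolus-size and nonlinearity sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import Trajectory, simulate_ssa
from .inputs import BolusEvent, InputSchedule, TaskSpec, generate_schedule
from .models import NeuronSpec, build_cn

__all__ = [
    "WeightSummary",
    "steady_state_weights",
    "index_of_dispersion",
    "DifferentialWeightResult",
    "differential_weight_fraction",
    "dispersion_sweep",
    "bolus_size_sweep",
    "RelearningReport",
    "relearning_check",
    "fit_hill_exponent",
    "chain_occupancy_curve",
]


def index_of_dispersion(weights) -> float:
    """Population standard deviation of the weights divided by their mean."""
    w = np.asarray(weights, dtype=float)
    mu = w.mean()
    if mu <= 0:
        return float("nan")
    return float(w.std() / mu)


@dataclass
class WeightSummary:
    """Time-averaged steady-state weights of one trajectory."""

    raw: np.ndarray
    normalized: np.ndarray
    dispersion: float
    transient: float
    window: float
    channels: list[str] = field(default_factory=list)
    degenerate: bool = False

    def ordering(self) -> tuple[int, ...]:
        """Channel indices (1-based) sorted by decreasing raw weight."""
        return tuple(int(i) + 1 for i in np.argsort(-self.raw, kind="stable"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channels or list(range(1, len(self.raw) + 1)),
            "raw": self.raw,
            "normalized": self.normalized,
        })


def steady_state_weights(traj: Trajectory, transient: float = 700.0,
                         window: float = 300.0,
                         prefix: str = "H_") -> WeightSummary:
    """Average the weight species over ``[transient, transient + window]``.

    The defaults discard a 700-time-unit burn-in and average over the
    following 300 time units.  If all averaged weights are zero the summary
    is flagged degenerate (normalized profile and dispersion undefined).
    """
    if transient < 0 or window <= 0:
        raise ValueError("transient must be >= 0 and window > 0")
    if transient + window > traj.times[-1] + 1e-9:
        raise ValueError(
            f"window [{transient}, {transient + window}] extends beyond the "
            f"trajectory horizon {traj.times[-1]}")
    names = sorted((n for n in traj.species if n.startswith(prefix)),
                   key=lambda n: int(n[len(prefix):].split("_")[0]))
    if not names:
        raise ValueError(f"no weight species with prefix {prefix!r}")
    win = traj.window(transient, transient + window)
    raw = np.array([win.time_average(n) for n in names])
    total = raw.sum()
    if total > 0:
        normalized = raw / total
        dispersion = index_of_dispersion(raw)
        degenerate = False
    else:
        normalized = np.full_like(raw, np.nan)
        dispersion = float("nan")
        degenerate = True
    return WeightSummary(raw, normalized, dispersion, transient, window,
                         channels=names, degenerate=degenerate)


# ---------------------------------------------------------------------------
# coincidence-window protocol
# ---------------------------------------------------------------------------

@dataclass
class DifferentialWeightResult:
    """Mean share of the weight update received by the follower channel."""

    fraction: float
    n_used: int
    n_excluded: int
    delta: float

    def __float__(self) -> float:
        return self.fraction


def differential_weight_fraction(spec: NeuronSpec, delta: float, reps: int,
                                 seed: int, tail: float = 0.2,
                                 grid: float = 0.01) -> DifferentialWeightResult:
    """Two-bolus coincidence protocol.

    Both weights start at zero; channel 1 receives a bolus at t = 0 and
    channel 2 one at t = ``delta``; the run continues for another ``tail``
    time units.  Returns the mean over replicates of
    ``dH_2 / (dH_1 + dH_2)``; replicates in which neither weight increased
    are excluded (their count is reported).
    """
    if spec.N != 2:
        raise ValueError("the coincidence protocol requires N = 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    s = spec.with_(H_init=(0, 0))
    net = build_cn(s)
    horizon = delta + tail
    events = [BolusEvent(1, 0.0, s.beta, s.kappa),
              BolusEvent(2, delta, s.beta, s.kappa)]
    sched = InputSchedule(events)
    rng = np.random.default_rng(seed)
    fracs = []
    n_excluded = 0
    for _ in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        traj = simulate_ssa(net, sched, horizon, rep_seed, grid)
        dh1 = float(traj["H_1"][-1])
        dh2 = float(traj["H_2"][-1])
        total = dh1 + dh2
        if total <= 0:
            n_excluded += 1
            continue
        fracs.append(dh2 / total)
    if not fracs:
        raise RuntimeError(
            "differential weight fraction undefined: no replicate showed a "
            "weight increase")
    return DifferentialWeightResult(float(np.mean(fracs)), len(fracs),
                                    n_excluded, delta)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def dispersion_sweep(task: TaskSpec, m_values, beta_values, reps: int,
                     seed: int, spec: NeuronSpec | None = None,
                     transient: float = 700.0, window: float = 300.0,
                     grid: float = 0.1) -> pd.DataFrame:
    """Index of dispersion over a (m, bolus-size) grid.

    For each grid point the neuron is rebuilt, the task re-realized and
    simulated ``reps`` times.  Returns a tidy frame with one row per
    replicate (columns m, beta, rep, dispersion, mean_weight and the raw
    weights); aggregate with :func:`summarize_dispersion`.
    """
    m_values = list(m_values)
    beta_values = list(beta_values)
    if not m_values or not beta_values:
        raise ValueError("empty sweep grid")
    if spec is None:
        from .models import default_spec
        spec = default_spec(N=task.N)
    rng = np.random.default_rng(seed)
    rows = []
    for m in m_values:
        for beta in beta_values:
            s = spec.with_(m=int(m), beta=int(beta))
            net = build_cn(s)
            for rep in range(reps):
                rs = int(rng.integers(0, 2**31 - 1))
                t = TaskSpec(task.N, task.frequencies, task.correlation_chain,
                             task.delta, task.jitter_var, task.horizon, rs)
                sched = generate_schedule(t, s.beta, s.kappa)
                traj = simulate_ssa(net, sched, task.horizon, rs, grid)
                summ = steady_state_weights(traj, transient, window)
                rows.append({
                    "m": int(m), "beta": int(beta), "rep": rep,
                    "dispersion": summ.dispersion,
                    "mean_weight": float(summ.raw.mean()),
                    **{f"H_{i + 1}": w for i, w in enumerate(summ.raw)},
                })
    return pd.DataFrame(rows)


def summarize_dispersion(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a dispersion sweep per (m, beta) grid point.

    Reports the mean per-replicate dispersion, the dispersion of the
    replicate-mean weights, and a noise-corrected dispersion in which the
    sampling variance of the replicate means (estimated from the
    between-replicate spread) is subtracted from the between-channel
    variance.  The corrected statistic estimates the *systematic* channel
    discrimination and approaches zero for statistically identical channels
    even when the weights themselves are small and noisy.
    """
    n_ch = len([c for c in table.columns if c.startswith("H_")])
    cols = [f"H_{i + 1}" for i in range(n_ch)]
    out = []
    for (m, beta), g in table.groupby(["m", "beta"]):
        h = g[cols].to_numpy()              # reps x channels
        hbar = h.mean(axis=0)
        mu = hbar.mean()
        if mu > 0:
            between = hbar.var()
            n_rep = h.shape[0]
            sampling = (h.var(axis=0, ddof=1).mean() / n_rep
                        if n_rep > 1 else 0.0)
            corrected = float(np.sqrt(max(0.0, between - sampling)) / mu)
        else:
            corrected = 0.0
        out.append({
            "m": m, "beta": beta,
            "mean_dispersion": float(g["dispersion"].mean()),
            "dispersion_of_mean": index_of_dispersion(hbar),
            "corrected_dispersion": corrected,
            "mean_weight": float(mu),
        })
    return pd.DataFrame(out)


def bolus_size_sweep(spec: NeuronSpec, beta_values, reps: int, seed: int,
                     f_corr: float = 2.0, f_free: float = 4.0,
                     delta: float = 0.0047, jitter_var: float = 0.0001,
                     horizon: float = 1000.0, transient: float = 700.0,
                     window: float = 300.0, grid: float = 0.1) -> pd.DataFrame:
    """Steady-state weights versus bolus size for the three-input scenario:
    channels 1 and 2 temporally correlated at ``f_corr``, channel 3
    uncorrelated at twice that rate.

    Returns one row per (beta, rep) with raw and normalized weights.
    """
    beta_values = list(beta_values)
    if not beta_values:
        raise ValueError("empty beta grid")
    if spec.N != 3:
        spec = spec.with_(N=3)
    rng = np.random.default_rng(seed)
    rows = []
    for beta in beta_values:
        s = spec.with_(beta=int(beta))
        net = build_cn(s)
        for rep in range(reps):
            rs = int(rng.integers(0, 2**31 - 1))
            task = TaskSpec(3, (f_corr, f_corr, f_free), (1, 2), delta,
                            jitter_var, horizon, rs)
            sched = generate_schedule(task, s.beta, s.kappa)
            traj = simulate_ssa(net, sched, horizon, rs, grid)
            summ = steady_state_weights(traj, transient, window)
            row = {"beta": int(beta), "rep": rep,
                   "degenerate": summ.degenerate}
            for i in range(3):
                row[f"H_{i + 1}"] = summ.raw[i]
                row[f"w_{i + 1}"] = summ.normalized[i]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relearning
# ---------------------------------------------------------------------------

@dataclass
class RelearningReport:
    before: WeightSummary
    after: WeightSummary

    @property
    def ordering_before(self) -> tuple[int, ...]:
        return self.before.ordering()

    @property
    def ordering_after(self) -> tuple[int, ...]:
        return self.after.ordering()


def relearning_check(spec: NeuronSpec, task_before: TaskSpec,
                     task_after: TaskSpec, seed: int,
                     transient: float = 700.0, window: float = 300.0,
                     grid: float = 0.1) -> RelearningReport:
    """Train on one task, switch to another, and report the steady-state
    weight profiles of both epochs (forgetting / unlearning audit)."""
    if task_before.N != spec.N or task_after.N != spec.N:
        raise ValueError("task channel counts must match the neuron spec")
    net = build_cn(spec)
    sched1 = generate_schedule(
        TaskSpec(task_before.N, task_before.frequencies,
                 task_before.correlation_chain, task_before.delta,
                 task_before.jitter_var, task_before.horizon, seed),
        spec.beta, spec.kappa)
    sched2 = generate_schedule(
        TaskSpec(task_after.N, task_after.frequencies,
                 task_after.correlation_chain, task_after.delta,
                 task_after.jitter_var, task_after.horizon, seed + 1),
        spec.beta, spec.kappa)
    full = sched1.concat(sched2.shifted(task_before.horizon))
    horizon = task_before.horizon + task_after.horizon
    traj = simulate_ssa(net, full, horizon, seed, grid)
    before = steady_state_weights(traj, transient, window)
    after = steady_state_weights(
        traj, task_before.horizon + transient, window)
    return RelearningReport(before, after)


# ---------------------------------------------------------------------------
# activation-function analysis
# ---------------------------------------------------------------------------

def chain_occupancy_curve(m: int, k_plus: float, k_minus: float, rho: float,
                          b_levels) -> np.ndarray:
    """Equilibrium probability of the fully occupied chain state at clamped B.

    The ladder C_0 <-> ... <-> C_m with per-step ratio phi = k_plus*B/k_minus
    (final step slowed by rho) has stationary weights w_j = phi^j for j < m
    and w_m = phi^m / rho; the returned curve is w_m normalized by their sum.
    """
    b = np.asarray(b_levels, dtype=float)
    phi = k_plus * b / k_minus
    with np.errstate(divide="ignore", invalid="ignore"):
        num = phi ** m / rho
        den = num + sum(phi ** j for j in range(m))
        p = np.where(den > 0, num / den, 0.0)
    return p


def fit_hill_exponent(b_levels, active_fraction) -> float:
    """Least-squares Hill fit ``f(B) = A * B^n / (K^n + B^n)``; returns n.

    Emits a warning (and still fits) if the curve is not monotone
    non-decreasing.
    """
    b = np.asarray(b_levels, dtype=float)
    f = np.asarray(active_fraction, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 points spanning the threshold")
    if np.any(np.diff(f) < -1e-9 * max(1.0, np.max(np.abs(f)))):
        warnings.warn("activation curve is not monotone; Hill fit may be poor")

    def hill(x, amp, n, k):
        return amp * x ** n / (k ** n + x ** n)

    k0 = float(b[np.argmin(np.abs(f - 0.5 * f.max()))]) or float(np.median(b))
    amp0 = float(max(f.max(), 1e-9))
    popt, _ = curve_fit(hill, b, f, p0=(amp0, 1.5, k0),
                        bounds=([1e-12, 0.05, 1e-12],
                                [np.inf, 50.0, np.inf]),
                        maxfev=20000)
    return float(popt[1])
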