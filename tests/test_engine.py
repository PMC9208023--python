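"""Engine correctness: analytic oracles, conservation, reproducibility."""

import numpy as np
import pytest

from chemneuron import (
    BolusEvent, HillParams, InputSchedule, Reaction, ReactionNetwork, Species,
    build_cn, default_spec, generate_schedule, make_fb_task,
    simulate_hill, simulate_ode, simulate_ssa,
)
from chemneuron.engine import SimulationError


def decay_network(n0=1000, d=2.0):
    return ReactionNetwork(
        species=[Species("A", initial_count=n0), Species("I_1")],
        reactions=[Reaction(("A",), (), d, "decay"),
                   Reaction(("I_1",), ("A",), 100.0, "release")],
    )


EMPTY_SCHEDULE = InputSchedule([])


def test_ssa_matches_exponential_decay_law():
    """Replicate mean of A(t) tracks 1000*exp(-d t) within 3 standard errors."""
    net = decay_network(n0=1000, d=2.0)
    reps = 300
    t_check = 0.5
    finals = []
    for seed in range(reps):
        traj = simulate_ssa(net, EMPTY_SCHEDULE, t_check, seed, 0.25)
        finals.append(traj["A"][-1])
    finals = np.asarray(finals, dtype=float)
    p = np.exp(-2.0 * t_check)
    expected = 1000 * p
    se = np.sqrt(1000 * p * (1 - p) / reps)
    assert abs(finals.mean() - expected) <= 3 * se


def test_ssa_bolus_steps_counts_exactly():
    """With no reactions, a bolus is a pure step in the precursor count."""
    net = ReactionNetwork(species=[Species("I_1")])
    sched = InputSchedule([BolusEvent(1, 0.5, 77, 100.0)])
    traj = simulate_ssa(net, sched, 1.0, 1, 0.1)
    i_series = traj["I_1"]
    assert np.all(i_series[traj.times < 0.5] == 0)
    assert np.all(i_series[traj.times >= 0.5] == 77)


def test_ssa_reproducible_given_seed():
    spec = default_spec(N=2, m=2)
    net = build_cn(spec)
    task = make_fb_task(1, 4.0, 2.0, 2, horizon=20.0, seed=9)
    sched = generate_schedule(task, spec.beta, spec.kappa)
    t1 = simulate_ssa(net, sched, 20.0, 123, 0.1)
    t2 = simulate_ssa(net, sched, 20.0, 123, 0.1)
    assert np.array_equal(t1.counts, t2.counts)
    t3 = simulate_ssa(net, sched, 20.0, 124, 0.1)
    assert not np.array_equal(t1.counts, t3.counts)


def test_chain_conservation_exact_in_ssa():
    """Sum of chain states equals E_total at every recorded sample."""
    spec = default_spec(N=2, m=3)
    net = build_cn(spec)
    task = make_fb_task(1, 4.0, 2.0, 2, horizon=50.0, seed=4)
    sched = generate_schedule(task, spec.beta, spec.kappa)
    traj = simulate_ssa(net, sched, 50.0, 7, 0.05)
    total = sum(traj[f"C_{j}"] for j in range(spec.m + 1))
    assert np.all(total == spec.E_total)


def test_weight_rises_only_after_learning_signal():
    """Single-bolus protocol: H increases only once C_m has been occupied."""
    spec = default_spec(N=1, m=1, H_init=(100,))
    net = build_cn(spec)
    sched = InputSchedule([BolusEvent(1, 0.015, spec.beta, spec.kappa)])
    traj = simulate_ssa(net, sched, 0.4, 11, 0.001)
    h = traj["H_1"].astype(float)
    cm = traj[f"C_{spec.m}"]
    rise = np.nonzero(h > h[0])[0]
    first_active = np.nonzero(cm > 0)[0]
    assert rise.size > 0, "calibrated defaults must trigger learning"
    assert first_active.size > 0
    assert first_active[0] <= rise[0]


def test_ode_closed_form_decay():
    net = decay_network(n0=1000, d=2.0)
    traj = simulate_ode(net, EMPTY_SCHEDULE, 2.0, 0.1, rtol=1e-8)
    expected = 1000 * np.exp(-2.0 * traj.times)
    np.testing.assert_allclose(traj["A"], expected, rtol=1e-5, atol=1e-6)


def test_ode_zero_rate_constant_solution():
    net = ReactionNetwork(species=[Species("X", initial_count=42)],
                          reactions=[Reaction(("X",), (), 0.0, "noop")])
    traj = simulate_ode(net, EMPTY_SCHEDULE, 5.0, 0.5)
    np.testing.assert_allclose(traj["X"], 42.0, rtol=1e-9)


def test_ode_bolus_jump():
    net = ReactionNetwork(species=[Species("I_1")])
    sched = InputSchedule([BolusEvent(1, 1.0, 10, 100.0)])
    traj = simulate_ode(net, sched, 2.0, 0.25)
    assert traj["I_1"][traj.times < 1.0].max() == 0
    np.testing.assert_allclose(traj["I_1"][traj.times >= 1.0], 10.0)


def test_fluid_limit_consistency():
    """At x100 copy numbers the SSA replicate mean of B matches the ODE."""
    spec = default_spec(N=1, m=1, beta=5000, E_total=4000,
                        H_init=(10000,))
    net = build_cn(spec)
    sched = InputSchedule([BolusEvent(1, 0.1, spec.beta, spec.kappa)])
    horizon, grid = 0.6, 0.05
    ode = simulate_ode(net, sched, horizon, grid)
    runs = np.array([simulate_ssa(net, sched, horizon, s, grid)["B"]
                     for s in range(20)], dtype=float)
    mean_b = runs.mean(axis=0)
    se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
    mask = ode["B"] > 50  # compare where the signal is nontrivial
    assert mask.sum() >= 3
    diff = np.abs(mean_b - ode["B"])[mask]
    # 4 SE + 2% mean-field tolerance for finite-size corrections
    bound = (4 * se + 0.02 * ode["B"])[mask]
    assert np.all(diff <= bound)


def test_hill_midpoint_and_step_limit():
    hp = HillParams(m=1, theta=100.0, e_total=40)
    assert hp.active_fraction(100.0) == pytest.approx(0.5)
    steep = HillParams(m=200, theta=100.0, e_total=40)
    assert steep.active_fraction(80.0) < 1e-6
    assert steep.active_fraction(125.0) > 1 - 1e-6
    with pytest.raises(ValueError):
        HillParams(m=1, theta=0.0, e_total=40)


def test_hill_shortcut_matches_chain_ordering():
    """Full-chain SSA and the Hill shortcut agree on FB weight ordering."""
    spec = default_spec(N=3, m=1)
    task = make_fb_task(1, 6.0, 2.0, 3, horizon=300.0, seed=21)
    sched = generate_schedule(task, spec.beta, spec.kappa)
    chain_net = build_cn(spec)
    hill_net = build_cn(spec, activation="hill")
    hp = HillParams(spec.m, spec.threshold, spec.E_total)
    t_chain = simulate_ssa(chain_net, sched, 300.0, 3, 0.1)
    t_hill = simulate_hill(hill_net, sched, hp, 300.0, 3, 0.1)
    sel = t_chain.times >= 150.0

    def weights(traj):
        return np.array([traj[f"H_{i}"][sel].mean() for i in (1, 2, 3)])

    w_c, w_h = weights(t_chain), weights(t_hill)
    assert w_c.argmax() == 0 and w_h.argmax() == 0


def test_hill_network_requires_hill_params():
    net = build_cn(default_spec(N=1, m=1), activation="hill")
    with pytest.raises(SimulationError):
        simulate_ssa(net, EMPTY_SCHEDULE, 1.0, 1, 0.1)


def test_unknown_channel_in_schedule_errors():
    net = decay_network()
    sched = InputSchedule([BolusEvent(9, 0.1, 10, 100.0)])
    with pytest.raises(SimulationError):
        simulate_ssa(net, sched, 1.0, 1, 0.1)


def test_python_kernel_agrees_with_numba_on_determinism():
    """The pure-Python fallback implements the same algorithm contract."""
    net = decay_network(n0=50, d=1.0)
    t1 = simulate_ssa(net, EMPTY_SCHEDULE, 1.0, 5, 0.1, use_numba=False)
    t2 = simulate_ssa(net, EMPTY_SCHEDULE, 1.0, 5, 0.1, use_numba=False)
    assert np.array_equal(t1.counts, t2.counts)
    assert t1.counts[-1, 0] <= 50


def test_ccn_compartment_conservation_and_learning():
    """Each compartment's receptor chain is conserved, and the faster-firing
    compartment accumulates more transporter H."""
    from chemneuron import build_ccn

    spec = default_spec(N=2, m=2)
    net = build_ccn(spec)
    task = make_fb_task(1, 4.0, 2.0, 2, horizon=100.0, seed=1)
    sched = generate_schedule(task, spec.beta, spec.kappa)
    traj = simulate_ssa(net, sched, 100.0, 5, 0.1)
    for i in (1, 2):
        total = sum(traj[f"C_{j}_{i}"] for j in range(spec.m + 1))
        assert np.all(total == spec.E_total)
    sel = traj.times >= 50.0
    h1 = traj["H_1"][sel].mean()
    h2 = traj["H_2"][sel].mean()
    assert h1 > h2
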