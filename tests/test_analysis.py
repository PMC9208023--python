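"""Weight statistics, coincidence protocol, Hill-exponent fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemneuron import Trajectory, default_spec
from chemneuron.analysis import (
    DifferentialWeightResult, chain_occupancy_curve,
    differential_weight_fraction, fit_hill_exponent, index_of_dispersion,
    steady_state_weights, summarize_dispersion,
)


def constant_traj(values, horizon=1000.0, grid=10.0):
    times = np.arange(0.0, horizon + grid / 2, grid)
    counts = np.tile(values, (times.size, 1))
    species = [f"H_{i + 1}" for i in range(len(values))]
    return Trajectory(times, counts, species, "ssa", 0, grid)


def test_constant_weights_summary():
    traj = constant_traj([10, 10, 10, 10, 10])
    summ = steady_state_weights(traj, 700.0, 300.0)
    np.testing.assert_allclose(summ.normalized, 0.2)
    assert summ.dispersion == pytest.approx(0.0)
    assert not summ.degenerate


def test_dispersion_two_zero_arithmetic():
    """H = (2, 0): population std / mean = 1/1 = 1."""
    traj = constant_traj([2, 0])
    summ = steady_state_weights(traj, 700.0, 300.0)
    assert summ.dispersion == pytest.approx(1.0)
    np.testing.assert_allclose(summ.normalized, [1.0, 0.0])


def test_degenerate_all_zero_weights():
    traj = constant_traj([0, 0, 0])
    summ = steady_state_weights(traj, 700.0, 300.0)
    assert summ.degenerate
    assert np.isnan(summ.dispersion)


def test_window_outside_trajectory_errors():
    traj = constant_traj([1, 2], horizon=100.0, grid=1.0)
    with pytest.raises(ValueError):
        steady_state_weights(traj, 700.0, 300.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=8),
       st.floats(0.01, 100.0))
def test_dispersion_scale_invariant(weights, c):
    w = np.asarray(weights)
    d1 = index_of_dispersion(w)
    d2 = index_of_dispersion(c * w)
    assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=8).filter(
    lambda w: sum(w) > 0))
def test_normalized_weights_sum_to_one(weights):
    summ = steady_state_weights(constant_traj(weights), 700.0, 300.0)
    assert summ.normalized.sum() == pytest.approx(1.0)


def test_symmetric_simultaneous_boli_split_evenly():
    """Zero lag with symmetric channels: follower fraction ~ 0.5."""
    spec = default_spec(N=2, m=1)
    res = differential_weight_fraction(spec, delta=0.0, reps=400, seed=5)
    assert isinstance(res, DifferentialWeightResult)
    assert res.fraction == pytest.approx(0.5, abs=0.05)


def test_forced_follower_only_update():
    """With learning disabled on channel 1, the fraction is exactly 1."""
    from chemneuron.models import Reaction, build_cn
    from chemneuron.inputs import BolusEvent, InputSchedule
    from chemneuron.engine import simulate_ssa

    spec = default_spec(N=2, m=1)
    net = build_cn(spec)
    net.reactions = [
        r if r.label != "learn_1" else Reaction(r.reactants, r.products, 0.0,
                                                r.label)
        for r in net.reactions
    ]
    sched = InputSchedule([BolusEvent(1, 0.0, spec.beta, spec.kappa),
                           BolusEvent(2, 0.0, spec.beta, spec.kappa)])
    fracs = []
    for seed in range(40):
        traj = simulate_ssa(net, sched, 0.2, seed, 0.01)
        dh1, dh2 = traj["H_1"][-1], traj["H_2"][-1]
        if dh1 + dh2 > 0:
            fracs.append(dh2 / (dh1 + dh2))
    assert fracs and all(f == 1.0 for f in fracs)


def test_large_lag_high_nonlinearity_symmetric():
    """Boli far outside the coincidence window update weights evenly for
    m > 1 (no differential update)."""
    spec = default_spec(N=2, m=4)
    res = differential_weight_fraction(spec, delta=0.5, reps=400, seed=17)
    assert res.fraction == pytest.approx(0.5, abs=0.07)


def test_fit_hill_exponent_self_consistency():
    b = np.linspace(1, 400, 40)
    f = b ** 2 / (100.0 ** 2 + b ** 2)
    assert fit_hill_exponent(b, f) == pytest.approx(2.0, abs=0.05)


def test_fit_hill_warns_on_nonmonotone():
    b = np.array([1.0, 10.0, 20.0, 50.0, 100.0])
    f = np.array([0.0, 0.4, 0.2, 0.6, 0.9])
    with pytest.warns(UserWarning):
        fit_hill_exponent(b, f)


def test_chain_occupancy_noncooperative_m1():
    """With rho = 1, m = 1 the occupancy is B / (B + k_minus/k_plus)."""
    b = np.linspace(1, 500, 30)
    occ = chain_occupancy_curve(1, 10.0, 1000.0, 1.0, b)
    np.testing.assert_allclose(occ, b / (b + 100.0), rtol=1e-12)
    n = fit_hill_exponent(b, occ)
    assert n == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize("m", [1, 2, 3, 4])
def test_hill_exponent_bounded_by_chain_length(m):
    """The fitted Hill exponent of the equilibrium occupancy never exceeds m."""
    theta = 100.0
    b = np.geomspace(theta / 30, theta * 30, 60)
    occ = chain_occupancy_curve(m, 10.0, 10.0 * theta, 0.01, b)
    n = fit_hill_exponent(b, occ)
    assert n <= m + 0.1
    if m > 1:
        assert n > 1.0  # cooperativity steepens the curve


def test_summarize_dispersion_unbiased_corrected_near_zero():
    """Statistically identical replicated channels: the corrected dispersion
    collapses toward zero even when each replicate is noisy."""
    import pandas as pd

    rng = np.random.default_rng(0)
    rows = []
    for rep in range(12):
        w = rng.normal(100.0, 10.0, size=5)
        rows.append({"m": 1, "beta": 50, "rep": rep,
                     "dispersion": index_of_dispersion(w),
                     **{f"H_{i + 1}": w[i] for i in range(5)}})
    summ = summarize_dispersion(pd.DataFrame(rows))
    assert summ["mean_dispersion"].iloc[0] > 0.05      # raw statistic noisy
    assert summ["corrected_dispersion"].iloc[0] < 0.05  # corrected ~ 0


def test_relearning_flips_ordering():
    """Reversing the frequency bias reverses the learned weight ordering;
    the neuron forgets and re-learns without intervention."""
    from chemneuron.analysis import relearning_check
    from chemneuron.inputs import TaskSpec

    spec = default_spec(N=2, m=1)
    fast_first = TaskSpec(N=2, frequencies=(4.0, 2.0), horizon=1000.0)
    fast_second = TaskSpec(N=2, frequencies=(2.0, 4.0), horizon=1000.0)
    report = relearning_check(spec, fast_first, fast_second, seed=8)
    assert report.before.raw[0] > report.before.raw[1]
    assert report.after.raw[0] < report.after.raw[1]
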