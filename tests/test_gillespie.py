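"""Direct-method stochastic simulation: propensities, sampling, ensembles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aggfrag import (
    KernelModel,
    SystemState,
    blatz_tobolsky_kernel,
    constant_kernel,
    draw_waiting_time,
    ensemble_average,
    propensities,
    sample_on_grid,
    select_reaction,
    simulate_ensemble,
    simulate_observable_counts,
    simulate_trajectory,
)
from aggfrag.gillespie import ChannelTable, spawn_rngs
from aggfrag.kernels import iter_channels


def _state(N, **counts):
    n = np.zeros(N + 1, dtype=np.int64)
    for size, cnt in counts.items():
        n[int(size)] = cnt
    return SystemState(n=n)


def _channel_index(N, kind, pair):
    channels = list(iter_channels(N))
    k = channels.index(pair)
    return k if kind == "agg" else k + len(channels)


def test_propensity_pair_counting():
    k = 1.7
    m = constant_kernel(k, 5)
    # five monomers: n(n-1)/2 identical pairs
    a = propensities(_state(5, **{"1": 5}), m, V=1.0)
    assert a[_channel_index(5, "agg", (1, 1))] == pytest.approx(k * 5 * 4 / 2)
    # mixed pair: n_1 n_2
    a = propensities(_state(5, **{"1": 2, "2": 1}), m, V=1.0)
    assert a[_channel_index(5, "agg", (1, 2))] == pytest.approx(2 * k)
    # a lone monomer can do nothing
    a = propensities(_state(5, **{"1": 1}), m, V=1.0)
    assert np.all(a == 0.0)


def test_fragmentation_propensity_counts_clusters():
    f_b = 0.9
    m = KernelModel(
        "custom",
        {},
        K=lambda i, j: 0.0,
        F=lambda i, j: f_b if (i, j) in ((1, 3), (3, 1)) else 0.0,
        max_size=4,
    )
    a = propensities(_state(4, **{"4": 2}), m, V=1.0)
    assert a[_channel_index(4, "frag", (1, 3))] == pytest.approx(2 * f_b)


def test_waiting_time_closed_form():
    assert draw_waiting_time(2.0, math.exp(-2.0)) == pytest.approx(1.0)
    assert draw_waiting_time(1.0, 0.5) == pytest.approx(math.log(2.0))
    with pytest.raises(ValueError):
        draw_waiting_time(0.0, 0.5)
    with pytest.raises(ValueError):
        draw_waiting_time(1.0, 1.5)


def test_waiting_time_exponential_law():
    rng = np.random.default_rng(5)
    a_tot = 4.0
    taus = np.array(
        [draw_waiting_time(a_tot, 1.0 - rng.random()) for _ in range(100_000)]
    )
    se = taus.std(ddof=1) / math.sqrt(len(taus))
    assert abs(taus.mean() - 0.25) < 3 * se


def test_select_reaction_smallest_index_rule():
    rates = np.array([1.0, 3.0])
    assert select_reaction(rates, 0.2) == 0  # 0.8 <= 1
    assert select_reaction(rates, 0.5) == 1  # 2.0 > 1
    with pytest.raises(ValueError):
        select_reaction(np.zeros(3), 0.5)


def test_select_reaction_frequencies_multinomial():
    rng = np.random.default_rng(11)
    rates = np.array([0.5, 1.5, 2.0])
    draws = np.array(
        [select_reaction(rates, rng.random()) for _ in range(100_000)]
    )
    for k, p in enumerate(rates / rates.sum()):
        freq = np.mean(draws == k)
        se = math.sqrt(p * (1 - p) / len(draws))
        assert abs(freq - p) < 3 * se


def test_trajectory_determinism_and_mass_conservation():
    m = blatz_tobolsky_kernel(1.0, 1.0, 8)
    t1 = simulate_trajectory(8, 8.0, m, t_max=5.0, seed=3)
    t2 = simulate_trajectory(8, 8.0, m, t_max=5.0, seed=3)
    assert np.array_equal(t1.times, t2.times)
    assert np.array_equal(t1.states, t2.states)
    sizes = np.arange(9)
    assert np.all(t1.states @ sizes == 8)


def test_irreversible_endpoint_absorbs():
    m = constant_kernel(1.0, 6)
    traj = simulate_trajectory(6, 1.0, m, t_max=200.0, seed=0)
    assert traj.frozen
    final = traj.states[-1]
    assert final[6] == 1 and final[1:6].sum() == 0
    # cluster count strictly decreases event by event
    totals = traj.states.sum(axis=1)
    assert np.all(np.diff(totals) == -1)


def test_two_monomer_waiting_time_matches_rate():
    """For N=2 the single aggregation fires at rate K*2*1/2 = k_f."""
    k = 2.0
    m = constant_kernel(k, 2)
    waits = []
    for rng in spawn_rngs(17, 10_000):
        traj = simulate_trajectory(2, 1.0, m, t_max=1e6, seed=rng)
        waits.append(traj.times[1])
    waits = np.array(waits)
    se = waits.std(ddof=1) / math.sqrt(len(waits))
    assert abs(waits.mean() - 1.0 / k) < 3 * se


def test_ensemble_single_trajectory_and_mass():
    m = constant_kernel(1.0, 6)
    grid = np.linspace(0, 3, 16)
    traj = simulate_trajectory(6, 2.0, m, t_max=3.0, seed=9)
    ens = ensemble_average([traj], grid)
    assert ens.n_repeats == 1
    assert np.all(ens.sem == 0.0)
    assert np.array_equal(ens.mean * 2.0, sample_on_grid(traj, grid))
    assert np.allclose(ens.mass(), 3.0, atol=1e-12)  # N/V = 6/2
    with pytest.raises(ValueError):
        ensemble_average([], grid)


def test_simulate_ensemble_reproducible_and_conserving(grid_t5):
    m = blatz_tobolsky_kernel(1.0, 1.0, 6)
    a = simulate_ensemble(m, 6, 6.0, grid_t5, 50, seed=21)
    b = simulate_ensemble(m, 6, 6.0, grid_t5, 50, seed=21)
    assert np.array_equal(a.mean, b.mean)
    assert np.array_equal(a.sem, b.sem)
    assert np.allclose(a.mass(), 1.0, atol=1e-12)
    assert a.sem.min() >= 0.0


def test_observable_counts_initial_row():
    m = constant_kernel(1.0, 10)
    grid = np.linspace(0, 1, 6)
    obs = simulate_observable_counts(m, 10, 10.0, grid, n_repeats=4, seed=2)
    for name, t0 in [("monomers", 10), ("dimers", 0), ("trimers", 0), ("clusters", 10)]:
        mean, sem = obs[name]
        assert mean[0] == t0
        assert sem[0] == 0.0


@given(seed=st.integers(0, 2**16))
def test_mass_conserved_for_random_seeds(seed):
    m = blatz_tobolsky_kernel(1.0, 0.5, 5)
    traj = simulate_trajectory(5, 5.0, m, t_max=2.0, seed=seed)
    sizes = np.arange(6)
    assert np.all(traj.states @ sizes == 5)


def test_channel_table_matches_public_propensities():
    m = blatz_tobolsky_kernel(1.3, 0.4, 7)
    table = ChannelTable(m, V=3.0)
    state = _state(7, **{"1": 3, "2": 1, "4": 0, "3": 0})
    state.n[4] = 1
    assert np.array_equal(table.rates(state.n), propensities(state, m, 3.0))
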