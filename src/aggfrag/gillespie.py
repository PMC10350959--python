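"""Direct-method stochastic simulation of finite aggregation-fragmentation.

The state of a system of ``N`` monomers in a volume ``V`` is the integer
count vector ``n = (n_1, ..., n_N)`` with the exactly conserved mass
``Sum_i i n_i = N``.  Reaction channels are unordered pairs ``(i, j)``,
``i <= j``, ``i + j <= N``:

* aggregation ``C_i + C_j -> C_{i+j}`` with propensity
  ``K(i, j) n_i (n_j - delta_ij) / ((1 + delta_ij) V)``;
* fragmentation ``C_{i+j} -> C_i + C_j`` with propensity
  ``F(i, j) n_{i+j}``.

Each step of the direct method draws two uniform variates: the waiting time
``tau = ln(1/u1) / a_tot`` (exponential with the total propensity as rate)
and the channel as the smallest index whose cumulative propensity reaches
``u2 a_tot``.  A state with ``a_tot = 0`` is absorbing; the trajectory is
frozen there for the remainder of the requested time span.

Ensembles are averaged onto a fixed time grid by piecewise-constant
(state-holds-until-next-event) sampling.  One master seed spawns
independent per-trajectory child streams via ``numpy.random.SeedSequence``,
so ensembles are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .kernels import KernelModel, iter_channels

__all__ = [
    "SystemState",
    "ReactionChannel",
    "ChannelTable",
    "Trajectory",
    "TrajectoryEnsemble",
    "propensities",
    "draw_waiting_time",
    "select_reaction",
    "simulate_trajectory",
    "sample_on_grid",
    "ensemble_average",
    "simulate_ensemble",
    "simulate_observable_counts",
    "spawn_rngs",
    "OBSERVABLE_NAMES",
]

logger = logging.getLogger("aggfrag.gillespie")


@dataclass
class SystemState:
    """Cluster counts ``n`` (index ``i`` holds the number of i-mers,
    ``n[0]`` unused) and the current time."""

    n: np.ndarray
    t: float = 0.0

    @property
    def mass(self) -> int:
        return int(np.dot(np.arange(len(self.n)), self.n))


@dataclass(frozen=True)
class ReactionChannel:
    """One aggregation or fragmentation channel for the pair ``(i, j)``."""

    kind: str  # "aggregation" | "fragmentation"
    i: int
    j: int

    def apply(self, n: np.ndarray) -> None:
        """Apply the channel's state change in place."""
        i, j = self.i, self.j
        if self.kind == "aggregation":
            n[i] -= 1
            n[j] -= 1
            n[i + j] += 1
        else:
            n[i + j] -= 1
            n[i] += 1
            n[j] += 1


class ChannelTable:
    """Precomputed channel list and vectorized propensity evaluation.

    For a model with ``max_size = N`` and volume ``V`` the table holds the
    channel pairs ``(i, j)`` and the constant per-channel coefficients, so a
    propensity evaluation is a few vector operations on the current counts.
    The propensity vector lists all aggregation channels first, then all
    fragmentation channels (same pair order).
    """

    def __init__(self, model: KernelModel, V: float, N: int | None = None):
        self.N = model.max_size if N is None else N
        self.V = float(V)
        pairs = np.array(list(iter_channels(self.N)), dtype=np.intp)
        self.I = pairs[:, 0]
        self.J = pairs[:, 1]
        self.IJ = self.I + self.J
        self.diag = (self.I == self.J).astype(np.intp)
        Km = model.K_matrix(self.N)
        Fm = model.F_matrix(self.N)
        self.agg_coef = Km[self.I, self.J] / (self.V * (1.0 + self.diag))
        self.frag_coef = Fm[self.I, self.J]
        self.reversible = bool(np.any(self.frag_coef > 0.0))
        self.n_channels = len(pairs)
        self.channels = [ReactionChannel("aggregation", i, j) for i, j in pairs] + [
            ReactionChannel("fragmentation", i, j) for i, j in pairs
        ]

    def rates(self, n: np.ndarray) -> np.ndarray:
        """Propensity vector (aggregation block then fragmentation block)."""
        agg = self.agg_coef * n[self.I] * (n[self.J] - self.diag)
        frag = self.frag_coef * n[self.IJ]
        return np.concatenate([agg, frag])


def propensities(state: SystemState, model: KernelModel, V: float) -> np.ndarray:
    """Propensity vector for ``state``; zero entries mark impossible events."""
    table = ChannelTable(model, V)
    return table.rates(state.n)


def draw_waiting_time(a_tot: float, u1: float) -> float:
    """Exponential waiting time ``tau = ln(1/u1)/a_tot``.

    Raises if ``a_tot`` is not positive — the caller must treat a zero total
    propensity as an absorbing state and freeze the trajectory.
    """
    if a_tot <= 0:
        raise ValueError("absorbing state: total propensity is zero")
    if not 0.0 < u1 <= 1.0:
        raise ValueError("u1 must lie in (0, 1]")
    return math.log(1.0 / u1) / a_tot


def select_reaction(rates: np.ndarray, u2: float) -> int:
    """Smallest channel index whose cumulative rate reaches ``u2 * a_tot``."""
    cum = np.cumsum(rates)
    a_tot = cum[-1]
    if a_tot <= 0:
        raise ValueError("absorbing state: all channel rates are zero")
    return int(np.searchsorted(cum, u2 * a_tot, side="left"))


@dataclass
class Trajectory:
    """Piecewise-constant jump trajectory: event times (starting at 0) and
    the state *after* each event; ``states[k]`` holds on
    ``[times[k], times[k+1])``."""

    times: np.ndarray  # (n_events + 1,)
    states: np.ndarray  # (n_events + 1, N + 1) integer counts, column 0 unused
    N: int
    V: float
    t_max: float
    frozen: bool  # reached an absorbing state before t_max


def _monodisperse(N: int) -> np.ndarray:
    n = np.zeros(N + 1, dtype=np.int64)
    n[1] = N
    return n


def simulate_trajectory(
    N: int,
    V: float,
    model: KernelModel,
    t_max: float,
    seed: int | np.random.Generator,
) -> Trajectory:
    """Run one direct-method trajectory from the all-monomer start.

    Mass ``Sum_i i n_i = N`` is conserved exactly (integer arithmetic) at
    every event.  Identical seeds give identical event sequences.
    """
    if N < 2:
        raise ValueError("need at least N=2 monomers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = ChannelTable(model, V, N)
    n = _monodisperse(N)
    t = 0.0
    times = [0.0]
    states = [n.copy()]
    frozen = False
    while True:
        rates = table.rates(n)
        a_tot = float(rates.sum())
        if a_tot <= 0.0:
            frozen = True
            break
        u1 = 1.0 - rng.random()  # in (0, 1]
        u2 = rng.random()
        t += draw_waiting_time(a_tot, u1)
        if t > t_max:
            break
        table.channels[select_reaction(rates, u2)].apply(n)
        times.append(t)
        states.append(n.copy())
    logger.debug("trajectory: %d events, frozen=%s", len(times) - 1, frozen)
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        N=N,
        V=V,
        t_max=float(t_max),
        frozen=frozen,
    )


def sample_on_grid(traj: Trajectory, grid: np.ndarray) -> np.ndarray:
    """Counts (len(grid), N) at the grid times; the state holds from each
    event until the next one."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and grid[-1] > traj.t_max and not traj.frozen:
        raise ValueError("grid extends beyond the simulated time span")
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    return traj.states[idx][:, 1:]


@dataclass
class TrajectoryEnsemble:
    """Grid-sampled ensemble statistics.

    ``mean`` and ``sem`` are (len(times), N) arrays of per-size mean
    concentrations ``c_bar_i(t)`` and standard errors of the mean; column
    ``i-1`` corresponds to size ``i``.  Concentrations are counts divided by
    the volume ``V``.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_repeats: int
    N: int
    V: float

    def mean_counts(self) -> np.ndarray:
        return self.mean * self.V

    def sem_counts(self) -> np.ndarray:
        return self.sem * self.V

    def mass(self) -> np.ndarray:
        """Sum_i i c_bar_i(t); equals N/V at every grid point."""
        sizes = np.arange(1, self.N + 1)
        return self.mean @ sizes


class _RunningMoments:
    """Streaming mean/SEM accumulator over trajectories."""

    def __init__(self, shape: tuple[int, ...]):
        self.count = 0
        self.s1 = np.zeros(shape)
        self.s2 = np.zeros(shape)

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        self.s1 += x
        self.s2 += x * x

    def mean(self) -> np.ndarray:
        return self.s1 / self.count

    def sem(self) -> np.ndarray:
        if self.count < 2:
            return np.zeros_like(self.s1)
        var = (self.s2 - self.s1 * self.s1 / self.count) / (self.count - 1)
        return np.sqrt(np.clip(var, 0.0, None) / self.count)


def ensemble_average(trajectories, grid: np.ndarray) -> TrajectoryEnsemble:
    """Average a collection (or generator) of trajectories onto a grid."""
    grid = np.asarray(grid, dtype=float)
    acc = None
    N = V = None
    for traj in trajectories:
        if acc is None:
            N, V = traj.N, traj.V
            acc = _RunningMoments((len(grid), N))
        elif (traj.N, traj.V) != (N, V):
            raise ValueError("all trajectories must share (N, V)")
        acc.add(sample_on_grid(traj, grid).astype(float))
    if acc is None:
        raise ValueError("at least one trajectory is required")
    return TrajectoryEnsemble(
        times=grid,
        mean=acc.mean() / V,
        sem=acc.sem() / V,
        n_repeats=acc.count,
        N=N,
        V=V,
    )


def _simulate_counts_on_grid(
    table: ChannelTable, N: int, grid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One trajectory sampled straight onto the grid (no event storage)."""
    n = _monodisperse(N)
    out = np.empty((len(grid), N), dtype=np.int64)
    t = 0.0
    g = 0
    G = len(grid)
    n_events = 0
    while g < G:
        rates = table.rates(n)
        cum = np.cumsum(rates)
        a_tot = cum[-1]
        if a_tot <= 0.0:
            break  # absorbing: frozen state fills the rest of the grid
        t_next = t + math.log(1.0 / (1.0 - rng.random())) / a_tot
        while g < G and grid[g] < t_next:
            out[g] = n[1:]
            g += 1
        if g >= G:
            break
        k = int(np.searchsorted(cum, rng.random() * a_tot, side="left"))
        table.channels[k].apply(n)
        t = t_next
        n_events += 1
    while g < G:
        out[g] = n[1:]
        g += 1
    return out


OBSERVABLE_NAMES = ("monomers", "dimers", "trimers", "clusters")


def simulate_observable_counts(
    model: KernelModel,
    N: int,
    V: float,
    grid: np.ndarray,
    n_repeats: int,
    seed: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean and SEM of the standard observables across repeats.

    Observables are the average *numbers* (not concentrations) of monomers,
    dimers and trimers and the total number of clusters including monomers,
    ``n_cluster = Sum_i n_i``.  The SEM of the cluster count is taken across
    whole repeats, so within-trajectory correlations between sizes are
    retained.
    """
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2 for nonzero SEM error bars")
    grid = np.asarray(grid, dtype=float)
    table = ChannelTable(model, V, N)
    acc = _RunningMoments((len(grid), 4))
    for rng in spawn_rngs(seed, n_repeats):
        counts = _simulate_counts_on_grid(table, N, grid, rng)
        obs = np.empty((len(grid), 4))
        obs[:, 0] = counts[:, 0]
        obs[:, 1] = counts[:, 1] if N >= 2 else 0.0
        obs[:, 2] = counts[:, 2] if N >= 3 else 0.0
        obs[:, 3] = counts.sum(axis=1)
        acc.add(obs)
    mean, sem = acc.mean(), acc.sem()
    return {
        name: (mean[:, k].copy(), sem[:, k].copy())
        for k, name in enumerate(OBSERVABLE_NAMES)
    }


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_ensemble(
    model: KernelModel,
    N: int,
    V: float,
    grid: np.ndarray,
    n_repeats: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Run ``n_repeats`` trajectories and average them onto ``grid``.

    Streaming: each trajectory is sampled and discarded, so memory is
    independent of the repeat count.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    grid = np.asarray(grid, dtype=float)
    table = ChannelTable(model, V, N)
    acc = _RunningMoments((len(grid), N))
    for rng in spawn_rngs(seed, n_repeats):
        acc.add(_simulate_counts_on_grid(table, N, grid, rng).astype(float))
    logger.info(
        "ensemble: model=%s N=%d V=%g repeats=%d channels=%d",
        model.name,
        N,
        V,
        n_repeats,
        table.n_channels,
    )
    return TrajectoryEnsemble(
        times=grid,
        mean=acc.mean() / V,
        sem=acc.sem() / V,
        n_repeats=n_repeats,
        N=N,
        V=V,
    )
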