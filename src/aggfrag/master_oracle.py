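"""Exact master-equation solution by full state-space enumeration.

For small monomer counts the set of reachable states — integer-partition
count vectors ``n`` with ``Sum_i i n_i = N`` — is small enough (627 states
at N = 20, 5604 at N = 30) to build the full generator matrix of the
master equation and propagate the probability vector exactly.  The exact
means ``<n_i>(t)`` obtained this way are the ground truth against which
both the stochastic simulator and the mean-field (modified Smoluchowski)
equations are validated.

The generator ``Q`` is the column-stochastic rate matrix: the off-diagonal
entry ``Q[m, n]`` is the propensity of the unique channel taking state
``n`` to state ``m`` (shared with the stochastic simulator through
:class:`~aggfrag.gillespie.ChannelTable`), and each diagonal entry makes
its column sum to zero, so probability is conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .gillespie import ChannelTable
from .kernels import KernelModel

__all__ = [
    "StateSpace",
    "enumerate_states",
    "partition_count",
    "build_generator",
    "monodisperse_distribution",
    "solve_master",
    "mean_counts",
    "stationary_distribution",
]

logger = logging.getLogger("aggfrag.master_oracle")

MAX_ENUMERABLE_N = 30


@lru_cache(maxsize=None)
def partition_count(n: int) -> int:
    """Number of integer partitions p(n), by Euler's pentagonal recurrence."""
    if n < 0:
        return 0
    p = [1] + [0] * n
    for m in range(1, n + 1):
        k = 1
        while True:
            g1 = k * (3 * k - 1) // 2
            g2 = k * (3 * k + 1) // 2
            if g1 > m and g2 > m:
                break
            sign = -1 if k % 2 == 0 else 1
            if g1 <= m:
                p[m] += sign * p[m - g1]
            if g2 <= m:
                p[m] += sign * p[m - g2]
            k += 1
    return p[n]


@dataclass
class StateSpace:
    """All count vectors with total mass ``N``, in a deterministic order.

    ``states`` is an (n_states, N + 1) integer array (column 0 unused);
    ``index`` maps the tuple of counts (sizes 1..N) to its row.
    """

    N: int
    states: np.ndarray
    index: dict[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.states)


def _partitions(n: int, max_part: int):
    """Yield partitions of n as descending part lists."""
    if n == 0:
        yield []
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield [first] + rest


def enumerate_states(N: int) -> StateSpace:
    """Enumerate every state of total mass ``N``.

    The state count equals the partition number p(N); requests beyond
    N = 30 are refused with the partition count in the message.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > MAX_ENUMERABLE_N:
        raise ValueError(
            f"refusing to enumerate N={N}: the state space has "
            f"{partition_count(N)} states; use the stochastic simulator instead"
        )
    rows = []
    for parts in _partitions(N, N):
        n = np.zeros(N + 1, dtype=np.int64)
        for part in parts:
            n[part] += 1
        rows.append(n)
    states = np.array(rows)
    index = {tuple(row[1:]): k for k, row in enumerate(states)}
    assert len(states) == partition_count(N)
    return StateSpace(N=N, states=states, index=index)


def build_generator(space: StateSpace, model: KernelModel, V: float) -> sp.csr_matrix:
    """Sparse generator of the master equation on ``space``.

    Columns sum to zero; off-diagonal entries are the channel propensities
    evaluated with exactly the same code path as the stochastic simulator.
    """
    table = ChannelTable(model, V, space.N)
    rows, cols, vals = [], [], []
    for col, state in enumerate(space.states):
        rates = table.rates(state)
        exit_rate = 0.0
        for k in np.nonzero(rates > 0.0)[0]:
            target = state.copy()
            table.channels[k].apply(target)
            row = space.index[tuple(target[1:])]
            rows.append(row)
            cols.append(col)
            vals.append(rates[k])
            exit_rate += rates[k]
        if exit_rate > 0.0:
            rows.append(col)
            cols.append(col)
            vals.append(-exit_rate)
    gen = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(space), len(space))
    ).tocsr()
    logger.info(
        "generator: N=%d states=%d nnz=%d", space.N, len(space), gen.nnz
    )
    return gen


def monodisperse_distribution(space: StateSpace) -> np.ndarray:
    """Point mass on the all-monomer state."""
    p0 = np.zeros(len(space))
    n0 = tuple(
        np.concatenate([[space.N], np.zeros(space.N - 1, dtype=np.int64)])
    )
    p0[space.index[n0]] = 1.0
    return p0


def solve_master(
    generator: sp.csr_matrix,
    p0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> np.ndarray:
    """Propagate dp/dt = Q p on the grid; returns (len(times), n_states).

    Uses stiff-capable BDF integration with the sparse generator as exact
    Jacobian.  Normalization is preserved to the solver tolerance; tiny
    negative entries are clipped to zero.
    """
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, p: generator @ p,
        (times[0], times[-1]),
        np.asarray(p0, dtype=float),
        t_eval=times,
        method="BDF",
        jac=lambda t, p: generator,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"master-equation integration failed (rtol={rtol}, atol={atol}): "
            f"{sol.message}"
        )
    P = sol.y.T
    return np.clip(P, 0.0, None)


def mean_counts(P: np.ndarray, space: StateSpace) -> np.ndarray:
    """Exact means ``<n_i>(t)``: (len(times), N) array from probabilities."""
    P = np.atleast_2d(P)
    return P @ space.states[:, 1:]


def stationary_distribution(generator: sp.csr_matrix) -> np.ndarray:
    """Normalized null vector of the generator (dense SVD; small spaces)."""
    dense = generator.toarray()
    _, _, vt = np.linalg.svd(dense)
    p = np.abs(vt[-1])
    return p / p.sum()
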