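"""Mean-field rate equations: finite-system (modified) and classical forms.

The modified Smoluchowski equations describe the ensemble-averaged
concentrations ``c_bar_i = <n_i>/V`` of a finite system of ``N`` monomers.
They follow from the master equation by the mean-field moment closure
``<n_i (n_j - delta_ij)> ~= <n_i><n_j>`` and read, for ``i = 1..N``::

    d c_bar_i / dt =  1/2 Sum_{j<i} [ k_{j,i-j} c_bar_j c_bar_{i-j}
                                      - f'_{j,i-j} c_bar_i ]
                     - Sum_{j<=N-i} [ k_{i,j} c_bar_i c_bar_j
                                      - f'_{i,j} c_bar_{i+j} ]

with ``k_ij = K_ij`` and the modified fragmentation coefficient
``f'_ij = (1 + delta_ij) F_ij``.  No channel creates sizes above ``N``;
mass ``Sum_i i c_bar_i`` is conserved identically by the pairwise
bookkeeping.  The same right-hand side with a large truncation ``N_max``
(and the kernel evaluated beyond the physical ``N``) serves as the
classical, infinite-system reference; its truncation is auto-doubled until
the small-oligomer concentrations are converged.

The channel set and the ``(1 + delta)`` factors come from the same
enumeration used by the stochastic simulator, so the deterministic and
stochastic codepaths cannot drift apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kernels import KernelModel, iter_channels

__all__ = [
    "DeterministicSolution",
    "modified_rhs",
    "integrate_modified",
    "integrate_unmodified",
    "number_average_size",
    "total_clusters",
]

logger = logging.getLogger("aggfrag.smoluchowski_ode")


@dataclass
class DeterministicSolution:
    """Integrated mean concentrations.

    ``conc`` is (len(times), n_sizes) with column ``i-1`` holding
    ``c_bar_i(t)``; ``variant`` is "modified" (finite system) or
    "unmodified" (truncated classical reference); ``c`` is the initial
    monomer concentration.
    """

    times: np.ndarray
    conc: np.ndarray
    variant: str
    model: KernelModel
    c: float

    def mass(self) -> np.ndarray:
        sizes = np.arange(1, self.conc.shape[1] + 1)
        return self.conc @ sizes


class _MeanFieldSystem:
    """Precomputed vectorized right-hand side for a model truncated at n."""

    def __init__(self, model: KernelModel, n: int):
        self.n = n
        pairs = np.array(list(iter_channels(n)), dtype=np.intp)
        iu, ju = pairs[:, 0], pairs[:, 1]
        diag = (iu == ju).astype(float)
        Km = model.K_matrix(n)
        Fm = model.F_matrix(n)
        # aggregation gain: one (i+j)-mer per event, event rate K c_i c_j/(1+d)
        self.iu, self.ju, self.s = iu, ju, iu + ju
        self.pair_coef = Km[iu, ju] / (1.0 + diag)
        # aggregation loss: c_s * Sum_{j <= n-s} K[s, j] c_j (diagonal j=s
        # counts twice via the unrestricted sum, matching the 2 i-mers lost)
        sizes = np.arange(n + 1)
        allowed = (sizes[:, None] + sizes[None, :]) <= n
        self.KL = np.where(allowed, Km, 0.0)
        self.KL[0, :] = 0.0
        self.KL[:, 0] = 0.0
        # fragmentation: modified coefficients f' = (1+delta) F
        fp = Fm * (1.0 + np.eye(n + 1))
        # breakup rate of an s-mer: 1/2 Sum_{j<s} f'[j, s-j]
        br = np.zeros(n + 1)
        for s in range(2, n + 1):
            j = np.arange(1, s)
            br[s] = 0.5 * float(fp[j, s - j].sum())
        self.br = br
        # gain of s from (s+j)-mer splits: Sum_j f'[s, j] c_{s+j}
        FG = np.zeros((n + 1, n + 1))
        for s in range(1, n):
            j = np.arange(1, n - s + 1)
            FG[s, s + j] = fp[s, j]
        self.FG = FG

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        # c is the full (n+1,) vector with c[0] unused (kept at 0)
        w = self.pair_coef * c[self.iu] * c[self.ju]
        gain_agg = np.bincount(self.s, weights=w, minlength=self.n + 1)
        loss_agg = c * (self.KL @ c)
        loss_frag = self.br * c
        gain_frag = self.FG @ c
        d = gain_agg - loss_agg - loss_frag + gain_frag
        d[0] = 0.0
        return d


def _system(model: KernelModel, n: int) -> _MeanFieldSystem:
    key = ("ode", n)
    if key not in model._caches:
        model._caches[key] = _MeanFieldSystem(model, n)
    return model._caches[key]


def modified_rhs(conc: np.ndarray, model: KernelModel, N: int) -> np.ndarray:
    """Time derivative of the modified equations for sizes ``1..N``.

    ``conc`` has length ``N`` (entry ``i-1`` is ``c_bar_i``); the returned
    derivative has the same layout.  ``Sum_i i * d c_bar_i / dt == 0``
    identically for any input.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (N,):
        raise ValueError(f"expected a length-{N} concentration vector")
    full = np.concatenate([[0.0], conc])
    return _system(model, N).rhs(0.0, full)[1:]


def _integrate(
    model: KernelModel,
    n: int,
    c0_full: np.ndarray,
    times: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
) -> np.ndarray:
    sys_ = _system(model, n)
    sol = solve_ivp(
        sys_.rhs,
        (times[0], times[-1]),
        c0_full,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"rate-equation integration failed ({sol.message}); try looser "
            f"tolerances than rtol={rtol}, atol={atol}"
        )
    conc = sol.y.T[:, 1:]
    if conc.min() < -atol * 1e3:
        raise RuntimeError(
            f"negative concentration {conc.min():.3e} exceeds tolerance; "
            "integration is unreliable"
        )
    return conc


def integrate_modified(
    model: KernelModel,
    N: int,
    V: float,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> DeterministicSolution:
    """Integrate the modified (finite-N) equations from the monodisperse
    start ``c_bar_1(0) = N/V``."""
    times = np.asarray(times, dtype=float)
    c = N / V
    atol = 1e-12 * c if atol is None else atol
    c0 = np.zeros(N + 1)
    c0[1] = c
    conc = _integrate(model, N, c0, times, rtol, atol, "LSODA")
    drift = np.max(np.abs(conc @ np.arange(1, N + 1) - c))
    if drift > 1e-8 * c:
        raise RuntimeError(f"mass drift {drift:.3e} exceeds 1e-8 c")
    return DeterministicSolution(times, conc, "modified", model, c)


def integrate_unmodified(
    model: KernelModel,
    c: float,
    times: np.ndarray,
    N_max: int = 250,
    rtol: float = 1e-10,
    atol: float | None = None,
    limit: int = 4096,
) -> DeterministicSolution:
    """Classical (infinite-system) kinetics by truncation at ``N_max``.

    ``N_max`` is doubled until the monomer/dimer/trimer curves change by
    less than 1e-8 relative, so the result represents the deterministic
    ``N = infinity`` limit on the requested time span.
    """
    times = np.asarray(times, dtype=float)
    atol = 1e-14 * c if atol is None else atol

    def run(n: int) -> np.ndarray:
        c0 = np.zeros(n + 1)
        c0[1] = c
        return _integrate(model, n, c0, times, rtol, atol, "DOP853")

    prev = run(N_max)
    n = N_max
    while True:
        n *= 2
        if n > limit:
            raise RuntimeError(
                f"truncation did not converge up to N_max={n // 2}"
            )
        cur = run(n)
        scale = np.maximum(np.abs(cur[:, :3]), 1e-300)
        rel = np.max(np.abs(cur[:, :3] - prev[:, :3]) / scale)
        logger.info("unmodified truncation N_max=%d rel-change=%.2e", n, rel)
        if rel < 1e-8:
            return DeterministicSolution(times, cur, "unmodified", model, c)
        prev = cur


def _conc_rows(obj, t=None) -> tuple[np.ndarray, np.ndarray]:
    """Concentration rows and times from a solution or ensemble."""
    if isinstance(obj, np.ndarray):
        return np.atleast_2d(obj), None
    conc = getattr(obj, "conc", None)
    if conc is None:
        conc = obj.mean
    times = obj.times
    if t is not None:
        idx = int(np.argmin(np.abs(times - t)))
        return np.atleast_2d(conc[idx]), np.atleast_1d(times[idx])
    return conc, times


def number_average_size(obj, t: float | None = None):
    """Number-average aggregate size L = Sum_i i c_i / Sum_i c_i.

    ``obj`` may be a :class:`DeterministicSolution`, a trajectory ensemble,
    or a bare concentration (or count) vector/array; ``t`` selects the
    nearest grid time, otherwise L is returned for every row.
    """
    conc, _ = _conc_rows(obj, t)
    sizes = np.arange(1, conc.shape[1] + 1)
    total = conc.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("number-average size undefined for empty system")
    L = (conc @ sizes) / total
    return float(L[0]) if (t is not None or L.size == 1) else L


def total_clusters(obj, t: float | None = None, V: float | None = None):
    """Total cluster count n_cluster = V Sum_i c_bar_i (monomers included).

    For bare count arrays pass ``V = 1``; for solutions and ensembles the
    volume is inferred unless given.
    """
    conc, _ = _conc_rows(obj, t)
    if V is None:
        V = getattr(obj, "V", None)
        if V is None:  # DeterministicSolution stores c = N/V only
            V = 1.0
    total = conc.sum(axis=1) * V
    return float(total[0]) if (t is not None or total.size == 1) else total
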