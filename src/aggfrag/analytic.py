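"""Closed-form cluster-size distributions in the deterministic limit.

These are the exact time-dependent solutions of the classical (infinite
system, N = infinity) rate equations under monodisperse initial conditions
``c_i(0) = c * delta_{1,i}`` for three solvable kernels:

* constant kernel ``K = k_f`` (irreversible):
  ``c_i(t) = c B^{i-1} (1 - B)^2`` with ``B = (T/2) / (1 + T/2)`` and the
  scaled time ``T = k_f c t``;
* additive kernel ``K(i, j) = k_f (i + j)/2``:
  ``c_i(t) = c (1 - tau) (i tau)^{i-1} e^{-i tau} / i!`` with
  ``tau = 1 - exp(-T/2)``;
* size-independent reversible (Blatz-Tobolsky) model ``k_ij = k_f``,
  ``f_ij = k_b``: the distribution stays geometric,
  ``c_i(t) = c (1 - p)^2 p^{i-1}``, where the bond-conversion-like variable
  ``p(t)`` solves the Riccati equation
  ``dp/dt = [k_f c (1 - p)^2 - k_b p] / 2`` with ``p(0) = 0``, integrated in
  closed form through the two roots of its stationary condition.

Large-``i`` values are evaluated in log space to avoid underflow; the series
used for mass checks is truncated adaptively where ``i c_i < 1e-15 c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "AnalyticSolution",
    "constant_kernel_solution",
    "additive_kernel_solution",
    "blatz_tobolsky_solution",
]


@dataclass(frozen=True)
class AnalyticSolution:
    """Evaluatable deterministic-limit solution ``c_i(t)``.

    ``evaluate(i, t)`` accepts scalar or array ``i`` (sizes >= 1) and scalar
    ``t >= 0`` and returns concentrations.  ``total_concentration`` and
    ``mass`` sum the series with an adaptive tail cutoff.
    """

    model: str
    c: float
    params: dict[str, float]
    _log_ci: Callable[[np.ndarray, float], np.ndarray]

    def evaluate(self, i, t: float):
        i_arr = np.asarray(i)
        if np.any(i_arr < 1) or np.any(i_arr != np.floor(i_arr)):
            raise ValueError("cluster size i must be an integer >= 1")
        if t < 0:
            raise ValueError("time must be non-negative")
        out = np.exp(self._log_ci(i_arr.astype(float), float(t)))
        return out if out.shape else float(out)

    def _series(self, t: float, weight_mass: bool) -> float:
        total = 0.0
        i0 = 1
        block = 256
        tiny = 1e-15 * self.c
        while i0 < 10_000_000:
            sizes = np.arange(i0, i0 + block)
            ci = np.exp(self._log_ci(sizes.astype(float), float(t)))
            terms = sizes * ci if weight_mass else ci
            total += float(terms.sum())
            if sizes[-1] * ci[-1] < tiny and i0 > 1:
                break
            i0 += block
            block *= 2
        return total

    def total_concentration(self, t: float) -> float:
        """Sum_i c_i(t), the total cluster concentration."""
        return self._series(t, weight_mass=False)

    def mass(self, t: float) -> float:
        """Sum_i i c_i(t); equals the conserved initial mass c."""
        return self._series(t, weight_mass=True)

    def number_average_size(self, t: float) -> float:
        """L(t) = mass / total clusters = c / Sum_i c_i(t)."""
        return self.mass(t) / self.total_concentration(t)


def constant_kernel_solution(c: float, k_f: float) -> AnalyticSolution:
    """Irreversible size-independent aggregation, monodisperse start."""
    if not (c > 0 and k_f > 0):
        raise ValueError("c and k_f must be positive")

    def log_ci(i: np.ndarray, t: float) -> np.ndarray:
        half_T = 0.5 * k_f * c * t
        b = half_T / (1.0 + half_T)
        return np.log(c) + xlogy(i - 1.0, b) + 2.0 * np.log1p(-b)

    return AnalyticSolution("constant", c, {"k_f": k_f}, log_ci)


def additive_kernel_solution(c: float, k_f: float) -> AnalyticSolution:
    """Sum kernel K(i,j) = k_f (i+j)/2, monodisperse start."""
    if not (c > 0 and k_f > 0):
        raise ValueError("c and k_f must be positive")

    def log_ci(i: np.ndarray, t: float) -> np.ndarray:
        tau = -np.expm1(-0.5 * k_f * c * t)
        return (
            np.log(c)
            + np.log1p(-tau)
            + xlogy(i - 1.0, i * tau)
            - i * tau
            - gammaln(i + 1.0)
        )

    return AnalyticSolution("additive", c, {"k_f": k_f}, log_ci)


def bt_conversion(t, c: float, k_f: float, k_b: float):
    """Geometric-distribution parameter p(t) of the reversible flat model.

    Solves dp/dt = [k_f c (1-p)^2 - k_b p]/2, p(0) = 0, in closed form.
    For k_b = 0 this is p = (T/2)/(1 + T/2) with T = k_f c t.
    """
    t = np.asarray(t, dtype=float)
    if k_b == 0.0:
        half_T = 0.5 * k_f * c * t
        return half_T / (1.0 + half_T)
    a = 0.5 * k_f * c
    b = 0.5 * k_b
    disc = np.sqrt(b * (b + 4.0 * a))  # = a (p_plus - p_minus)
    p_minus = (2.0 * a + b - disc) / (2.0 * a)  # equilibrium root, < 1
    e = np.exp(-disc * t)
    return p_minus * (1.0 - e) / (1.0 - p_minus * p_minus * e)


def blatz_tobolsky_solution(c: float, k_f: float, k_b: float) -> AnalyticSolution:
    """Reversible size-independent model, monodisperse start.

    The k_b = 0 limit reproduces :func:`constant_kernel_solution` exactly.
    """
    if not (c > 0 and k_f > 0):
        raise ValueError("c and k_f must be positive")
    if k_b < 0:
        raise ValueError("k_b must be non-negative")

    def log_ci(i: np.ndarray, t: float) -> np.ndarray:
        p = bt_conversion(t, c, k_f, k_b)
        return np.log(c) + xlogy(i - 1.0, p) + 2.0 * np.log1p(-p)

    return AnalyticSolution("blatz_tobolsky", c, {"k_f": k_f, "k_b": k_b}, log_ci)
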