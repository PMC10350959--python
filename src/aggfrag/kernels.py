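"""Aggregation and fragmentation kernels for finite-system cluster kinetics.

A kinetic model for a well-mixed system of ``N`` monomers in a volume ``V``
is specified by two symmetric kernels on cluster sizes:

* ``K(i, j)`` — the aggregation kernel (units: volume/time).  ``K(i, j)/V``
  is the probability per unit time that one *given* i-mer/j-mer pair
  coalesces into an (i+j)-mer.
* ``F(i, j)`` — the fragmentation kernel (units: 1/time).  ``F(i, j)`` is
  the probability per unit time that one given (i+j)-mer splits into an
  i-mer and a j-mer.

Every aggregation-fragmentation reaction pair ``C_{i+j} <-> C_i + C_j`` is
indexed by an *unordered* pair ``(i, j)`` with ``i <= j`` and ``i + j <= N``:
permuting the indexes does not introduce a new process.  The number of
distinct reactant pairs in a state with cluster counts ``n`` is
``n_i n_j`` for ``i != j`` and ``n_i (n_i - 1)/2`` for ``i == j``, compactly
``n_i (n_j - delta_ij) / (1 + delta_ij)``.

The deterministic rate equations use rate *coefficients* instead of kernels.
In the convention adopted here they are related by::

    k_ij = K_ij                      (aggregation)
    f_ij = (1 + delta_ij) F_ij       (fragmentation)

where the stoichiometric factor ``1 + delta_ij`` accounts for fragmentation
events in which a cluster splits into two equal fragments.  The modified
(finite-system) equations use the same fragmentation coefficient, here
exposed as ``f_prime`` alongside ``f``.

Native units are nm^3/ps for ``K`` and 1/ps for ``F``; a dimensionless mode
(``k_f = c = 1``, scaled time ``T = k_f c t``) is the default throughout the
test-suite and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping

import numpy as np

__all__ = [
    "KernelModel",
    "RateCoefficients",
    "constant_kernel",
    "additive_kernel",
    "diffusion_kernel",
    "blatz_tobolsky_kernel",
    "three_param_kernel",
    "kernels_to_rate_coefficients",
    "iter_channels",
    "kernel_from_config",
]

KERNEL_FAMILIES = ("constant", "additive", "diffusion", "blatz_tobolsky", "three_param")


def iter_channels(n_max: int) -> Iterator[tuple[int, int]]:
    """Yield every reaction channel ``(i, j)`` with ``i <= j``, ``i + j <= n_max``.

    This is the single source of truth for channel enumeration shared by the
    stochastic simulator, the master-equation generator and the deterministic
    integrators.  Order: lexicographic in ``(i, j)``.
    """
    for i in range(1, n_max // 2 + 1):
        for j in range(i, n_max - i + 1):
            yield i, j


@dataclass(eq=False)
class KernelModel:
    """A named aggregation-fragmentation model.

    Attributes
    ----------
    name : str
        Kernel family identifier.
    params : dict
        Named positive parameters (``k_f``: volume/time, ``k_b``: 1/time,
        ``q``: dimensionless).
    K, F : callable
        Symmetric kernel functions of two integer cluster sizes ``>= 1``.
    max_size : int
        Largest cluster size ``N`` the model is meant for; dense kernel
        matrices are cached up to this size for the ODE/SSA hot loops.
    """

    name: str
    params: dict[str, float]
    K: Callable[[int, int], float]
    F: Callable[[int, int], float]
    max_size: int
    _caches: dict = field(default_factory=dict, repr=False)

    @property
    def reversible(self) -> bool:
        return bool(np.any(self.F_matrix() > 0.0))

    def _matrix(self, fn: Callable[[int, int], float], n: int) -> np.ndarray:
        """Dense (n+1, n+1) kernel matrix; row/column 0 unused (zero)."""
        m = np.zeros((n + 1, n + 1))
        idx = np.arange(1, n + 1)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        vec = np.vectorize(fn, otypes=[float])
        m[1:, 1:] = vec(ii, jj)
        return m

    def K_matrix(self, n: int | None = None) -> np.ndarray:
        n = self.max_size if n is None else n
        key = ("K", n)
        if key not in self._caches:
            self._caches[key] = self._matrix(self.K, n)
        return self._caches[key]

    def F_matrix(self, n: int | None = None) -> np.ndarray:
        n = self.max_size if n is None else n
        key = ("F", n)
        if key not in self._caches:
            self._caches[key] = self._matrix(self.F, n)
        return self._caches[key]

    def to_config(self, V: float | None = None) -> dict:
        cfg = {"family": self.name, "N": self.max_size, **self.params}
        if V is not None:
            cfg["V"] = V
        return cfg


@dataclass(frozen=True)
class RateCoefficients:
    """Deterministic rate coefficients derived from stochastic kernels.

    ``k[i, j]`` are second-order aggregation coefficients, ``f[i, j]`` the
    first-order fragmentation coefficients of the classical equations and
    ``f_prime[i, j]`` the modified fragmentation coefficients of the
    finite-system equations.  All matrices are symmetric with index 0 unused.
    For this model class the classical and modified fragmentation
    coefficients carry the same ``(1 + delta_ij)`` stoichiometric factor and
    coincide.
    """

    k: np.ndarray
    f: np.ndarray
    f_prime: np.ndarray


def _validate(k_f: float, n: int, k_b: float = 0.0, q: float = 1.0) -> None:
    if not k_f > 0:
        raise ValueError(f"k_f must be positive, got {k_f}")
    if k_b < 0:
        raise ValueError(f"k_b must be non-negative, got {k_b}")
    if not q > 0:
        raise ValueError(f"q must be positive, got {q}")
    if n < 2:
        raise ValueError(f"need at least N=2 monomers, got {n}")


def _zero(i: int, j: int) -> float:
    return 0.0


def constant_kernel(k_f: float, N: int) -> KernelModel:
    """Size-independent irreversible aggregation, ``K(i, j) = k_f``, ``F = 0``."""
    _validate(k_f, N)
    return KernelModel("constant", {"k_f": k_f}, lambda i, j: k_f, _zero, N)


def additive_kernel(k_f: float, N: int) -> KernelModel:
    """Sum kernel ``K(i, j) = k_f (i + j) / 2`` (so ``K(1, 1) = k_f``), ``F = 0``."""
    _validate(k_f, N)
    return KernelModel(
        "additive", {"k_f": k_f}, lambda i, j: 0.5 * k_f * (i + j), _zero, N
    )


def diffusion_kernel(k_f: float, N: int) -> KernelModel:
    """Brownian coalescence kernel of diffusing spheres.

    ``K(i, j) = (k_f/4) (i^{1/3} + j^{1/3}) (i^{-1/3} + j^{-1/3})`` with the
    composite prefactor ``k_f`` absorbing ``8 k_B T / 3 eta``-type constants;
    normalized so that the diagonal ``K(i, i) = k_f`` for every ``i``.
    """
    _validate(k_f, N)

    def K(i: int, j: int) -> float:
        a, b = i ** (1.0 / 3.0), j ** (1.0 / 3.0)
        return 0.25 * k_f * (a + b) * (1.0 / a + 1.0 / b)

    return KernelModel("diffusion", {"k_f": k_f}, K, _zero, N)


def blatz_tobolsky_kernel(k_f: float, k_b: float, N: int) -> KernelModel:
    """Size-independent reversible aggregation-fragmentation.

    Rate coefficients are flat: ``k_ij = k_f`` and ``f_ij = k_b``, i.e. in
    kernel form ``K(i, j) = k_f`` and ``F(i, j) = k_b / (1 + delta_ij)``.
    The total breakup rate of an i-mer is then ``(i - 1) k_b / 2``,
    proportional to the number of internal bonds of a linear chain, which is
    the counting under which the cluster-size distribution stays geometric
    and the model has a closed-form solution.  ``k_b = 0`` reduces exactly
    to :func:`constant_kernel`.
    """
    _validate(k_f, N, k_b=k_b)
    if k_b == 0.0:
        m = constant_kernel(k_f, N)
        return KernelModel("blatz_tobolsky", {"k_f": k_f, "k_b": 0.0}, m.K, m.F, N)

    def F(i: int, j: int) -> float:
        return k_b / 2.0 if i == j else k_b

    return KernelModel(
        "blatz_tobolsky", {"k_f": k_f, "k_b": k_b}, lambda i, j: k_f, F, N
    )


def three_param_kernel(k_f: float, k_b: float, q: float, N: int) -> KernelModel:
    """Blatz-Tobolsky base with monomer channels boosted by a factor ``q``.

    Every channel whose smaller index equals 1 — a monomer aggregating onto
    a cluster, or a monomer splitting off — is faster by the dimensionless
    factor ``q``, on both the aggregation and the fragmentation side.
    ``q = 1`` reduces exactly to :func:`blatz_tobolsky_kernel`.
    """
    _validate(k_f, N, k_b=k_b, q=q)
    base = blatz_tobolsky_kernel(k_f, k_b, N)
    if q == 1.0:
        return KernelModel(
            "three_param", {"k_f": k_f, "k_b": k_b, "q": 1.0}, base.K, base.F, N
        )
    baseK, baseF = base.K, base.F

    def boost(i: int, j: int) -> float:
        return q if min(i, j) == 1 else 1.0

    return KernelModel(
        "three_param",
        {"k_f": k_f, "k_b": k_b, "q": q},
        lambda i, j: boost(i, j) * baseK(i, j),
        lambda i, j: boost(i, j) * baseF(i, j),
        N,
    )


def kernels_to_rate_coefficients(model: KernelModel) -> RateCoefficients:
    """Convert stochastic kernels to deterministic rate-coefficient matrices.

    ``k = K`` and ``f = f' = (1 + delta_ij) F``.  Substituted into the rate
    equations these reproduce the event-rate bookkeeping: the rate of
    aggregation events per unit volume for a pair ``(i, j)`` is
    ``K_ij c_i c_j / (1 + delta_ij)`` and the rate of fragmentation events
    per unit volume is ``F_ij c_{i+j}``.
    """
    n = model.max_size
    k = model.K_matrix(n).copy()
    F = model.F_matrix(n)
    f = F * (1.0 + np.eye(n + 1))
    f[0, :] = 0.0
    f[:, 0] = 0.0
    return RateCoefficients(k=k, f=f, f_prime=f.copy())


_BUILDERS: dict[str, Callable[..., KernelModel]] = {
    "constant": lambda N, k_f=1.0, **_: constant_kernel(k_f, N),
    "additive": lambda N, k_f=1.0, **_: additive_kernel(k_f, N),
    "diffusion": lambda N, k_f=1.0, **_: diffusion_kernel(k_f, N),
    "blatz_tobolsky": lambda N, k_f=1.0, k_b=0.0, **_: blatz_tobolsky_kernel(
        k_f, k_b, N
    ),
    "three_param": lambda N, k_f=1.0, k_b=0.0, q=1.0, **_: three_param_kernel(
        k_f, k_b, q, N
    ),
}


def build_kernel(family: str, N: int, **params: float) -> KernelModel:
    """Build a kernel model by family name with keyword parameters."""
    try:
        builder = _BUILDERS[family]
    except KeyError:
        raise ValueError(
            f"unknown kernel family {family!r}; choose from {KERNEL_FAMILIES}"
        ) from None
    return builder(N, **params)


def kernel_from_config(cfg: Mapping) -> tuple[KernelModel, float | None]:
    """Build a model from a plain config mapping.

    Expected keys: ``family``, ``N`` and the family's parameters; an optional
    ``V`` (volume) is returned alongside the model.
    """
    cfg = dict(cfg)
    family = cfg.pop("family")
    n = int(cfg.pop("N"))
    volume = cfg.pop("V", None)
    model = build_kernel(family, n, **{k: float(v) for k, v in cfg.items()})
    return model, (None if volume is None else float(volume))
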