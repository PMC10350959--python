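"""Generator of MD-like averaged cluster-size datasets.

Coarse-grained aggregation simulations are typically repeated a handful of
times (three to six) and averaged, giving time series of mean monomer,
dimer and trimer numbers and total cluster counts with SEM error bars.
This module emulates exactly that data structure by running a small
ensemble of stochastic trajectories from a chosen kernel: the observation
noise comes solely from finite-repeat averaging — the same noise structure
as the real averages — with no extra additive noise.

An optional concentration-dependence hook rescales ``k_f`` with the
initial concentration, which violates the core assumption of the
stochastic model (concentration-independent kernels) on purpose: it
reproduces the failure mode where single-concentration fits look fine but
a joint fit across concentrations degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .fitting import ObservableSet
from .gillespie import simulate_observable_counts
from .kernels import build_kernel

__all__ = ["SyntheticSpec", "generate_observables", "generate_two_concentration_suite"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic averaged dataset.

    Defaults emulate the structure of a small-repeat simulation campaign:
    72 monomers, three repeats, 101 grid points on the scaled-time window
    [0, 5] in dimensionless units (k_f = c = 1).  ``kf_of_c`` optionally
    maps the initial concentration to a multiplicative factor on ``k_f``
    (default: constant 1, the stochastic model's own assumption).
    """

    family: str = "three_param"
    params: dict[str, float] = field(
        default_factory=lambda: {"k_f": 1.0, "k_b": 0.5, "q": 4.0}
    )
    N: int = 72
    V: float = 72.0
    n_repeats: int = 3
    t_max: float = 5.0
    n_grid: int = 101
    seed: int = 0
    kf_of_c: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2 so SEMs are nonzero")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_grid)

    @property
    def concentration(self) -> float:
        return self.N / self.V


def _effective_params(spec: SyntheticSpec) -> dict[str, float]:
    params = dict(spec.params)
    if spec.kf_of_c is not None:
        params["k_f"] = params["k_f"] * float(spec.kf_of_c(spec.concentration))
    return params


def generate_observables(spec: SyntheticSpec) -> ObservableSet:
    """Run the repeat ensemble and package means and SEMs.

    Bit-identical for identical specs (one master seed spawns the per-repeat
    streams).
    """
    params = _effective_params(spec)
    model = build_kernel(spec.family, spec.N, **params)
    data = simulate_observable_counts(
        model, spec.N, spec.V, spec.grid, spec.n_repeats, spec.seed
    )
    return ObservableSet(
        times=spec.grid,
        data=data,
        N=spec.N,
        V=spec.V,
        meta={
            "family": spec.family,
            "true_params": params,
            "n_repeats": spec.n_repeats,
            "seed": spec.seed,
        },
    )


def generate_two_concentration_suite(
    spec: SyntheticSpec, c_ratio: float
) -> tuple[ObservableSet, ObservableSet]:
    """Two datasets differing only in concentration (volume).

    The second dataset keeps ``N`` and rescales the volume by ``1/c_ratio``
    so its initial concentration is ``c_ratio`` times the first.  With the
    default constant-``k_f`` hook the pair is consistent under joint
    fitting; with a concentration-dependent hook it reproduces the
    cross-concentration failure mode.
    """
    if not c_ratio > 0:
        raise ValueError("c_ratio must be positive")
    spec_b = replace(
        spec,
        V=spec.V / c_ratio,
        seed=spec.seed + 1,
        params=dict(spec.params),
    )
    return generate_observables(spec), generate_observables(spec_b)
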