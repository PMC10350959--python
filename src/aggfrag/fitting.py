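"""Weighted fitting of the modified rate equations to cluster time series.

The workflow mirrors how kinetic models are developed from averaged
simulation data: the observables are the average numbers of monomers,
dimers and trimers and the total cluster count (monomers included), each
with a standard error of the mean per time point.  A kernel family's
modified-Smoluchowski predictions are fitted by minimizing the reduced
chi-square

    chi2_nu = chi2 / nu,   chi2 = Sum [ (data - model) / SEM ]^2,
    nu = n - m  (observations minus fitted parameters),

chi2_nu ~= 1 indicating a good fit.  Competing kernel families are ranked
by chi2_nu (ties favour fewer parameters), and a converged fit is
validated by re-simulating the stochastic model at the fitted parameters
and comparing the Monte Carlo averages with the data.

Optimization is deterministic: five log-uniformly spaced starts inside the
bounds, a bounded Nelder-Mead simplex stage, then a least-squares polish,
all in log-parameter space so positivity is built in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .gillespie import OBSERVABLE_NAMES, simulate_observable_counts
from .kernels import KernelModel, build_kernel
from .smoluchowski_ode import integrate_modified

__all__ = [
    "ObservableSet",
    "FitResult",
    "ValidationReport",
    "CrossConcentrationReport",
    "FAMILY_PARAMS",
    "predict_observables",
    "chi_square",
    "fit_model",
    "model_discrimination",
    "validate_fit",
    "cross_concentration_check",
]

logger = logging.getLogger("aggfrag.fitting")

FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "constant": ("k_f",),
    "additive": ("k_f",),
    "diffusion": ("k_f",),
    "blatz_tobolsky": ("k_f", "k_b"),
    "three_param": ("k_f", "k_b", "q"),
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_f": (1e-4, 1e4),
    "k_b": (1e-8, 1e4),
    "q": (1e-2, 1e3),
}

SEM_FLOOR_FRACTION = 1e-6  # floor = fraction * max |observable|


@dataclass
class ObservableSet:
    """Averaged cluster-size observables on a common time grid.

    ``data`` maps an observable name (from ``OBSERVABLE_NAMES``) to a
    ``(mean, sem)`` pair of arrays matching ``times``.  ``N`` and ``V`` are
    the monomer count and volume of the system that produced the data.
    """

    times: np.ndarray
    data: dict[str, tuple[np.ndarray, np.ndarray]]
    N: int
    V: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name, (mean, sem) in list(self.data.items()):
            if name not in OBSERVABLE_NAMES:
                raise ValueError(
                    f"unknown observable {name!r}; allowed: {OBSERVABLE_NAMES}"
                )
            mean = np.asarray(mean, dtype=float)
            sem = np.asarray(sem, dtype=float)
            if mean.shape != self.times.shape or sem.shape != self.times.shape:
                raise ValueError(f"observable {name!r} does not match the grid")
            if np.any(sem < 0):
                raise ValueError(f"negative SEM in observable {name!r}")
            self.data[name] = (mean, sem)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in OBSERVABLE_NAMES if n in self.data)

    @property
    def concentration(self) -> float:
        return self.N / self.V


@dataclass
class FitResult:
    """Fitted parameters and goodness-of-fit summary."""

    family: str
    params: dict[str, float]
    stderr: dict[str, float]
    chi2: float
    nu: int
    chi2_reduced: float
    converged: bool
    n_eval: int
    message: str
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_free_params(self) -> int:
        return len(self.params) - len(self.fixed)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "stderr": self.stderr,
            "chi2": self.chi2,
            "nu": self.nu,
            "chi2_reduced": self.chi2_reduced,
            "converged": self.converged,
            "n_eval": self.n_eval,
            "message": self.message,
            "fixed": self.fixed,
        }


def predict_observables(
    family: str,
    params: dict[str, float],
    N: int,
    V: float,
    times: np.ndarray,
    rtol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Modified-equation predictions of the observable *counts*."""
    model = build_kernel(family, N, **params)
    sol = integrate_modified(model, N, V, np.asarray(times, dtype=float), rtol=rtol)
    counts = sol.conc * V
    return {
        "monomers": counts[:, 0],
        "dimers": counts[:, 1] if N >= 2 else np.zeros(len(times)),
        "trimers": counts[:, 2] if N >= 3 else np.zeros(len(times)),
        "clusters": counts.sum(axis=1),
    }


def _sem_floor(mean: np.ndarray, sem_kept: np.ndarray) -> float:
    """Weight floor for zero-SEM points.

    A point whose SEM is exactly zero (every repeat gave the same value,
    e.g. no trimer was ever seen at an early time) is not infinitely
    precise — it is at the resolution limit of the repeat ensemble.  Such
    points are floored at the observable's smallest *positive* SEM, with a
    1e-6-of-maximum numerical backstop when the whole series is noiseless.
    """
    positive = sem_kept[sem_kept > 0]
    floor = SEM_FLOOR_FRACTION * max(np.max(np.abs(mean)), 1.0)
    if positive.size:
        floor = max(floor, float(positive.min()))
    return floor


def _included(times: np.ndarray, include_t0: bool) -> np.ndarray:
    keep = np.ones(len(times), dtype=bool)
    if not include_t0 and len(times) and times[0] == 0.0:
        keep[0] = False
    return keep


def _residual_vector(
    data: ObservableSet,
    prediction: dict[str, np.ndarray],
    include_t0: bool = False,
    scale: str = "none",
) -> np.ndarray:
    keep = _included(data.times, include_t0)
    chunks = []
    for name in data.names:
        mean, sem = data.data[name]
        w = np.maximum(sem[keep], _sem_floor(mean, sem[keep]))
        r = (mean[keep] - prediction[name][keep]) / w
        if scale == "per_observable":
            r = r / np.sqrt(len(r))
        elif scale != "none":
            raise ValueError("scale must be 'none' or 'per_observable'")
        chunks.append(r)
    return np.concatenate(chunks)


def chi_square(
    data: ObservableSet,
    prediction: dict[str, np.ndarray],
    m_params: int,
    include_t0: bool = False,
    scale: str = "none",
) -> tuple[float, float]:
    """Weighted chi-square and reduced chi-square of a prediction.

    Time points with SEM = 0 receive a small floor (1e-6 of the observable
    maximum); the t = 0 point, identical in every repeat, is excluded
    unless ``include_t0`` is set.
    """
    r = _residual_vector(data, prediction, include_t0, scale)
    n = len(r)
    nu = n - m_params
    if nu < 1:
        raise ValueError(f"no degrees of freedom: n={n} observations, m={m_params}")
    chi2 = float(r @ r)
    return chi2, chi2 / nu


def _log_starts(lo: np.ndarray, hi: np.ndarray, n_starts: int) -> np.ndarray:
    fracs = np.linspace(0.15, 0.85, n_starts)
    return np.log(lo) + fracs[:, None] * (np.log(hi) - np.log(lo))


def fit_model(
    data: ObservableSet,
    family: str,
    N: int | None = None,
    V: float | None = None,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: dict[str, float] | None = None,
    n_starts: int = 5,
    scale: str = "none",
    rtol: float = 1e-8,
) -> FitResult:
    """Fit one kernel family to an observable set.

    Deterministic given the data and settings.  ``fixed`` pins named
    parameters (they do not count toward the degrees of freedom).  A
    non-converged optimizer is reported through ``converged``/``message``,
    never silently.
    """
    N = data.N if N is None else N
    V = data.V if V is None else V
    names = FAMILY_PARAMS[family]
    fixed = dict(fixed or {})
    free = [p for p in names if p not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    user_bounds = bounds or {}
    lo = np.array([user_bounds.get(p, DEFAULT_BOUNDS[p])[0] for p in free])
    hi = np.array([user_bounds.get(p, DEFAULT_BOUNDS[p])[1] for p in free])

    n_eval = 0

    def unpack(z: np.ndarray) -> dict[str, float]:
        p = dict(fixed)
        p.update({name: float(np.exp(v)) for name, v in zip(free, z)})
        return p

    def residuals(z: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        zc = np.clip(z, np.log(lo), np.log(hi))
        pred = predict_observables(family, unpack(zc), N, V, data.times, rtol=rtol)
        r = _residual_vector(data, pred, scale=scale)
        # quadratic penalty keeps the simplex inside the box
        penalty = np.linalg.norm(z - zc) * (1.0 + np.abs(r).max())
        return r + penalty / max(len(r), 1)

    def objective(z: np.ndarray) -> float:
        r = residuals(z)
        return float(r @ r)

    m = len(free)
    n_points = len(_residual_vector(data, {k: data.data[k][0] for k in data.names}))
    if n_points - m < 1:
        raise ValueError(f"no degrees of freedom: n={n_points}, m={m}")

    starts = _log_starts(lo, hi, n_starts)
    if init:
        starts[0] = np.log([init[p] for p in free])
    best = None
    for z0 in starts:
        nm = optimize.minimize(
            objective,
            z0,
            method="Nelder-Mead",
            options={"maxfev": 150 * m, "xatol": 1e-6, "fatol": 1e-8},
        )
        ls = optimize.least_squares(
            residuals,
            np.clip(nm.x, np.log(lo), np.log(hi)),
            bounds=(np.log(lo), np.log(hi)),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        cand = (float(ls.cost * 2.0), ls)
        if best is None or cand[0] < best[0]:
            best = cand
    chi2, ls = best
    z_opt = ls.x
    params = unpack(z_opt)
    nu = n_points - m
    chi2_red = chi2 / nu

    # parameter uncertainties from the Jacobian in log space, scaled by
    # the reduced chi-square (standard error-propagation convention)
    stderr = {}
    try:
        JtJ = ls.jac.T @ ls.jac
        cov = np.linalg.pinv(JtJ) * chi2_red
        sig_z = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for name, z, s in zip(free, z_opt, sig_z):
            stderr[name] = float(np.exp(z) * s)
    except Exception:  # pragma: no cover - singular Jacobian
        stderr = {name: float("nan") for name in free}

    converged = bool(ls.success)
    result = FitResult(
        family=family,
        params=params,
        stderr=stderr,
        chi2=chi2,
        nu=nu,
        chi2_reduced=chi2_red,
        converged=converged,
        n_eval=n_eval,
        message=str(ls.message),
        fixed=fixed,
    )
    logger.info(
        "fit %s: chi2_nu=%.4g params=%s converged=%s evals=%d",
        family,
        chi2_red,
        {k: round(v, 6) for k, v in params.items()},
        converged,
        n_eval,
    )
    return result


def model_discrimination(
    data: ObservableSet,
    families: list[str],
    N: int | None = None,
    V: float | None = None,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit each family and rank by reduced chi-square (ties: fewer params)."""
    results = [fit_model(data, fam, N=N, V=V, **fit_kwargs) for fam in families]
    return sorted(results, key=lambda r: (r.chi2_reduced, r.n_free_params))


@dataclass
class ValidationReport:
    """Monte Carlo validation of a converged fit.

    ``max_dev_vs_data`` / ``max_dev_vs_ode`` give, per observable, the
    maximum absolute deviation of the Monte Carlo ensemble mean from the
    data (resp. from the fitted mean-field prediction) in units of the
    combined SEM; ``frac_within`` is the fraction of (observable, time)
    points with data deviation <= 3.  The fit passes when that fraction is
    at least 0.95.
    """

    passed: bool
    frac_within: float
    max_dev_vs_data: dict[str, float]
    max_dev_vs_ode: dict[str, float]
    n_repeats: int
    seed: int


def validate_fit(
    fit: FitResult,
    data: ObservableSet,
    n_repeats: int = 1000,
    seed: int = 0,
    N: int | None = None,
    V: float | None = None,
) -> ValidationReport:
    """Re-simulate the stochastic model at the fitted parameters and compare
    the Monte Carlo averages with the data (and with the mean-field fit)."""
    if not fit.converged:
        raise ValueError("refusing to validate a non-converged fit")
    N = data.N if N is None else N
    V = data.V if V is None else V
    model_params = fit.params
    mc = simulate_observable_counts(
        build_kernel(fit.family, N, **model_params), N, V, data.times, n_repeats, seed
    )
    ode = predict_observables(fit.family, model_params, N, V, data.times)
    keep = _included(data.times, include_t0=False)
    devs_data, devs_ode = {}, {}
    within = total = 0
    for name in data.names:
        d_mean, d_sem = data.data[name]
        m_mean, m_sem = mc[name]
        combined = np.sqrt(d_sem[keep] ** 2 + m_sem[keep] ** 2)
        w = np.maximum(combined, _sem_floor(d_mean, combined))
        dev = np.abs(m_mean[keep] - d_mean[keep]) / w
        devs_data[name] = float(dev.max())
        within += int(np.sum(dev <= 3.0))
        total += len(dev)
        w_ode = np.maximum(m_sem[keep], _sem_floor(d_mean, m_sem[keep]))
        devs_ode[name] = float(
            np.max(np.abs(m_mean[keep] - ode[name][keep]) / w_ode)
        )
    frac = within / total
    return ValidationReport(
        passed=frac >= 0.95,
        frac_within=frac,
        max_dev_vs_data=devs_data,
        max_dev_vs_ode=devs_ode,
        n_repeats=n_repeats,
        seed=seed,
    )


@dataclass
class CrossConcentrationReport:
    """Consistency of fits across initial concentrations.

    ``single_fits`` are per-dataset fits, ``joint_fit`` shares one parameter
    set across all datasets.  ``kf_relative_spread`` is
    (max - min)/mean of the single-fit k_f values; ``scaled_curves`` holds
    (scaled time k_f c t, n_cluster / N) pairs per dataset for the
    master-curve collapse diagnostic.
    """

    single_fits: list[FitResult]
    joint_fit: FitResult
    kf_values: list[float]
    kf_relative_spread: float
    scaled_curves: list[tuple[np.ndarray, np.ndarray]]


def _joint_fit(
    datasets: list[ObservableSet], family: str, scale: str, n_starts: int
) -> FitResult:
    names = FAMILY_PARAMS[family]
    free = list(names)
    lo = np.array([DEFAULT_BOUNDS[p][0] for p in free])
    hi = np.array([DEFAULT_BOUNDS[p][1] for p in free])
    n_eval = 0

    def residuals(z: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        zc = np.clip(z, np.log(lo), np.log(hi))
        params = {p: float(np.exp(v)) for p, v in zip(free, zc)}
        parts = []
        for ds in datasets:
            pred = predict_observables(family, params, ds.N, ds.V, ds.times)
            parts.append(_residual_vector(ds, pred, scale=scale))
        return np.concatenate(parts)

    n_points = sum(
        len(_residual_vector(ds, {k: ds.data[k][0] for k in ds.names}))
        for ds in datasets
    )
    m = len(free)
    best = None
    for z0 in _log_starts(lo, hi, n_starts):
        nm = optimize.minimize(
            lambda z: float(residuals(z) @ residuals(z)),
            z0,
            method="Nelder-Mead",
            options={"maxfev": 150 * m},
        )
        ls = optimize.least_squares(
            residuals,
            np.clip(nm.x, np.log(lo), np.log(hi)),
            bounds=(np.log(lo), np.log(hi)),
            method="trf",
        )
        cand = (float(ls.cost * 2.0), ls)
        if best is None or cand[0] < best[0]:
            best = cand
    chi2, ls = best
    params = {p: float(np.exp(v)) for p, v in zip(free, ls.x)}
    nu = n_points - m
    return FitResult(
        family=family,
        params=params,
        stderr={},
        chi2=chi2,
        nu=nu,
        chi2_reduced=chi2 / nu,
        converged=bool(ls.success),
        n_eval=n_eval,
        message=str(ls.message),
    )


def cross_concentration_check(
    datasets: list[ObservableSet],
    family: str = "constant",
    scale: str = "none",
    n_starts: int = 5,
) -> CrossConcentrationReport:
    """Fit each dataset separately and jointly across concentrations.

    If the kernels really are concentration-independent the single-fit
    ``k_f`` values agree within uncertainty and the joint fit is as good as
    the single fits; a concentration-dependent rate shows up as a large
    ``k_f`` spread and a degraded joint chi2_nu.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets at different concentrations")
    singles = [
        fit_model(ds, family, scale=scale, n_starts=n_starts) for ds in datasets
    ]
    joint = _joint_fit(datasets, family, scale, n_starts)
    kfs = [f.params["k_f"] for f in singles]
    spread = (max(kfs) - min(kfs)) / np.mean(kfs)
    curves = []
    for ds, f in zip(datasets, singles):
        c = ds.concentration
        ncl = ds.data["clusters"][0] if "clusters" in ds.data else None
        if ncl is not None:
            curves.append((f.params["k_f"] * c * ds.times, ncl / ds.N))
    return CrossConcentrationReport(
        single_fits=singles,
        joint_fit=joint,
        kf_values=kfs,
        kf_relative_spread=float(spread),
        scaled_curves=curves,
    )
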