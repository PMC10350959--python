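"""Reduced-chi-square fitting, nesting, validation, cross-concentration."""

import numpy as np
import pytest

from aggfrag import (
    ObservableSet,
    SyntheticSpec,
    chi_square,
    cross_concentration_check,
    fit_model,
    generate_observables,
    validate_fit,
)
from aggfrag.fitting import FitResult, predict_observables


def _toy_observables(offset_sem=0.0):
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    mean = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    sem = np.full(5, 0.5)
    return ObservableSet(
        times=times, data={"monomers": (mean + offset_sem * sem, sem)}, N=5, V=1.0
    )


def test_chi_square_perfect_and_one_sigma():
    data = _toy_observables()
    perfect = {"monomers": data.data["monomers"][0].copy()}
    chi2, chi2r = chi_square(data, perfect, m_params=1)
    assert chi2 == 0.0
    off = _toy_observables(offset_sem=1.0)
    chi2, chi2r = chi_square(off, perfect, m_params=1)
    assert chi2 == pytest.approx(5.0)
    assert chi2r == pytest.approx(5.0 / 4.0)


def test_chi_square_requires_degrees_of_freedom():
    data = _toy_observables()
    pred = {"monomers": data.data["monomers"][0]}
    with pytest.raises(ValueError):
        chi_square(data, pred, m_params=5)


@pytest.fixture(scope="module")
def bt_dataset():
    """Small reversible synthetic dataset, modest repeats."""
    spec = SyntheticSpec(
        family="blatz_tobolsky",
        params={"k_f": 1.0, "k_b": 0.8},
        N=20,
        V=20.0,
        n_repeats=60,
        t_max=5.0,
        n_grid=26,
        seed=5,
    )
    return generate_observables(spec)


def test_noiseless_self_fit_recovers_rate():
    """Fitting the model to its own prediction recovers k_f essentially
    exactly (1% SEM floor on every point)."""
    N, V = 20, 20.0
    times = np.linspace(0.0, 5.0, 26)
    k_true = 1.7
    pred = predict_observables("constant", {"k_f": k_true}, N, V, times)
    data = ObservableSet(
        times=times,
        data={
            name: (pred[name], 0.01 * np.max(np.abs(pred[name])) * np.ones_like(times))
            for name in ("monomers", "dimers", "trimers", "clusters")
        },
        N=N,
        V=V,
    )
    fit = fit_model(data, "constant")
    assert fit.converged
    assert fit.params["k_f"] == pytest.approx(k_true, rel=1e-4)
    assert fit.chi2 < 1e-8


def test_nested_models_reduce_exactly(bt_dataset):
    bt = fit_model(bt_dataset, "blatz_tobolsky")
    three_fixed = fit_model(bt_dataset, "three_param", fixed={"q": 1.0})
    assert three_fixed.params["k_f"] == pytest.approx(bt.params["k_f"], rel=1e-12)
    assert three_fixed.params["k_b"] == pytest.approx(bt.params["k_b"], rel=1e-12)
    assert three_fixed.chi2 == pytest.approx(bt.chi2, rel=1e-12)
    const = fit_model(bt_dataset, "constant")
    bt_fixed = fit_model(bt_dataset, "blatz_tobolsky", fixed={"k_b": 0.0})
    assert bt_fixed.params["k_f"] == pytest.approx(const.params["k_f"], rel=1e-12)
    assert bt_fixed.chi2 == pytest.approx(const.chi2, rel=1e-12)


def test_reversible_fit_recovers_truth_within_errors(bt_dataset):
    fit = fit_model(bt_dataset, "blatz_tobolsky")
    assert fit.converged
    assert fit.nu == len(bt_dataset.times[1:]) * 4 - 2
    assert fit.chi2_reduced == pytest.approx(fit.chi2 / fit.nu)
    # modest-repeat data: truth within ~4 combined uncertainties
    for name, truth in [("k_f", 1.0), ("k_b", 0.8)]:
        err = max(fit.stderr[name], 0.02 * truth)
        assert abs(fit.params[name] - truth) < 5 * err


def test_validation_detects_corrupted_parameters(bt_dataset):
    fit = fit_model(bt_dataset, "blatz_tobolsky")
    good = validate_fit(fit, bt_dataset, n_repeats=200, seed=9)
    assert good.passed
    again = validate_fit(fit, bt_dataset, n_repeats=200, seed=9)
    assert again.max_dev_vs_data == good.max_dev_vs_data  # seed-reproducible
    corrupted = FitResult(
        family=fit.family,
        params={**fit.params, "k_f": 2.0 * fit.params["k_f"]},
        stderr=fit.stderr,
        chi2=fit.chi2,
        nu=fit.nu,
        chi2_reduced=fit.chi2_reduced,
        converged=True,
        n_eval=0,
        message="corrupted",
    )
    bad = validate_fit(corrupted, bt_dataset, n_repeats=200, seed=9)
    assert not bad.passed


def test_validation_refuses_unconverged_fit(bt_dataset):
    dud = FitResult(
        family="constant",
        params={"k_f": 1.0},
        stderr={},
        chi2=1.0,
        nu=1,
        chi2_reduced=1.0,
        converged=False,
        n_eval=0,
        message="",
    )
    with pytest.raises(ValueError):
        validate_fit(dud, bt_dataset)


def test_cross_concentration_requires_two_datasets(bt_dataset):
    with pytest.raises(ValueError):
        cross_concentration_check([bt_dataset])


def test_cross_concentration_null_and_failure_modes():
    """Datasets from one concentration-independent model are consistent
    under joint fitting; a concentration-dependent rate makes the single
    fits stay good while the joint fit degrades sharply."""
    import dataclasses

    from aggfrag import generate_two_concentration_suite

    spec = SyntheticSpec(
        family="constant",
        params={"k_f": 1.0},
        N=72,
        V=72.0,
        n_repeats=6,
        t_max=5.0,
        n_grid=41,
        seed=23,
    )
    a, b = generate_two_concentration_suite(spec, c_ratio=2.0)
    null = cross_concentration_check([a, b], family="constant", n_starts=2)
    sigma = np.hypot(*(f.stderr["k_f"] for f in null.single_fits))
    assert abs(null.kf_values[0] - null.kf_values[1]) < 4 * sigma
    assert null.joint_fit.chi2_reduced < 2.0

    hooked = dataclasses.replace(spec, kf_of_c=lambda c: c)  # k_f grows with c
    a2, b2 = generate_two_concentration_suite(hooked, c_ratio=2.0)
    bad = cross_concentration_check([a2, b2], family="constant", n_starts=2)
    assert bad.kf_values[1] / bad.kf_values[0] == pytest.approx(2.0, rel=0.15)
    assert bad.joint_fit.chi2_reduced > 2.0 * max(
        f.chi2_reduced for f in bad.single_fits
    )
    for fit in bad.single_fits:
        assert fit.chi2_reduced < 3.0  # single-concentration fits stay good


def test_cross_concentration_identical_dataset_is_consistent(bt_dataset):
    report = cross_concentration_check(
        [bt_dataset, bt_dataset], family="blatz_tobolsky", n_starts=2
    )
    assert report.kf_relative_spread == pytest.approx(0.0, abs=1e-12)
    assert report.joint_fit.chi2_reduced <= 1.05 * max(
        f.chi2_reduced for f in report.single_fits
    )
    assert len(report.scaled_curves) == 2
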