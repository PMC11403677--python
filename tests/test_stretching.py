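"""Stretching model: closed forms, energetics oracle, coverage map, fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from bilayermech.errors import InvalidParameterError, UnderdeterminedFitError
from bilayermech.stretching import (
    CoverageModel,
    MembraneModel,
    TensionCurveModel,
    TensionSeries,
    cell_free_energy,
    control_parameter_zeta,
    equilibrium_wrapping,
    fit_tension_series,
    fit_tension_table,
    langmuir_coverage,
    predict_tension,
    tension_increase,
)
from bilayermech.synthetic import gen_tension_series


def brute_force_wrapping(zeta, phi, n_grid=2001):
    """Independent oracle: grid scan of the cell free energy plus refinement.

    The closed-form expression under test is not used here; the minimum is
    located by direct evaluation and a bounded scalar minimization, with
    the interval endpoints compared explicitly so boundary optima are exact.
    """
    u = np.linspace(0.0, 1.0, n_grid)
    f = cell_free_energy(u, zeta, phi, 200.0)
    i = int(np.argmin(f))
    lo, hi = max(u[i] - 2 / n_grid, 0.0), min(u[i] + 2 / n_grid, 1.0)
    res = minimize_scalar(
        lambda v: cell_free_energy(v, zeta, phi, 200.0),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-13},
    )
    candidates = [0.0, 1.0, float(res.x)]
    vals = [cell_free_energy(v, zeta, phi, 200.0) for v in candidates]
    return candidates[int(np.argmin(vals))]


def test_zeta_ratio_values():
    assert control_parameter_zeta(1.0, 100.0) == pytest.approx(-0.01)
    assert control_parameter_zeta(1.0, 300.0) == pytest.approx(-1.0 / 300.0)
    assert control_parameter_zeta(0.0, 200.0) == 0.0


def test_zeta_rejects_bad_modulus():
    with pytest.raises(InvalidParameterError):
        control_parameter_zeta(1.0, 0.0)


def test_free_energy_hand_value():
    # adhesion gain -2*200*0.01*0.1*0.5 = -0.2; penalty 100*(0.1*0.25)^2 = 0.0625
    assert cell_free_energy(0.5, -0.01, 0.1, 200.0) == pytest.approx(-0.1375)


def test_free_energy_limits():
    assert cell_free_energy(0.0, -0.05, 0.3, 200.0) == 0.0
    # no adhesion: any contact is pure stretching penalty
    assert cell_free_energy(0.4, 0.0, 0.3, 200.0) > 0.0


def test_equilibrium_wrapping_closed_form():
    st_ = equilibrium_wrapping(-0.01, 0.1)
    # stationarity u^3 = |zeta|/phi = 0.1
    assert st_.wrap_fraction_u == pytest.approx(0.4641588833612779, rel=1e-9)
    assert st_.alpha == pytest.approx(0.021544346900318842, rel=1e-9)
    assert st_.adsorption_point_density == pytest.approx(1 / 1.021544346900318842, rel=1e-9)


def test_equilibrium_wrapping_boundaries():
    st_ = equilibrium_wrapping(0.0, 0.5)
    assert st_.wrap_fraction_u == 0.0 and st_.alpha == 0.0
    st_ = equilibrium_wrapping(-0.1, 0.05)  # phi <= |zeta|: hemisphere clamp
    assert st_.wrap_fraction_u == 1.0
    assert st_.alpha == pytest.approx(0.05)
    with pytest.raises(InvalidParameterError):
        equilibrium_wrapping(-0.01, 0.0)


def test_wrapping_matches_energy_minimization():
    """Closed form agrees with brute-force minimization of the free energy."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        zeta = -(10.0 ** rng.uniform(-4, 0))
        phi = 10.0 ** rng.uniform(-3, 0)
        u_closed = equilibrium_wrapping(zeta, phi).wrap_fraction_u
        u_brute = brute_force_wrapping(zeta, phi)
        assert abs(u_closed - u_brute) < 1e-8


def test_tension_increase_values_and_continuity():
    assert tension_increase(-0.01, 0.1, 200.0) == pytest.approx(4.308869380063768)
    assert tension_increase(-0.05, 0.0, 200.0) == 0.0
    # both branches at the clamp boundary phi = |zeta| give k*phi
    at_boundary = tension_increase(-0.01, 0.01, 200.0)
    assert at_boundary == pytest.approx(2.0)
    eps = 1e-9
    assert tension_increase(-0.01, 0.01 + eps, 200.0) == pytest.approx(2.0, abs=1e-5)
    assert tension_increase(-0.01, 0.01 - eps, 200.0) == pytest.approx(2.0, abs=1e-5)


@given(
    zeta1=st.floats(-0.2, -1e-4),
    dz=st.floats(1e-4, 0.1),
    phi1=st.floats(1e-3, 0.9),
    dphi=st.floats(1e-3, 0.1),
)
def test_tension_increase_monotonicity(zeta1, dz, phi1, dphi):
    """dGamma grows with adhesion magnitude and with coverage."""
    k = 200.0
    assert tension_increase(zeta1 - dz, phi1, k) >= tension_increase(zeta1, phi1, k)
    assert tension_increase(zeta1, min(phi1 + dphi, 1.0), k) >= tension_increase(
        zeta1, phi1, k
    )


def test_langmuir_coverage():
    m = CoverageModel(phi_max=0.8, K_half=100.0)
    assert langmuir_coverage(0.0, m) == 0.0
    assert langmuir_coverage(100.0, m) == pytest.approx(0.4)   # half saturation
    assert langmuir_coverage(1e9, m) == pytest.approx(0.8, rel=1e-6)
    with pytest.raises(InvalidParameterError):
        langmuir_coverage(-1.0, m)


def test_predict_tension_intercept_and_saturation():
    mem = MembraneModel(k=200.0, zeta=-0.01, gamma0=1.7)
    cov = CoverageModel(phi_max=1.0, K_half=120.0)
    assert predict_tension(0.0, mem, cov) == pytest.approx(1.7)
    # saturation with phi_max = 1: Gamma0 + k * |zeta|^(2/3)
    assert predict_tension(1e12, mem, cov) == pytest.approx(
        1.7 + 200.0 * 0.01 ** (2 / 3), rel=1e-6
    )
    c = np.array([0.0, 50.0, 150.0, 500.0])
    assert np.all(np.diff(predict_tension(c, mem, cov)) >= 0)


def test_membrane_model_consistency():
    m = MembraneModel(k=100.0, eps_n0=1.0)
    assert m.zeta == pytest.approx(-0.01)
    m = MembraneModel(k=100.0, zeta=-0.01)
    assert m.eps_n0 == pytest.approx(1.0)
    with pytest.raises(InvalidParameterError):
        MembraneModel(k=100.0, eps_n0=1.0, zeta=-0.02)
    with pytest.raises(InvalidParameterError):
        MembraneModel(k=100.0, zeta=0.5)


def test_fit_recovers_generating_zeta():
    series = gen_tension_series(
        zeta=-0.05, K_half=120.0, gamma0=1.7, k=200.0, noise_sigma=0.2, seed=1
    )
    fit = fit_tension_series(series)
    assert fit.zeta_hat <= 0
    assert abs(fit.zeta_hat - (-0.05)) / 0.05 < 0.10
    assert fit.chi2_reduced >= 0
    assert fit.predicted_curve(0.0) == pytest.approx(series.gamma_bilayer[0])


def test_fit_rejects_underdetermined_series():
    s = TensionSeries("x", "y", [0.0, 50.0, 100.0], [1.7, 2.0, 2.2], [0.2, 0.2, 0.2])
    with pytest.raises(UnderdeterminedFitError):
        fit_tension_series(s)


def test_estimator_sklearn_protocol():
    est = TensionCurveModel(k=150.0)
    params = est.get_params()
    assert params["k"] == 150.0
    est.set_params(k=250.0)
    series = gen_tension_series(
        zeta=-0.03, K_half=100.0, gamma0=1.7, k=250.0, noise_sigma=0.1, seed=3
    )
    est.fit(series.concentrations, series.gamma_bilayer, series.errors)
    assert est.zeta_ <= 0 and est.K_half_ > 0
    pred = est.predict([0.0, 500.0])
    assert pred[1] >= pred[0]


def test_shared_coverage_joint_fit_recovers_common_K():
    """Two series generated at one K and different zeta: the joint fit
    recovers the shared half-saturation and preserves the adhesion order."""
    weak = gen_tension_series(-0.01, 120.0, 1.7, noise_sigma=0.1, seed=11)
    strong = gen_tension_series(-0.05, 120.0, 1.7, noise_sigma=0.1, seed=12)
    res = fit_tension_table({"weak": weak, "strong": strong})
    assert abs(res.zeta_hats["strong"]) > abs(res.zeta_hats["weak"])
    assert res.K_shared == pytest.approx(120.0, rel=0.5)
    assert res.zeta_hats["strong"] == pytest.approx(-0.05, rel=0.25)
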