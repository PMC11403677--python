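"""Pendant-drop shape integration, tension fitting, and plateau detection."""

import numpy as np
import pytest

from bilayermech.errors import (
    InvalidParameterError,
    NoPlateauError,
    UnidentifiableTensionError,
)
from bilayermech.pendant import (
    DropletProfile,
    TensionTimeTrace,
    bond_number,
    fit_profile,
    integrate_young_laplace,
    plateau_tension,
)
from bilayermech.synthetic import gen_droplet_profile


def test_zero_gravity_profile_is_spherical():
    """With no density contrast the contour is a circle of radius b."""
    prof = integrate_young_laplace(2.0, 1.0, delta_rho=0.0, arc_span=2.5)
    r = np.hypot(prof.points[:, 0], prof.points[:, 1] - 1.0)
    assert np.max(np.abs(r - 1.0)) < 1e-6


def test_apex_boundary_condition():
    """Mean curvature at the apex equals 2/b for a deformed drop."""
    prof = integrate_young_laplace(
        2.0, 1.0, delta_rho=140.0, arc_span=0.01, n_points=2000
    )
    # osculating circle with center on the symmetry axis through the apex arc
    pts = prof.points[1:30]
    A = np.column_stack([2 * pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, pts[:, 0] ** 2 + pts[:, 1] ** 2, rcond=None)
    b_est = np.sqrt(coef[1] + coef[0] ** 2)
    assert 2.0 / b_est == pytest.approx(2.0, rel=1e-4)


def test_invalid_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        integrate_young_laplace(-2.0, 1.0)
    with pytest.raises(InvalidParameterError):
        integrate_young_laplace(2.0, 0.0)
    with pytest.raises(InvalidParameterError):
        integrate_young_laplace(2.0, 1.0, n_points=5)


def test_profile_truncates_at_closure():
    """A long arc request on a high-Bond drop stops where the contour closes."""
    with pytest.warns(UserWarning):
        prof = integrate_young_laplace(1.0, 1.5, delta_rho=500.0, arc_span=12.0)
    assert prof.truncated
    assert len(prof.points) == 200


@pytest.mark.parametrize(
    "gamma, b, delta_rho",
    [(2.0, 1.0, 140.0), (10.0, 1.5, 400.0), (1.0, 0.6, 100.0)],
)
def test_round_trip_recovers_tension(gamma, b, delta_rho):
    """Noiseless generate-then-fit recovers gamma and b within 0.5%."""
    prof = integrate_young_laplace(gamma, b, delta_rho=delta_rho, arc_span=2.5 * b)
    res = fit_profile(prof)
    assert res.converged
    assert res.gamma == pytest.approx(gamma, rel=5e-3)
    assert res.apex_radius_b == pytest.approx(b, rel=5e-3)
    assert res.residual_rms < 1e-4 * b


def test_noisy_recovery_median_within_3_percent():
    errs = []
    for seed in range(10):
        prof = gen_droplet_profile(
            2.0, 1.2, delta_rho=140.0, coord_noise_um=2.0, seed=seed
        )
        errs.append(abs(fit_profile(prof).gamma - 2.0) / 2.0)
    assert np.median(errs) < 0.03


def test_zero_density_contrast_unidentifiable():
    prof = integrate_young_laplace(2.0, 1.0, delta_rho=0.0, arc_span=2.5)
    with pytest.raises(UnidentifiableTensionError):
        fit_profile(prof, delta_rho=0.0)


def test_scale_covariance_of_shape_family():
    """Scaling lengths by lam and gamma by lam^2 rescales the contour and
    leaves the Bond number unchanged."""
    lam = 1.7
    p1 = integrate_young_laplace(2.0, 1.0, delta_rho=140.0, arc_span=2.0)
    p2 = integrate_young_laplace(
        2.0 * lam**2, lam, delta_rho=140.0, arc_span=2.0 * lam
    )
    assert bond_number(2.0, 1.0, 140.0) == pytest.approx(
        bond_number(2.0 * lam**2, lam, 140.0), rel=1e-12
    )
    assert np.allclose(p2.points, lam * p1.points, atol=1e-8)


def test_profile_validation():
    with pytest.raises(InvalidParameterError):
        DropletProfile(points=np.zeros((5, 2)))  # too few points
    bad = np.column_stack([np.linspace(-0.1, 1, 30), np.linspace(0, 1, 30)])
    with pytest.raises(InvalidParameterError):
        DropletProfile(points=bad)  # negative x


def test_plateau_constant_trace():
    t = np.linspace(0, 100, 50)
    res = plateau_tension(TensionTimeTrace(times=t, gamma_values=np.full(50, 2.0)))
    assert res.value == pytest.approx(2.0)
    assert res.start_time == t[0]


def test_plateau_exponential_relaxation():
    """3 -> 2 mN/m with tau = 100 s over 1000 s: plateau within 2% of 2.0."""
    t = np.linspace(0, 1000, 500)
    trace = TensionTimeTrace(times=t, gamma_values=2.0 + np.exp(-t / 100.0))
    res = plateau_tension(trace)
    assert res.value == pytest.approx(2.0, rel=0.02)
    assert trace.plateau_value == res.value
    assert res.start_time > 0


def test_plateau_absent_on_linear_drift():
    t = np.linspace(0, 100, 50)
    trace = TensionTimeTrace(times=t, gamma_values=3.0 - 0.01 * t)
    with pytest.raises(NoPlateauError):
        plateau_tension(trace)


def test_plateau_requires_three_windows():
    t = np.linspace(0, 10, 30)
    trace = TensionTimeTrace(times=t, gamma_values=np.full(30, 2.0))
    with pytest.raises(InvalidParameterError):
        plateau_tension(trace, window=6.0)
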