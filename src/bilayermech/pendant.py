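"""Pendant-drop tensiometry: Young-Laplace profiles and their inverse problem.

A pendant drop hanging from a needle in a second, lighter fluid adopts the
axisymmetric shape that balances capillary pressure against hydrostatics.
With the apex placed at the origin and ``z`` increasing from the apex toward
the needle, the mean curvature at height ``z`` is ``2/b - (delta_rho * g / gamma) * z``
where ``b`` is the radius of curvature at the apex.  In arc-length form, with
lengths scaled by ``b``, the shape satisfies

    dx/ds   = cos(phi)
    dz/ds   = sin(phi)
    dphi/ds = 2 - Bo * z - sin(phi) / x,      Bo = delta_rho * g * b**2 / gamma

``Bo`` is the Bond number: the ratio of gravitational deformation to
capillary restoring force.  ``Bo = 0`` gives a sphere of radius ``b``;
increasing ``Bo`` elongates and eventually necks the drop.  Fitting a
measured contour with this family of shapes yields the interfacial tension
``gamma`` -- the working principle of drop-shape tensiometers.

Units follow the instrument conventions: lengths in mm, tensions in mN/m,
density difference in kg/m^3, gravity in m/s^2.  With these units
``Bo = delta_rho * g * b**2 * 1e-3 / gamma``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import (
    InvalidParameterError,
    NoPlateauError,
    UnidentifiableTensionError,
)

__all__ = [
    "DropletProfile",
    "PendantFitResult",
    "TensionTimeTrace",
    "PlateauResult",
    "bond_number",
    "integrate_young_laplace",
    "PendantDropFitter",
    "fit_profile",
    "plateau_tension",
]

#: Default density contrast, kg/m^3: water (~1000) against squalene (~858).
DELTA_RHO_DEFAULT = 140.0
GRAVITY_DEFAULT = 9.81

_MM_PER_M_TENSION = 1e-3  # converts kg/m^3 * m/s^2 * mm^2 / (mN/m) to dimensionless


def bond_number(gamma: float, apex_radius_b: float, delta_rho: float,
                gravity: float = GRAVITY_DEFAULT) -> float:
    """Bond number ``delta_rho * g * b^2 / gamma`` (dimensionless).

    ``gamma`` in mN/m, ``apex_radius_b`` in mm, ``delta_rho`` in kg/m^3.
    """
    if gamma <= 0:
        raise InvalidParameterError("gamma must be positive")
    return delta_rho * gravity * apex_radius_b**2 * _MM_PER_M_TENSION / gamma


@dataclass
class DropletProfile:
    """Ordered apex-first contour of an axisymmetric pendant drop.

    ``points`` is an (n, 2) array of (x, z) coordinates in mm with the apex
    at the first row; ``x >= 0`` (one meridian half of the symmetric
    contour) and ``z`` nondecreasing from apex to needle.
    """

    points: np.ndarray
    delta_rho: float = DELTA_RHO_DEFAULT
    gravity: float = GRAVITY_DEFAULT
    needle_radius: float | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidParameterError("points must be an (n, 2) array")
        if pts.shape[0] < 20:
            raise InvalidParameterError("a droplet profile needs at least 20 points")
        if np.any(pts[:, 0] < 0):
            raise InvalidParameterError("x coordinates must be nonnegative")
        z = pts[:, 1]
        z_range = float(z.max() - z.min())
        # allow small non-monotonicity from localization noise, not gross disorder
        if z_range > 0 and np.any(np.diff(z) < -0.02 * z_range):
            raise InvalidParameterError(
                "z must be (approximately) nondecreasing from the apex"
            )
        self.points = pts

    @property
    def arc_length(self) -> float:
        """Total polyline length of the contour, mm."""
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


@dataclass
class PendantFitResult:
    """Outcome of a Young-Laplace shape fit."""

    gamma: float                 # interfacial tension, mN/m
    apex_radius_b: float         # apex radius of curvature, mm
    bond_number: float           # delta_rho*g*b^2/gamma, dimensionless
    residual_rms: float          # RMS point-to-curve distance, mm
    converged: bool
    apex_offset: float = 0.0     # fitted z-shift of the apex, mm
    message: str = ""


@dataclass
class TensionTimeTrace:
    """Interfacial tension versus time during a pendant-drop measurement."""

    times: np.ndarray            # s, strictly increasing
    gamma_values: np.ndarray     # mN/m
    plateau_value: float | None = None
    plateau_start: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.gamma_values, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise InvalidParameterError("times and gamma_values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        self.times, self.gamma_values = t, g


class PlateauResult(NamedTuple):
    value: float        # mN/m
    start_time: float   # s


def _shape_rhs(s: float, y: np.ndarray, bo: float) -> list[float]:
    x, z, phi = y
    sin_phi = np.sin(phi)
    # sin(phi)/x -> curvature 1 at the apex; x>0 always holds on the orbit
    azim = sin_phi / x if x > 1e-12 else 1.0
    return [np.cos(phi), sin_phi, 2.0 - bo * z - azim]


def _integrate_dimensionless(bo: float, s_max: float, n_points: int,
                             rtol: float = 1e-10, atol: float = 1e-12):
    """Integrate the shape equations in apex-radius units up to arc s_max.

    Returns (points (n,2), truncated flag).  Integration stops early when the
    contour closes back onto the axis (x -> 0) or folds past phi = pi.
    """
    s0 = 1e-8
    y0 = [s0, 0.5 * s0**2, s0]  # spherical series expansion about the apex

    def hit_axis(s, y, bo):
        return y[0] - 1e-12

    def folded(s, y, bo):
        return y[2] - np.pi

    def descending(s, y, bo):
        # tangent angle returning through zero: z would start decreasing
        return y[2]

    hit_axis.terminal, hit_axis.direction = True, -1.0
    folded.terminal, folded.direction = True, 1.0
    descending.terminal, descending.direction = True, -1.0

    sol = solve_ivp(
        _shape_rhs, (s0, s_max), y0, args=(bo,), method="RK45",
        rtol=rtol, atol=atol, dense_output=True,
        events=[hit_axis, folded, descending], max_step=s_max / 10,
    )
    s_end = sol.t[-1]
    truncated = s_end < s_max * (1 - 1e-9)
    s_eval = np.linspace(s0, s_end, n_points - 1)
    xz = sol.sol(s_eval)[:2].T
    pts = np.vstack([[0.0, 0.0], xz])
    return pts, truncated


def integrate_young_laplace(
    gamma: float,
    apex_radius_b: float,
    delta_rho: float = DELTA_RHO_DEFAULT,
    gravity: float = GRAVITY_DEFAULT,
    arc_span: float | None = None,
    n_points: int = 200,
) -> DropletProfile:
    """Generate the pendant-drop contour for given tension and apex radius.

    Parameters
    ----------
    gamma : float
        Interfacial tension, mN/m (> 0).
    apex_radius_b : float
        Radius of curvature at the apex, mm (> 0); the apex mean curvature
        is ``2 / apex_radius_b``.
    arc_span : float, optional
        Arc length to integrate, mm; defaults to ``3 * apex_radius_b``.
        If the profile closes earlier the contour is truncated there and
        flagged via :attr:`DropletProfile.truncated`.
    """
    if gamma <= 0 or apex_radius_b <= 0:
        raise InvalidParameterError("gamma and apex_radius_b must be positive")
    if n_points < 20:
        raise InvalidParameterError("n_points must be at least 20")
    b = float(apex_radius_b)
    if arc_span is None:
        arc_span = 3.0 * b
    bo = bond_number(gamma, b, delta_rho, gravity)
    pts, truncated = _integrate_dimensionless(bo, arc_span / b, n_points)
    if truncated:
        warnings.warn(
            "profile closed before the requested arc span; contour truncated",
            stacklevel=2,
        )
    return DropletProfile(
        points=b * pts, delta_rho=delta_rho, gravity=gravity, truncated=truncated
    )


def _distance_to_polyline(pts: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to a polyline (vectorized)."""
    tree = cKDTree(curve)
    _, idx = tree.query(pts)
    n = len(curve)
    best = np.full(len(pts), np.inf)
    for lo in (idx - 1, idx):
        a_i = np.clip(lo, 0, n - 2)
        a, bseg = curve[a_i], curve[a_i + 1]
        ab = bseg - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", pts - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        best = np.minimum(best, np.hypot(*(pts - proj).T))
    return best


class PendantDropFitter(BaseEstimator):
    """Least-squares Young-Laplace shape fit of a pendant-drop contour.

    Follows the scikit-learn estimator protocol: construct with the physical
    configuration, then :meth:`fit` an (n, 2) contour (x, z in mm,
    apex-first).  The fitted interfacial tension and shape parameters are
    exposed as trailing-underscore attributes.

    Parameters
    ----------
    delta_rho : float
        Density difference between drop and surrounding phase, kg/m^3.
        Must be nonzero: a weightless drop is spherical at any tension and
        carries no tension information.
    gravity : float
        Gravitational acceleration, m/s^2.
    initial_guess : tuple (gamma, b), optional
        Starting point; when given, the multi-start over Bond numbers is
        skipped.
    n_starts : int
        Number of trial Bond numbers (log-spaced in [0.05, 1.5]) screened
        before the local optimization.
    curve_points : int
        Resolution of the model contour used for point-to-curve distances.

    Attributes
    ----------
    gamma_ : float
        Fitted interfacial tension, mN/m.
    apex_radius_b_ : float
        Fitted apex radius, mm.
    bond_number_ : float
    residual_rms_ : float
        RMS point-to-curve distance, mm.
    converged_ : bool
    result_ : PendantFitResult
    """

    def __init__(
        self,
        delta_rho: float = DELTA_RHO_DEFAULT,
        gravity: float = GRAVITY_DEFAULT,
        initial_guess: tuple[float, float] | None = None,
        n_starts: int = 5,
        curve_points: int = 400,
    ):
        self.delta_rho = delta_rho
        self.gravity = gravity
        self.initial_guess = initial_guess
        self.n_starts = n_starts
        self.curve_points = curve_points

    # -- internals ---------------------------------------------------------

    def _model_curve(self, gamma: float, b: float, arc_mm: float) -> np.ndarray:
        bo = self.delta_rho * self.gravity * b**2 * _MM_PER_M_TENSION / gamma
        # looser ODE tolerance than the generator: discretization of the
        # model polyline, not integration error, limits the fit accuracy
        pts, _ = _integrate_dimensionless(bo, max(arc_mm / b, 0.1),
                                          self.curve_points, rtol=1e-8, atol=1e-10)
        return b * pts

    def _residuals(self, params: np.ndarray, data: np.ndarray, arc_mm: float) -> np.ndarray:
        gamma, b, z0 = params
        if gamma <= 0 or b <= 0:
            return np.full(len(data), 1e3)
        curve = self._model_curve(gamma, b, arc_mm)
        shifted = data.copy()
        shifted[:, 1] -= z0
        return _distance_to_polyline(shifted, curve)

    @staticmethod
    def _apex_circle(data: np.ndarray) -> tuple[float, float]:
        """Estimate apex radius and apex z-position from the lowest contour arc.

        Fits a circle with its center constrained to the symmetry axis:
        x^2 + z^2 = 2 c z + (r^2 - c^2), linear in (c, r^2 - c^2).
        """
        m = max(10, len(data) // 4)
        x, z = data[:m, 0], data[:m, 1]
        A = np.column_stack([2 * z, np.ones(m)])
        coef, *_ = np.linalg.lstsq(A, x**2 + z**2, rcond=None)
        c, k = coef
        r2 = k + c**2
        if r2 <= 0:
            r = float(np.max(data[:, 0])) or 1.0
            return r, float(data[0, 1])
        r = float(np.sqrt(r2))
        return r, float(c - r)

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None) -> "PendantDropFitter":
        """Fit the Young-Laplace shape family to a contour.

        ``X`` may be a :class:`DropletProfile` or an (n, 2) array of
        (x, z) mm coordinates, apex-first.
        """
        if isinstance(X, DropletProfile):
            data = X.points
        else:
            data = np.asarray(X, dtype=float)
            DropletProfile(points=data, delta_rho=self.delta_rho, gravity=self.gravity)
        if self.delta_rho == 0:
            raise UnidentifiableTensionError(
                "delta_rho = 0: drop shape is spherical at any tension; "
                "gamma is not identifiable from shape"
            )

        arc_mm = float(np.sum(np.hypot(*np.diff(data, axis=0).T))) * 1.25
        b0, z00 = self._apex_circle(data)

        if self.initial_guess is not None:
            g0, b_init = self.initial_guess
            starts = [(float(g0), float(b_init), 0.0)]
        else:
            bonds = np.geomspace(0.05, 1.5, self.n_starts)
            cands = []
            for bo in bonds:
                g_c = self.delta_rho * self.gravity * b0**2 * _MM_PER_M_TENSION / bo
                r = self._residuals(np.array([g_c, b0, z00]), data, arc_mm)
                cands.append((float(np.sqrt(np.mean(r**2))), g_c))
            cands.sort()
            # local optimization from the two best screened Bond numbers
            starts = [(g_c, b0, z00) for _, g_c in cands[:2]]

        best = None
        for g_c, b_c, z_c in starts:
            res = least_squares(
                self._residuals, x0=[g_c, b_c, z_c], args=(data, arc_mm),
                bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                x_scale=[max(g_c, 1e-3), max(b_c, 1e-3), 0.1],
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=200,
            )
            rms = float(np.sqrt(np.mean(res.fun**2)))
            if best is None or rms < best[0]:
                best = (rms, res)
        rms, res = best

        gamma, b, z0 = res.x
        self.gamma_ = float(gamma)
        self.apex_radius_b_ = float(b)
        self.apex_offset_ = float(z0)
        self.bond_number_ = bond_number(self.gamma_, self.apex_radius_b_,
                                        self.delta_rho, self.gravity)
        self.residual_rms_ = rms
        self.converged_ = bool(res.success and gamma > 0 and b > 0)
        self.result_ = PendantFitResult(
            gamma=self.gamma_,
            apex_radius_b=self.apex_radius_b_,
            bond_number=self.bond_number_,
            residual_rms=self.residual_rms_,
            converged=self.converged_,
            apex_offset=self.apex_offset_,
            message=res.message,
        )
        return self


def fit_profile(
    profile: DropletProfile,
    delta_rho: float | None = None,
    gravity: float | None = None,
    initial_guess: tuple[float, float] | None = None,
) -> PendantFitResult:
    """Fit a droplet contour, returning a :class:`PendantFitResult`.

    Thin functional wrapper around :class:`PendantDropFitter`; ``delta_rho``
    and ``gravity`` default to the values carried by the profile.
    """
    dr = profile.delta_rho if delta_rho is None else delta_rho
    g = profile.gravity if gravity is None else gravity
    est = PendantDropFitter(delta_rho=dr, gravity=g, initial_guess=initial_guess)
    return est.fit(profile).result_


def plateau_tension(
    trace: TensionTimeTrace,
    window: float | None = None,
    slope_tol: float = 1e-3,
) -> PlateauResult:
    """Detect the terminal tension plateau of a measurement trace.

    Scans rolling windows of width ``window`` (default: 10% of the trace
    span) and finds the earliest start time from which every subsequent
    window has linear-slope magnitude below ``slope_tol`` (mN/m per s).
    The plateau value is the mean tension over that terminal segment; the
    drop-shape tensiometer reports exactly this quantity once adsorption
    has equilibrated.

    Raises
    ------
    NoPlateauError
        If even the final window exceeds the slope tolerance.
    """
    t, g = trace.times, trace.gamma_values
    span = t[-1] - t[0]
    if window is None:
        window = 0.1 * span
    if window <= 0 or span < 3 * window:
        raise InvalidParameterError("trace must span at least three windows")

    starts = np.flatnonzero(t + window <= t[-1] + 1e-12 * span)
    slopes = np.empty(len(starts))
    for j, i in enumerate(starts):
        sel = (t >= t[i]) & (t <= t[i] + window)
        if sel.sum() < 2:
            slopes[j] = np.inf
            continue
        slopes[j] = np.polyfit(t[sel], g[sel], 1)[0]
    quiet = np.abs(slopes) < slope_tol
    if not quiet[-1]:
        raise NoPlateauError("no terminal segment satisfies the slope criterion")
    # earliest start from which all remaining windows are quiet
    noisy = np.flatnonzero(~quiet)
    first = starts[noisy[-1] + 1] if len(noisy) else starts[0]
    sel = t >= t[first]
    value = float(np.mean(g[sel]))
    start_time = float(t[first])
    trace.plateau_value = value
    trace.plateau_start = start_time
    return PlateauResult(value=value, start_time=start_time)
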