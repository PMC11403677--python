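"""Elastic membrane-stretching model of microplastic adsorption.

An adhesive sphere of radius ``R`` sitting on a tense lipid bilayer draws
membrane area into a contact cap, stretching the surrounding free membrane.
Per particle, the membrane is divided into an adsorbed cap (wrapping
fraction ``u = 1 - cos(psi)`` of the hemisphere, ``u in [0, 1]``) and a
suspended annulus inside a unit cell of unperturbed area ``S0 = pi R^2 / phi``,
where ``phi`` is the projected area coverage of particles.  The excess area
pulled into the cap imposes a global area strain ``alpha = phi * u**2``, and
the free energy per unit projected cell area is

    f(u) = -2 * k * |zeta| * phi * u  +  (k / 2) * (phi * u**2)**2

i.e. an adhesion gain proportional to the cap area plus the quadratic
area-elasticity penalty ``(k/2) * alpha**2``.  Everything is controlled by
the single dimensionless ratio

    zeta = eps * n0 / k        (stored negative: attraction)

of adhesion energy per area ``eps*n0`` (mJ/m^2, numerically equal to mN/m)
to the area compressibility modulus ``k`` (mN/m; 100-300 mN/m for lipid
bilayers).  Minimizing ``f`` gives the closed-form equilibrium wrapping

    u* = min(1, (|zeta| / phi)**(1/3)),     alpha* = phi * u*^2

and the bilayer tension rises linearly with strain, ``dGamma = k * alpha*``.
Bulk particle concentration maps to coverage through a Langmuir isotherm
``phi(c) = phi_max * c / (K + c)``, closing the chain

    Gamma(c) = Gamma0 + dGamma(zeta, phi(c), k)

whose single shape parameter ``zeta`` (plus the half-saturation ``K``) is
fitted to measured tension-concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidParameterError, UnderdeterminedFitError

__all__ = [
    "MembraneModel",
    "StretchState",
    "CoverageModel",
    "TensionSeries",
    "ZetaFit",
    "control_parameter_zeta",
    "cell_free_energy",
    "equilibrium_wrapping",
    "tension_increase",
    "langmuir_coverage",
    "predict_tension",
    "TensionCurveModel",
    "fit_tension_series",
    "SharedCoverageFit",
    "fit_tension_table",
]

K_DEFAULT = 200.0      # mN/m, midpoint of the 100-300 mN/m bilayer range
GAMMA0_DEFAULT = 1.7   # mN/m, bare-bilayer tension of the DiB system


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """Physical parameter set of the stretching model.

    Exactly one of ``eps_n0`` (adhesion energy per area, mJ/m^2) or ``zeta``
    may be omitted; the other is derived through ``zeta = -eps_n0 / k``.
    """

    k: float = K_DEFAULT              # area compressibility modulus, mN/m
    eps_n0: float | None = None       # adhesion energy per area, mJ/m^2
    zeta: float | None = None         # dimensionless, <= 0
    gamma0: float = GAMMA0_DEFAULT    # baseline bilayer tension, mN/m
    radius_R: float = 0.5             # particle radius, um (bookkeeping only)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidParameterError("compressibility modulus k must be positive")
        if self.gamma0 <= 0:
            raise InvalidParameterError("baseline tension gamma0 must be positive")
        if self.radius_R <= 0:
            raise InvalidParameterError("particle radius must be positive")
        if self.zeta is None and self.eps_n0 is None:
            raise InvalidParameterError("provide eps_n0 or zeta")
        if self.zeta is None:
            self.zeta = control_parameter_zeta(self.eps_n0, self.k)
        elif self.eps_n0 is None:
            if self.zeta > 0:
                raise InvalidParameterError("zeta must be <= 0 (attraction)")
            self.eps_n0 = -self.zeta * self.k
        else:
            if abs(abs(self.zeta) - self.eps_n0 / self.k) > 1e-12:
                raise InvalidParameterError("zeta and eps_n0/k are inconsistent")
        if self.zeta > 0:
            raise InvalidParameterError("zeta must be <= 0 (attraction)")


@dataclass(frozen=True)
class StretchState:
    """Equilibrium wrapping state of the membrane around one particle."""

    wrap_fraction_u: float            # u = 1 - cos(psi), in [0, 1]
    alpha: float                      # area strain (S - S0)/S0 >= 0
    adsorption_point_density: float   # n(r)/n0 = 1/(1 + alpha) <= 1


@dataclass(frozen=True)
class CoverageModel:
    """Langmuir map from bulk concentration to projected surface coverage."""

    phi_max: float = 1.0    # saturation coverage, in (0, 1]
    K_half: float = 100.0   # half-saturation concentration, ug/mL

    def __post_init__(self) -> None:
        if not (0 < self.phi_max <= 1):
            raise InvalidParameterError("phi_max must lie in (0, 1]")
        if self.K_half <= 0:
            raise InvalidParameterError("K_half must be positive")


@dataclass
class TensionSeries:
    """Bilayer tension versus microplastic concentration with uncertainties."""

    plastic: str
    pollutant: str
    concentrations: np.ndarray   # ug/mL, nonnegative, strictly increasing
    gamma_bilayer: np.ndarray    # mN/m
    errors: np.ndarray           # mN/m, nonnegative

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        g = np.asarray(self.gamma_bilayer, dtype=float)
        e = np.asarray(self.errors, dtype=float)
        if not (c.shape == g.shape == e.shape) or c.ndim != 1:
            raise InvalidParameterError("series columns must be equal-length 1-D")
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise InvalidParameterError(
                "concentrations must be nonnegative and strictly increasing"
            )
        if np.any(e < 0):
            raise InvalidParameterError("errors must be nonnegative")
        self.concentrations, self.gamma_bilayer, self.errors = c, g, e

    def __len__(self) -> int:
        return self.concentrations.size


@dataclass
class ZetaFit:
    """Result of fitting the stretching model to a tension series."""

    zeta_hat: float
    K_hat: float                       # ug/mL
    gamma0_used: float                 # mN/m
    k_used: float                      # mN/m
    phi_max_used: float
    chi2_reduced: float
    converged: bool
    predicted_curve: Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------

def control_parameter_zeta(eps_n0: float, k: float) -> float:
    """Signed control parameter ``zeta = -eps_n0 / k``.

    ``eps_n0`` is the attractive adhesion energy per unit area (mJ/m^2) and
    ``k`` the area compressibility modulus (mN/m); the two units coincide
    numerically, so the ratio is dimensionless.  Attraction carries a
    negative sign: 1 mJ/m^2 against 100-300 mN/m gives the bare-plastic
    range ``zeta = -0.01`` to ``-0.003``.
    """
    if k <= 0:
        raise InvalidParameterError("compressibility modulus k must be positive")
    if eps_n0 < 0:
        raise InvalidParameterError("adhesion energy per area must be nonnegative")
    return -eps_n0 / k


def cell_free_energy(u, zeta: float, phi: float, k: float):
    """Free energy per unit projected cell area, mN/m.

    ``f(u) = -2*k*|zeta|*phi*u + (k/2)*(phi*u**2)**2``: adhesion gain of the
    contact cap (area fraction ``2*phi*u`` of the cell) plus the quadratic
    stretching penalty at strain ``alpha = phi*u**2``.  Accepts scalar or
    array ``u``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr > 1):
        raise InvalidParameterError("wrapping fraction u must lie in [0, 1]")
    if not (0 < phi <= 1):
        raise InvalidParameterError("coverage phi must lie in (0, 1]")
    if k <= 0:
        raise InvalidParameterError("compressibility modulus k must be positive")
    if zeta > 0:
        raise InvalidParameterError("zeta must be <= 0")
    f = -2.0 * k * abs(zeta) * phi * u_arr + 0.5 * k * (phi * u_arr**2) ** 2
    return f if f.ndim else float(f)


def equilibrium_wrapping(zeta: float, phi: float) -> StretchState:
    """Closed-form minimizer of :func:`cell_free_energy` over ``u in [0, 1]``.

    Stationarity gives ``u**3 = |zeta| / phi``; wrapping is capped at the
    hemisphere (``u = 1``) when adhesion beats the stretching penalty over
    the whole cap (``phi <= |zeta|``).
    """
    if not (0 < phi <= 1):
        raise InvalidParameterError("coverage phi must lie in (0, 1]")
    if zeta > 0:
        raise InvalidParameterError("zeta must be <= 0")
    u = min(1.0, (abs(zeta) / phi) ** (1.0 / 3.0))
    alpha = phi * u**2
    return StretchState(
        wrap_fraction_u=u,
        alpha=alpha,
        adsorption_point_density=1.0 / (1.0 + alpha),
    )


def _delta_gamma(abs_zeta: float, phi: np.ndarray, k: float) -> np.ndarray:
    """Vectorized tension increase ``k * alpha*(zeta, phi)`` over coverages."""
    phi = np.asarray(phi, dtype=float)
    out = np.where(
        phi <= abs_zeta,
        k * phi,                                      # full hemisphere cap, u = 1
        k * abs_zeta ** (2.0 / 3.0) * np.cbrt(phi),   # partial wrapping
    )
    return np.where(phi == 0.0, 0.0, out)


def tension_increase(zeta: float, phi: float, k: float) -> float:
    """Bilayer tension rise ``dGamma = k * alpha*`` at equilibrium wrapping, mN/m.

    Equals ``k * phi**(1/3) * |zeta|**(2/3)`` for ``phi > |zeta|`` and
    ``k * phi`` in the hemisphere-capped regime ``phi <= |zeta|``;
    the two branches join continuously at ``phi = |zeta|``.
    """
    if k <= 0:
        raise InvalidParameterError("compressibility modulus k must be positive")
    if zeta > 0:
        raise InvalidParameterError("zeta must be <= 0")
    if phi == 0:
        return 0.0
    state = equilibrium_wrapping(zeta, phi)
    return float(k * state.alpha)


def langmuir_coverage(c, model: CoverageModel):
    """Langmuir isotherm ``phi = phi_max * c / (K_half + c)``; accepts arrays."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise InvalidParameterError("concentration must be nonnegative")
    phi = model.phi_max * c_arr / (model.K_half + c_arr)
    return phi if phi.ndim else float(phi)


def predict_tension(c, membrane: MembraneModel, coverage: CoverageModel):
    """Bilayer tension ``Gamma(c) = Gamma0 + dGamma(zeta, phi(c), k)``, mN/m."""
    phi = np.asarray(langmuir_coverage(c, coverage), dtype=float)
    out = membrane.gamma0 + _delta_gamma(abs(membrane.zeta), phi, membrane.k)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TensionCurveModel(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of the stretching model to Gamma(c) data.

    scikit-learn-style estimator: ``fit(c, gamma, errors)`` optimizes the
    control parameter ``zeta`` and the Langmuir half-saturation ``K_half``
    (and optionally the baseline ``gamma0``) against a tension-concentration
    series, weighting residuals by the reciprocal measurement errors.

    The optimization is a dense log-spaced grid scan over
    ``(|zeta|, K_half)`` followed by bounded least-squares refinement from
    the best grid points.  Whenever the best-fit curve lies entirely in the
    hemisphere-capped regime (``phi(c) <= |zeta|`` for every measured
    concentration) the magnitude of ``zeta`` is unidentifiable upward; the
    reported ``zeta_`` is then the smallest magnitude producing the same
    curve, ``|zeta| = phi(c_max)``.

    Parameters
    ----------
    k : float
        Area compressibility modulus, mN/m (held fixed).
    phi_max : float
        Langmuir saturation coverage, held fixed (default 1.0) to break the
        (phi_max, zeta) scale degeneracy.
    gamma0 : "first" | "fit" | float
        Baseline tension policy: fix to the c=0 data point, fit it, or fix
        to an explicit value (mN/m).
    zeta_abs_bounds, K_bounds : tuple
        Box constraints for |zeta| and K_half (ug/mL).

    Attributes
    ----------
    zeta_ : float            fitted control parameter (<= 0)
    K_half_ : float          fitted half-saturation concentration, ug/mL
    gamma0_ : float          baseline tension used, mN/m
    chi2_reduced_ : float    chi^2 per degree of freedom
    converged_ : bool
    """

    def __init__(
        self,
        k: float = K_DEFAULT,
        phi_max: float = 1.0,
        gamma0: str | float = "first",
        zeta_abs_bounds: tuple[float, float] = (0.0, 1.0),
        K_bounds: tuple[float, float] = (1.0, 1e5),
        grid_size: int = 201,
        n_polish: int = 6,
    ):
        self.k = k
        self.phi_max = phi_max
        self.gamma0 = gamma0
        self.zeta_abs_bounds = zeta_abs_bounds
        self.K_bounds = K_bounds
        self.grid_size = grid_size
        self.n_polish = n_polish

    # -- internals ---------------------------------------------------------

    def _curve(self, abs_zeta: float, K: float, gamma0: float, c: np.ndarray) -> np.ndarray:
        phi = self.phi_max * c / (K + c)
        return gamma0 + _delta_gamma(abs_zeta, phi, self.k)

    def fit(self, X, y, errors=None) -> "TensionCurveModel":
        """Fit ``(zeta, K_half)`` to concentrations ``X`` and tensions ``y``.

        ``errors`` are per-point measurement uncertainties (mN/m) used as
        inverse weights; omitted, the fit is unweighted.
        """
        c = np.asarray(X, dtype=float).reshape(-1)
        g = np.asarray(y, dtype=float).reshape(-1)
        if errors is None:
            err = np.ones_like(g)
        else:
            err = np.asarray(errors, dtype=float).reshape(-1)
            if np.any(err <= 0):
                raise InvalidParameterError("errors must be positive for weighting")
        if c.size != g.size or c.size != err.size:
            raise InvalidParameterError("c, gamma and errors must be equal length")
        if c.size < 4 or c.min() != 0.0:
            raise UnderdeterminedFitError(
                "need at least 4 points including c = 0"
            )
        if self.k <= 0:
            raise InvalidParameterError("compressibility modulus k must be positive")

        fit_gamma0 = self.gamma0 == "fit"
        if self.gamma0 == "first":
            gamma0 = float(g[c.argmin()])
        elif fit_gamma0:
            gamma0 = float(g[c.argmin()])  # starting value
        else:
            gamma0 = float(self.gamma0)
        n_params = 3 if fit_gamma0 else 2
        if c.size <= n_params:
            raise UnderdeterminedFitError("too few points for the requested fit")

        w = 1.0 / err
        z_lo = max(self.zeta_abs_bounds[0], 1e-4)
        z_hi = self.zeta_abs_bounds[1]
        K_lo, K_hi = self.K_bounds

        def grid_chi2(zg, Kg, g0):
            # closed-form model: evaluate the full (|zeta|, K) product grid
            phi = self.phi_max * c[None, :] / (Kg[:, None] + c[None, :])  # (nK, n)
            az = zg[:, None, None]
            dg = np.where(
                phi[None] <= az,
                self.k * phi[None],
                self.k * az ** (2.0 / 3.0) * np.cbrt(phi[None]),
            )
            dg = np.where(phi[None] == 0.0, 0.0, dg)
            r = (g0 + dg - g[None, None, :]) * w[None, None, :]
            return np.einsum("ijn,ijn->ij", r, r)  # (n_zeta, n_K)

        zg = np.geomspace(z_lo, z_hi, self.grid_size)
        Kg = np.geomspace(K_lo, K_hi, self.grid_size)
        chi2 = grid_chi2(zg, Kg, gamma0)

        # seed from per-K-column champions so narrow interior basins are not
        # crowded out by the flat fully-wrapped plateau
        i_best = np.argmin(chi2, axis=0)
        col_chi2 = chi2[i_best, np.arange(Kg.size)]
        seeds, taken = [], []
        for j in np.argsort(col_chi2):
            if any(abs(j - j0) <= 2 for j0 in taken):
                continue
            taken.append(j)
            seeds.append((zg[i_best[j]], Kg[j]))
            if len(seeds) >= self.n_polish:
                break

        def residuals(p, g0_fixed):
            z, lK = p[0], p[1]
            g0 = p[2] if fit_gamma0 else g0_fixed
            return (self._curve(z, 10.0**lK, g0, c) - g) * w

        lb = [self.zeta_abs_bounds[0], np.log10(K_lo)] + ([0.0] if fit_gamma0 else [])
        ub = [z_hi, np.log10(K_hi)] + ([np.inf] if fit_gamma0 else [])

        z_step = (z_hi / z_lo) ** (1.0 / (self.grid_size - 1))
        K_step = (K_hi / K_lo) ** (1.0 / (self.grid_size - 1))
        best = None
        for z0, K0 in seeds:
            # zoomed grid refinement: robust to the kink at phi = |zeta|
            zc, Kc, fz, fK = z0, K0, z_step, K_step
            for _ in range(3):
                zg_l = np.geomspace(max(zc / fz, z_lo), min(zc * fz, z_hi), 21)
                Kg_l = np.geomspace(max(Kc / fK, K_lo), min(Kc * fK, K_hi), 21)
                c2 = grid_chi2(zg_l, Kg_l, gamma0)
                i, j = np.unravel_index(np.argmin(c2), c2.shape)
                zc, Kc = zg_l[i], Kg_l[j]
                fz, fK = fz ** (2.0 / 20.0), fK ** (2.0 / 20.0)
            cand_cost = float(c2[i, j])
            cand = (zc, np.log10(Kc), gamma0)

            # smooth local polish (also recovers gamma0 when it is fitted)
            x0 = [zc, np.log10(Kc)] + ([gamma0] if fit_gamma0 else [])
            res = least_squares(
                residuals, x0=x0, bounds=(lb, ub), args=(gamma0,),
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=500,
            )
            if 2 * res.cost < cand_cost:
                cand_cost = float(2 * res.cost)
                cand = (
                    float(res.x[0]), float(res.x[1]),
                    float(res.x[2]) if fit_gamma0 else gamma0,
                )
            # tie-break: prefer the smaller |zeta| among equal-chi^2 optima
            if (
                best is None
                or cand_cost < best[0] * (1 - 1e-9)
                or (cand_cost <= best[0] * (1 + 1e-9) and cand[0] < best[1][0])
            ):
                best = (cand_cost, cand, res.success)
        cost, (abs_zeta, lK, gamma0), success = best
        K_half = float(10.0 ** lK)

        # identifiability: inside the fully-capped regime any larger |zeta|
        # gives the identical curve; report the boundary value
        phi_max_data = self.phi_max * c.max() / (K_half + c.max())
        if abs_zeta >= phi_max_data > 0:
            abs_zeta = float(phi_max_data)

        dof = max(c.size - n_params, 1)
        self.zeta_ = -abs_zeta
        self.K_half_ = K_half
        self.gamma0_ = gamma0
        self.chi2_reduced_ = float(cost / dof)
        self.converged_ = bool(success)
        self.n_points_ = int(c.size)
        return self

    def predict(self, X) -> np.ndarray:
        """Model tension Gamma(c) at concentrations ``X`` (ug/mL), mN/m."""
        c = np.asarray(X, dtype=float)
        out = self._curve(-self.zeta_, self.K_half_, self.gamma0_, c)
        return out if out.ndim else float(out)


def fit_tension_series(
    series: TensionSeries,
    k: float = K_DEFAULT,
    phi_max: float = 1.0,
    gamma0_policy: str = "fix-to-first-point",
) -> ZetaFit:
    """Fit the stretching model to a tension-concentration series.

    ``gamma0_policy`` is ``"fix-to-first-point"`` (baseline pinned to the
    c = 0 entry, the default) or ``"fit"``.  Returns a :class:`ZetaFit`
    whose ``predicted_curve`` evaluates the fitted Gamma(c).
    """
    if gamma0_policy == "fix-to-first-point":
        gamma0: str | float = "first"
    elif gamma0_policy == "fit":
        gamma0 = "fit"
    else:
        raise InvalidParameterError(
            f"unknown gamma0_policy {gamma0_policy!r}"
        )
    est = TensionCurveModel(k=k, phi_max=phi_max, gamma0=gamma0)
    est.fit(series.concentrations, series.gamma_bilayer, series.errors)
    return ZetaFit(
        zeta_hat=est.zeta_,
        K_hat=est.K_half_,
        gamma0_used=est.gamma0_,
        k_used=k,
        phi_max_used=phi_max,
        chi2_reduced=est.chi2_reduced_,
        converged=est.converged_,
        predicted_curve=est.predict,
    )


@dataclass
class SharedCoverageFit:
    """Joint fit of several series with one common coverage calibration.

    ``zeta_hats`` is keyed like the input mapping; ``chi2_per_series`` holds
    each series' weighted sum of squares at the shared optimum.
    """

    K_shared: float                    # ug/mL
    zeta_hats: dict
    chi2_per_series: dict
    chi2_total: float
    k_used: float
    phi_max_used: float


def _zeta_profile(c, g, e, gamma0, K, k, phi_max, zgrid):
    """Best |zeta| on a grid for a fixed coverage curve; returns (|zeta|, chi2)."""
    phi = phi_max * c / (K + c)
    w = 1.0 / e
    dg = np.where(
        phi[None, :] <= zgrid[:, None],
        k * phi[None, :],
        k * zgrid[:, None] ** (2.0 / 3.0) * np.cbrt(phi[None, :]),
    )
    dg = np.where(phi[None, :] == 0.0, 0.0, dg)
    r = (gamma0 + dg - g[None, :]) * w[None, :]
    chi2 = np.einsum("ij,ij->i", r, r)
    i = int(np.argmin(chi2))
    return float(zgrid[i]), float(chi2[i])


def fit_tension_table(
    series_map: dict,
    k: float = K_DEFAULT,
    phi_max: float = 1.0,
    K_bounds: tuple[float, float] = (1.0, 1e5),
    zeta_abs_bounds: tuple[float, float] = (1e-4, 1.0),
) -> SharedCoverageFit:
    """Jointly fit many tension series with a single coverage calibration.

    The per-series fit leaves ``|zeta|`` and ``K_half`` entangled: each
    series picks its own concentration-to-coverage map, so fitted adhesion
    magnitudes are not comparable across series.  Experimentally the
    coverage isotherm is a property of the particle batch, measured once;
    this joint fit mirrors that by sharing one Langmuir ``K_half`` across
    all series in ``series_map`` (e.g. the nine incubation conditions of
    one plastic) while each series keeps its own control parameter
    ``zeta``.  Adhesion strengths fitted this way can be ranked directly.

    The optimization is a nested grid search (exhaustive scan over the
    shared ``K_half``, closed-form profile over each ``|zeta|``) with
    iterative zoom, which is robust to the kink of the wrapping law.
    """
    if not series_map:
        raise UnderdeterminedFitError("no series to fit")
    data = {}
    for key, s in series_map.items():
        if len(s) < 4 or s.concentrations.min() != 0:
            raise UnderdeterminedFitError(
                f"series {key}: need at least 4 points including c = 0"
            )
        if np.any(s.errors <= 0):
            raise InvalidParameterError(f"series {key}: errors must be positive")
        data[key] = (
            s.concentrations, s.gamma_bilayer, s.errors,
            float(s.gamma_bilayer[s.concentrations.argmin()]),
        )

    zgrid = np.geomspace(*zeta_abs_bounds, 800)

    def total(K):
        return sum(
            _zeta_profile(c, g, e, g0, K, k, phi_max, zgrid)[1]
            for c, g, e, g0 in data.values()
        )

    Kg = np.geomspace(K_bounds[0], K_bounds[1], 200)
    costs = [total(K) for K in Kg]
    Kc = Kg[int(np.argmin(costs))]
    f = (K_bounds[1] / K_bounds[0]) ** (1.0 / 199.0)
    for _ in range(3):
        Kg = np.geomspace(max(Kc / f, K_bounds[0]), min(Kc * f, K_bounds[1]), 21)
        costs = [total(K) for K in Kg]
        Kc = Kg[int(np.argmin(costs))]
        f = f ** (2.0 / 20.0)

    zeta_hats, chi2_per = {}, {}
    for key, (c, g, e, g0) in data.items():
        z, chi2 = _zeta_profile(c, g, e, g0, Kc, k, phi_max, zgrid)
        # local zeta refinement around the grid optimum
        step = (zeta_abs_bounds[1] / zeta_abs_bounds[0]) ** (1.0 / 799.0)
        zfine = np.geomspace(z / step, z * step, 201)
        z, chi2 = _zeta_profile(c, g, e, g0, Kc, k, phi_max, zfine)
        zeta_hats[key] = -z
        chi2_per[key] = chi2
    return SharedCoverageFit(
        K_shared=float(Kc),
        zeta_hats=zeta_hats,
        chi2_per_series=chi2_per,
        chi2_total=float(sum(chi2_per.values())),
        k_used=k,
        phi_max_used=phi_max,
    )
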