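"""Mean-square displacement and diffusion analysis of membrane-bound beads.

Microplastic beads adsorbed on a free-standing bilayer stay mobile and
perform 2-D Brownian motion; the time- and ensemble-averaged mean-square
displacement ``<r^2>(tau) = 4 * D * tau`` yields their diffusion
coefficient, to be compared with the Stokes-Einstein bulk value
``D = kB * T / (3 * pi * eta * d)`` for a sphere of diameter ``d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import Boltzmann
from sklearn.base import BaseEstimator

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionFit",
    "compute_msd",
    "DiffusionEstimator",
    "fit_diffusion_2d",
    "stokes_einstein_diffusion",
]

MIN_TRACK_LENGTH = 10


@dataclass
class Trajectory:
    """A single 2-D particle track sampled at uniform intervals."""

    particle_id: str
    times: np.ndarray   # s
    x: np.ndarray       # um
    y: np.ndarray       # um

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise InvalidParameterError("times, x, y must be equal-length 1-D")
        if t.size < 2:
            raise InvalidParameterError("a trajectory needs at least 2 samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > 1e-9 * dt):
            raise InvalidParameterError("sampling must be uniform")
        self.times, self.x, self.y = t, x, y

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MSDCurve:
    """Lag-time mean-square-displacement summary; ``msd(0) = 0`` by convention."""

    lags: np.ndarray      # s, strictly increasing, starting at 0
    msd: np.ndarray       # um^2
    n_pairs: np.ndarray   # displacement pairs averaged per lag


@dataclass(frozen=True)
class DiffusionFit:
    """Diffusion coefficient and anomalous exponent from an MSD curve."""

    D: float              # um^2/s
    exponent: float       # log-log slope; 1 for pure Brownian motion
    fit_range: tuple[float, float]   # lag interval used, s
    clamped: bool = False            # True when a negative slope was clipped to D=0


def compute_msd(
    trajectories: Sequence[Trajectory],
    max_lag_fraction: float = 0.25,
) -> MSDCurve:
    """Time- and ensemble-averaged 2-D MSD over overlapping lag pairs.

    Every ordered pair of samples separated by ``m`` frames contributes to
    lag ``m`` (overlapping-window averaging); lags run up to
    ``max_lag_fraction`` of the shortest retained track.  Tracks shorter
    than 10 points are excluded with a warning.
    """
    if not (0 < max_lag_fraction <= 0.5):
        raise InvalidParameterError("max_lag_fraction must lie in (0, 0.5]")
    tracks = []
    for tr in trajectories:
        if len(tr) < MIN_TRACK_LENGTH:
            warnings.warn(
                f"trajectory {tr.particle_id!r} shorter than {MIN_TRACK_LENGTH} "
                "points; excluded",
                stacklevel=2,
            )
            continue
        tracks.append(tr)
    if not tracks:
        raise EmptyInputError("no trajectory long enough for MSD analysis")

    dt = tracks[0].dt
    if any(abs(tr.dt - dt) > 1e-9 * dt for tr in tracks):
        raise InvalidParameterError("all trajectories must share the same dt")

    shortest = min(len(tr) for tr in tracks)
    max_lag = max(1, int(np.floor(max_lag_fraction * (shortest - 1))))
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for tr in tracks:
        for m in range(1, max_lag + 1):
            dx = tr.x[m:] - tr.x[:-m]
            dy = tr.y[m:] - tr.y[:-m]
            sums[m - 1] += np.sum(dx * dx + dy * dy)
            counts[m - 1] += dx.size
    lags = np.concatenate([[0.0], np.arange(1, max_lag + 1) * dt])
    msd = np.concatenate([[0.0], sums / counts])
    n_pairs = np.concatenate([[sum(len(tr) for tr in tracks)], counts])
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


class DiffusionEstimator(BaseEstimator):
    """Fit ``<r^2> = 4*D*tau`` to an MSD curve (scikit-learn protocol).

    The diffusion coefficient comes from a weighted through-origin linear
    fit of MSD against lag (weights: number of displacement pairs per lag),
    the anomalous exponent from the log-log slope over the same range.  The
    default fit window, lags 2 to 10 frame intervals, avoids both the
    localization-noise-dominated first lag and the statistics-poor tail.

    Attributes
    ----------
    D_ : float               diffusion coefficient, um^2/s (>= 0)
    exponent_ : float        log-log slope (1 = Brownian)
    fit_range_ : tuple       lag interval used, s
    clamped_ : bool          True when a negative slope was clipped to zero
    """

    def __init__(self, fit_range: tuple[float, float] | None = None):
        self.fit_range = fit_range

    def fit(self, X, y=None) -> "DiffusionEstimator":
        """``X`` may be an :class:`MSDCurve` or a sequence of trajectories."""
        if isinstance(X, MSDCurve):
            curve = X
        else:
            curve = compute_msd(X)
        lags, msd, n_pairs = curve.lags, curve.msd, curve.n_pairs
        dt = lags[1] - lags[0] if lags.size > 1 else 0.0
        if self.fit_range is None:
            fit_range = (2 * dt, 10 * dt)
        else:
            fit_range = tuple(self.fit_range)
        sel = (lags > 0) & (lags >= fit_range[0] - 1e-12) & (lags <= fit_range[1] + 1e-12)
        if sel.sum() < 4:
            sel = lags > 0  # short curve: use everything available
            if sel.sum() < 4:
                raise InvalidParameterError("need at least 4 nonzero lags to fit")
        tau, m, w = lags[sel], msd[sel], n_pairs[sel].astype(float)

        slope = float(np.sum(w * tau * m) / np.sum(w * tau**2))
        clamped = slope < 0
        D = max(slope, 0.0) / 4.0
        pos = m > 0
        if pos.sum() >= 2:
            exponent = float(np.polyfit(np.log(tau[pos]), np.log(m[pos]), 1)[0])
        else:
            exponent = float("nan")
        self.D_ = D
        self.exponent_ = exponent
        self.fit_range_ = (float(tau.min()), float(tau.max()))
        self.clamped_ = clamped
        self.result_ = DiffusionFit(
            D=D, exponent=exponent, fit_range=self.fit_range_, clamped=clamped
        )
        return self


def fit_diffusion_2d(
    msd: MSDCurve, fit_range: tuple[float, float] | None = None
) -> DiffusionFit:
    """Functional wrapper around :class:`DiffusionEstimator`."""
    return DiffusionEstimator(fit_range=fit_range).fit(msd).result_


def stokes_einstein_diffusion(
    diameter: float, temperature: float = 298.15, viscosity: float = 0.89
) -> float:
    """Bulk Stokes-Einstein diffusion coefficient, um^2/s.

    ``D = kB*T / (3*pi*eta*d)`` for a sphere of diameter ``d`` (um) in a
    fluid of viscosity ``eta`` (mPa s) at temperature ``T`` (K).
    """
    if diameter <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("diameter, temperature and viscosity must be positive")
    d_m = diameter * 1e-6
    eta = viscosity * 1e-3
    D_m2_s = Boltzmann * temperature / (3.0 * np.pi * eta * d_m)
    return float(D_m2_s * 1e12)
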