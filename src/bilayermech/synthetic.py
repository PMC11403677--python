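"""Seeded synthetic-data generators and packaged reference tables.

Each generator is the forward model of exactly one estimator in the
package: tension-concentration series for the stretching-model fit, DiB
contact angles for the Young-Dupre aggregation, pendant-drop contours for
the Young-Laplace shape fit, and Brownian tracks for the MSD pipeline.
Noise magnitudes default to the experimental scales of the DiB study
(tension scatter 0.2-0.5 mN/m, contour localization of order micrometres,
bead localization tens of nanometres).  All randomness flows from a single
integer seed through a local :func:`numpy.random.default_rng` stream, so
identical arguments give identical outputs.

:func:`table_fixtures` returns the 27 measured bilayer-tension series
(3 plastics x 9 incubation conditions x 6 concentrations) shipped with the
package as plain CSV.  The "PA" series were measured on PMMA microbeads as
a stand-in for polyamide; the label follows the source tables.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .dib import ContactAngleMeasurement, contact_angle_from_tensions
from .errors import InvalidParameterError
from .pendant import DELTA_RHO_DEFAULT, DropletProfile, integrate_young_laplace
from .stretching import (
    CoverageModel,
    MembraneModel,
    TensionSeries,
    predict_tension,
)
from .tracking import Trajectory

__all__ = [
    "gen_tension_series",
    "gen_dib_angles",
    "gen_droplet_profile",
    "gen_brownian_tracks",
    "table_fixtures",
    "PLASTICS",
    "POLLUTANTS",
    "CONCENTRATIONS_UG_PER_ML",
]

PLASTICS = ("PS", "PE", "PA")
POLLUTANTS = (
    "PBS",
    "mercury",
    "hexane",
    "toluene",
    "1-octanol",
    "perfluoroctanol",
    "zonyl",
    "DDT",
    "sunscreen",
)
CONCENTRATIONS_UG_PER_ML = (0.0, 50.0, 100.0, 150.0, 300.0, 500.0)

_TABLE_FILES = {"PS": "table1_ps.csv", "PE": "table2_pe.csv", "PA": "table3_pa.csv"}


def gen_tension_series(
    zeta: float,
    K_half: float,
    gamma0: float,
    k: float = 200.0,
    phi_max: float = 1.0,
    concentrations: Sequence[float] = CONCENTRATIONS_UG_PER_ML,
    noise_sigma: float = 0.3,
    seed: int = 0,
    plastic: str = "synthetic",
    pollutant: str = "synthetic",
) -> TensionSeries:
    """Tension-concentration series from the stretching model plus Gaussian noise.

    The errors column is set to ``noise_sigma`` (the generating standard
    deviation), mirroring how the measured tables report one uncertainty
    per entry.
    """
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be nonnegative")
    c = np.asarray(sorted(concentrations), dtype=float)
    if c[0] != 0:
        raise InvalidParameterError("concentrations must include 0")
    membrane = MembraneModel(k=k, zeta=zeta, gamma0=gamma0)
    coverage = CoverageModel(phi_max=phi_max, K_half=K_half)
    clean = np.asarray(predict_tension(c, membrane, coverage), dtype=float)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sigma, size=c.size)
    return TensionSeries(
        plastic=plastic,
        pollutant=pollutant,
        concentrations=c,
        gamma_bilayer=noisy,
        errors=np.full(c.size, noise_sigma),
    )


def gen_dib_angles(
    gamma_bilayer_true: float,
    monolayer_gamma: float,
    n: int = 25,
    angle_noise_deg: float = 2.0,
    seed: int = 0,
) -> list[ContactAngleMeasurement]:
    """Replicate DiB contact angles consistent with a true (Gamma, gamma) pair.

    Angles are the exact Young-Dupre inverse plus Gaussian noise, clipped
    to the physical range [0, 180) degrees.
    """
    if n < 1:
        raise InvalidParameterError("need at least one replicate")
    if angle_noise_deg < 0:
        raise InvalidParameterError("angle noise must be nonnegative")
    true_angle = contact_angle_from_tensions(gamma_bilayer_true, monolayer_gamma)
    rng = np.random.default_rng(seed)
    angles = true_angle + rng.normal(0.0, angle_noise_deg, size=n)
    angles = np.clip(angles, 0.0, np.nextafter(180.0, 0.0))
    return [
        ContactAngleMeasurement(full_angle_2theta=float(a), monolayer_gamma=monolayer_gamma)
        for a in angles
    ]


def gen_droplet_profile(
    gamma: float,
    apex_radius_b: float,
    delta_rho: float = DELTA_RHO_DEFAULT,
    n_points: int = 200,
    coord_noise_um: float = 0.0,
    seed: int = 0,
    arc_span: float | None = None,
) -> DropletProfile:
    """Noisy pendant-drop contour at known interfacial tension.

    Integrates the Young-Laplace shape and adds independent Gaussian noise
    of ``coord_noise_um`` micrometres to both coordinates (x is clipped at
    the symmetry axis).
    """
    if coord_noise_um < 0:
        raise InvalidParameterError("coordinate noise must be nonnegative")
    profile = integrate_young_laplace(
        gamma, apex_radius_b, delta_rho=delta_rho, arc_span=arc_span,
        n_points=n_points,
    )
    if coord_noise_um == 0:
        return profile
    rng = np.random.default_rng(seed)
    pts = profile.points + rng.normal(0.0, coord_noise_um * 1e-3, size=profile.points.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, None)
    # re-impose apex-first ordering of the z coordinate disturbed by noise
    pts = pts[np.argsort(pts[:, 1], kind="stable")]
    return DropletProfile(
        points=pts, delta_rho=delta_rho, gravity=profile.gravity,
        truncated=profile.truncated,
    )


def gen_brownian_tracks(
    D: float,
    n_particles: int = 100,
    n_steps: int = 1000,
    dt: float = 0.05,
    loc_noise_um: float = 0.0,
    seed: int = 0,
) -> list[Trajectory]:
    """2-D Brownian trajectories at diffusion coefficient ``D`` (um^2/s).

    Per-axis step variance is ``2*D*dt``; independent localization noise of
    standard deviation ``loc_noise_um`` is added to every observed position.
    """
    if D < 0:
        raise InvalidParameterError("diffusion coefficient must be nonnegative")
    if n_particles < 1 or n_steps < MIN_STEPS:
        raise InvalidParameterError(
            f"need at least one particle and {MIN_STEPS} steps"
        )
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if loc_noise_um < 0:
        raise InvalidParameterError("localization noise must be nonnegative")
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps) * dt
    sigma_step = np.sqrt(2.0 * D * dt)
    tracks = []
    for i in range(n_particles):
        steps = rng.normal(0.0, sigma_step, size=(n_steps - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if loc_noise_um > 0:
            pos = pos + rng.normal(0.0, loc_noise_um, size=pos.shape)
        tracks.append(
            Trajectory(particle_id=f"p{i:04d}", times=times, x=pos[:, 0], y=pos[:, 1])
        )
    return tracks


MIN_STEPS = 10


def _load_table(plastic: str) -> pd.DataFrame:
    fname = _TABLE_FILES[plastic]
    with resources.files("bilayermech.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)


def table_fixtures() -> dict[tuple[str, str], TensionSeries]:
    """The 27 measured bilayer-tension series, keyed by (plastic, pollutant).

    Concentrations are 0-500 ug/mL; every series starts at the bare-bilayer
    tension 1.7 mN/m.  Values are transcribed verbatim from the packaged
    CSV tables.
    """
    out: dict[tuple[str, str], TensionSeries] = {}
    for plastic in PLASTICS:
        df = _load_table(plastic)
        for pollutant, grp in df.groupby("pollutant", sort=False):
            grp = grp.sort_values("conc_ug_per_ml")
            out[(plastic, pollutant)] = TensionSeries(
                plastic=plastic,
                pollutant=str(pollutant),
                concentrations=grp["conc_ug_per_ml"].to_numpy(float),
                gamma_bilayer=grp["gamma_mN_per_m"].to_numpy(float),
                errors=grp["err_mN_per_m"].to_numpy(float),
            )
    return out
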