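"""Droplet-interface-bilayer (DiB) tension via the Young-Dupre relation.

Two lipid-monolayer-coated water droplets pressed together in oil form a
bilayer at their contact zone.  Force balance at the three-phase contact
line gives the Young-Dupre relation

    Gamma = 2 * gamma * cos(theta)

where ``gamma`` is the monolayer (droplet-oil) tension, ``Gamma`` the
bilayer tension, and ``2*theta`` the full angle between the two droplet
caps as measured on a micrograph.  ``Gamma`` ranges from ``2*gamma``
(flat, parallel monolayers, ``2*theta = 0``) down to zero at
``2*theta = 180`` degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    InfeasibleTensionError,
    InsufficientReplicatesError,
    InvalidAngleError,
    InvalidParameterError,
)

__all__ = [
    "ContactAngleMeasurement",
    "BilayerTensionEstimate",
    "young_dupre",
    "contact_angle_from_tensions",
    "aggregate_replicates",
    "bilayer_tension_from_replicates",
]


@dataclass(frozen=True)
class ContactAngleMeasurement:
    """One DiB contact-angle observation and the monolayer tension it pairs with."""

    full_angle_2theta: float   # degrees, angle between the two droplet caps
    monolayer_gamma: float     # mN/m

    def __post_init__(self) -> None:
        if not (0 <= self.full_angle_2theta < 180):
            raise InvalidAngleError("full angle 2*theta must lie in [0, 180) degrees")
        if self.monolayer_gamma <= 0:
            raise InvalidParameterError("monolayer tension must be positive")


@dataclass(frozen=True)
class BilayerTensionEstimate:
    """Replicate-aggregated bilayer tension."""

    gamma_bilayer: float   # mN/m
    sem: float             # standard error of the mean, mN/m
    n_replicates: int


def young_dupre(monolayer_gamma: float, full_angle_2theta: float) -> float:
    """Bilayer tension from the DiB contact angle: ``Gamma = 2*gamma*cos(theta)``.

    ``full_angle_2theta`` is the measured angle between the droplet caps in
    degrees; ``theta`` (half of it) is the angle each monolayer makes with
    the bilayer plane.
    """
    if not (0 <= full_angle_2theta < 180):
        raise InvalidAngleError("full angle 2*theta must lie in [0, 180) degrees")
    if monolayer_gamma <= 0:
        raise InvalidParameterError("monolayer tension must be positive")
    theta = np.deg2rad(full_angle_2theta / 2.0)
    return float(2.0 * monolayer_gamma * np.cos(theta))


def contact_angle_from_tensions(gamma_bilayer: float, monolayer_gamma: float) -> float:
    """Inverse of :func:`young_dupre`: full angle 2*theta (degrees) for a (Gamma, gamma) pair."""
    if monolayer_gamma <= 0:
        raise InvalidParameterError("monolayer tension must be positive")
    if gamma_bilayer < 0:
        raise InvalidParameterError("bilayer tension must be nonnegative")
    if gamma_bilayer > 2.0 * monolayer_gamma:
        raise InfeasibleTensionError(
            "bilayer tension exceeds 2*gamma; no contact angle exists"
        )
    ratio = gamma_bilayer / (2.0 * monolayer_gamma)
    return float(2.0 * np.rad2deg(np.arccos(ratio)))


def aggregate_replicates(estimates: Sequence[float]) -> BilayerTensionEstimate:
    """Mean and standard error over replicate bilayer-tension values.

    Matches the experimental convention of reporting the average of ~20-30
    DiB measurements with its standard error.
    """
    vals = np.asarray(list(estimates), dtype=float)
    if vals.size < 2:
        raise InsufficientReplicatesError("need at least 2 replicates to aggregate")
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
    return BilayerTensionEstimate(gamma_bilayer=mean, sem=sem, n_replicates=vals.size)


def bilayer_tension_from_replicates(
    measurements: Iterable[ContactAngleMeasurement],
) -> BilayerTensionEstimate:
    """Apply Young-Dupre to each replicate angle and aggregate."""
    gammas = [
        young_dupre(m.monolayer_gamma, m.full_angle_2theta) for m in measurements
    ]
    return aggregate_replicates(gammas)
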