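"""CSV readers and writers for the package's plain-text interchange formats.

Schemas (header required, ``#`` starts a comment line):

* profile:    ``x_mm,z_mm`` apex-first
* trace:      ``t_s,gamma_mN_per_m``
* replicates: ``replicate_id,angle_2theta_deg,gamma_mono_mN_per_m``
* series:     ``plastic,pollutant,conc_ug_per_ml,gamma_mN_per_m,err_mN_per_m``
* tracks:     ``particle,frame,t_s,x_um,y_um``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dib import ContactAngleMeasurement
from .errors import SchemaError
from .pendant import DropletProfile, TensionTimeTrace
from .stretching import TensionSeries
from .tracking import Trajectory

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "read_trace_csv",
    "read_replicates_csv",
    "read_series_csv",
    "write_series_csv",
    "read_tracks_csv",
    "write_tracks_csv",
]


def _read(path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def read_profile_csv(path, delta_rho=None, gravity=None) -> DropletProfile:
    df = _read(path, ["x_mm", "z_mm"])
    kwargs = {}
    if delta_rho is not None:
        kwargs["delta_rho"] = delta_rho
    if gravity is not None:
        kwargs["gravity"] = gravity
    return DropletProfile(points=df[["x_mm", "z_mm"]].to_numpy(float), **kwargs)


def write_profile_csv(path, profile: DropletProfile) -> None:
    pd.DataFrame(profile.points, columns=["x_mm", "z_mm"]).to_csv(path, index=False)


def read_trace_csv(path) -> TensionTimeTrace:
    df = _read(path, ["t_s", "gamma_mN_per_m"])
    return TensionTimeTrace(
        times=df["t_s"].to_numpy(float),
        gamma_values=df["gamma_mN_per_m"].to_numpy(float),
    )


def read_replicates_csv(path) -> list[ContactAngleMeasurement]:
    df = _read(path, ["replicate_id", "angle_2theta_deg", "gamma_mono_mN_per_m"])
    return [
        ContactAngleMeasurement(
            full_angle_2theta=float(row.angle_2theta_deg),
            monolayer_gamma=float(row.gamma_mono_mN_per_m),
        )
        for row in df.itertuples()
    ]


_SERIES_COLS = ["plastic", "pollutant", "conc_ug_per_ml", "gamma_mN_per_m", "err_mN_per_m"]


def read_series_csv(path) -> TensionSeries:
    """Read a single tension-concentration series (one plastic/pollutant pair)."""
    df = _read(path, _SERIES_COLS)
    pairs = df[["plastic", "pollutant"]].drop_duplicates()
    if len(pairs) != 1:
        raise SchemaError(f"{path}: expected one (plastic, pollutant) pair, found {len(pairs)}")
    df = df.sort_values("conc_ug_per_ml")
    return TensionSeries(
        plastic=str(df["plastic"].iloc[0]),
        pollutant=str(df["pollutant"].iloc[0]),
        concentrations=df["conc_ug_per_ml"].to_numpy(float),
        gamma_bilayer=df["gamma_mN_per_m"].to_numpy(float),
        errors=df["err_mN_per_m"].to_numpy(float),
    )


def write_series_csv(path, series: TensionSeries) -> None:
    pd.DataFrame(
        {
            "plastic": series.plastic,
            "pollutant": series.pollutant,
            "conc_ug_per_ml": series.concentrations,
            "gamma_mN_per_m": series.gamma_bilayer,
            "err_mN_per_m": series.errors,
        }
    ).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Trajectory]:
    df = _read(path, ["particle", "frame", "t_s", "x_um", "y_um"])
    tracks = []
    for pid, grp in df.groupby("particle", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Trajectory(
                particle_id=str(pid),
                times=grp["t_s"].to_numpy(float),
                x=grp["x_um"].to_numpy(float),
                y=grp["y_um"].to_numpy(float),
            )
        )
    return tracks


def write_tracks_csv(path, tracks: Sequence[Trajectory]) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "particle": tr.particle_id,
                    "frame": np.arange(len(tr)),
                    "t_s": tr.times,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
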