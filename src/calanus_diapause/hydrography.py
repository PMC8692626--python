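"""CTD temperature profiles: ingestion, interpolation and layer means.

A profile is modelled as piecewise linear in depth (positive downward,
metres).  Point queries interpolate linearly between bracketing samples and
clamp to the nearest endpoint outside the sampled range; layer means are
depth-weighted trapezoidal integrals of the piecewise-linear profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CTDProfile", "read_ctd_profile", "temperature_at_depth", "mean_temperature"]


@dataclass(frozen=True)
class CTDProfile:
    """Depth-ordered temperature record for one station."""

    station: str
    depth_m: np.ndarray
    temperature_C: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.depth_m, dtype=float)
        t = np.asarray(self.temperature_C, dtype=float)
        if z.shape != t.shape or z.ndim != 1:
            raise ValueError("depth and temperature must be 1-d arrays of equal length")
        if z.size < 2:
            raise ValueError("a CTD profile needs at least 2 distinct depths")
        if np.any(z < 0):
            raise ValueError("depths must be >= 0 m (positive downward)")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing after ingestion")
        object.__setattr__(self, "depth_m", z)
        object.__setattr__(self, "temperature_C", t)

    @classmethod
    def from_samples(cls, station: str, depth_m, temperature_C) -> "CTDProfile":
        """Build a profile from possibly unordered samples.

        Samples are sorted by depth; duplicate depths are averaged.
        """
        z = np.asarray(depth_m, dtype=float)
        t = np.asarray(temperature_C, dtype=float)
        if np.any(~np.isfinite(z)) or np.any(~np.isfinite(t)):
            raise ValueError("non-finite depth or temperature sample")
        df = pd.DataFrame({"z": z, "t": t}).groupby("z", as_index=False).mean()
        return cls(station=station, depth_m=df["z"].to_numpy(), temperature_C=df["t"].to_numpy())


def read_ctd_profile(path, station: str | None = None) -> CTDProfile:
    """Read a CTD CSV with columns ``depth_m, temperature_C``.

    Extra columns (e.g. salinity) are accepted and ignored.  Rows are sorted
    by depth and duplicate depths averaged; fewer than 2 distinct depths or
    a non-numeric cell is an error (reported with its CSV line number).
    """
    df = pd.read_csv(path)
    for col in ("depth_m", "temperature_C"):
        if col not in df.columns:
            raise ValueError(f"CTD file {path} missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise ValueError(f"CTD file {path}: non-numeric {col} at line {line}")
        df[col] = coerced
    name = station if station is not None else str(df["station"].iloc[0]) if "station" in df.columns else ""
    return CTDProfile.from_samples(name, df["depth_m"], df["temperature_C"])


def temperature_at_depth(profile: CTDProfile, depth_m):
    """Temperature (°C) at depth by linear interpolation.

    Outside the sampled depth range the nearest-endpoint value is returned
    with a warning.
    """
    z = np.asarray(depth_m, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0 m")
    zmin, zmax = profile.depth_m[0], profile.depth_m[-1]
    if np.any((z < zmin) | (z > zmax)):
        warnings.warn(
            f"depth outside sampled range [{zmin}, {zmax}] m; clamping to endpoint",
            stacklevel=2,
        )
    t = np.interp(z, profile.depth_m, profile.temperature_C)
    return float(t) if np.isscalar(depth_m) else t


def mean_temperature(profile: CTDProfile, z1: float, z2: float) -> float:
    """Depth-weighted mean temperature (°C) over the layer [z1, z2].

    Trapezoidal integration of the piecewise-linear profile divided by the
    layer thickness.  The layer must intersect the sampled range; beyond the
    shallowest/deepest sample the profile is extended as a constant.
    """
    if not 0 <= z1 < z2:
        raise ValueError("need 0 <= z1 < z2")
    zmin, zmax = profile.depth_m[0], profile.depth_m[-1]
    if z2 <= zmin or z1 >= zmax:
        raise ValueError(
            f"layer [{z1}, {z2}] m lies entirely outside sampled range [{zmin}, {zmax}] m"
        )
    inner = profile.depth_m[(profile.depth_m > z1) & (profile.depth_m < z2)]
    knots = np.concatenate(([z1], inner, [z2]))
    temps = np.interp(knots, profile.depth_m, profile.temperature_C)
    return float(np.trapezoid(temps, knots) / (z2 - z1))
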