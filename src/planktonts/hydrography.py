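"""Seawater density, mixed-layer depth, and the combined nutrient index.

Density is the potential density anomaly sigma-theta computed with the
EOS-80 (UNESCO 1983) one-atmosphere polynomial; for casts shallower than
~40 m the in-situ vs potential temperature distinction and the pressure
dependence of sigma-theta are negligible, so the one-atmosphere form is
used throughout with temperature treated as potential temperature.  The
mixed layer depth is the shallowest depth at which sigma-theta exceeds
the surface value by a fixed threshold (default 0.125 kg m-3), located
by linear interpolation between the bracketing levels.  The combined
nutrient availability is the cube root of the product of nitrate+nitrite,
phosphate and silicate concentrations (Fleming-Kaitala index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtdProfile",
    "MldResult",
    "sigma_theta",
    "mixed_layer_depth",
    "mld_from_density",
    "nutrient_availability",
    "read_ctd_csv",
    "write_ctd_csv",
]

# EOS-80 valid ranges (practical salinity, deg C)
_S_RANGE = (0.0, 42.0)
_T_RANGE = (-2.0, 35.0)


@dataclass
class CtdProfile:
    """One CTD cast: depth-ordered pressure/temperature/salinity levels."""

    cast_date: pd.Timestamp
    depth_m: np.ndarray
    pressure_dbar: np.ndarray
    temperature_c: np.ndarray
    salinity_psu: np.ndarray
    station_depth_m: float = 40.0

    def __post_init__(self) -> None:
        self.cast_date = pd.Timestamp(self.cast_date)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.pressure_dbar = np.asarray(self.pressure_dbar, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.salinity_psu = np.asarray(self.salinity_psu, dtype=float)
        if self.depth_m.size < 2:
            raise ValueError("a CTD profile needs at least 2 levels")
        if not np.all(np.diff(self.depth_m) > 0):
            raise ValueError("depths must be strictly increasing from the surface")
        if np.any(self.temperature_c < _T_RANGE[0]) or np.any(self.temperature_c > _T_RANGE[1]):
            raise ValueError("temperature outside physical range (-2..35 degC)")

    def sigma_theta(self) -> np.ndarray:
        return sigma_theta(self.salinity_psu, self.temperature_c, self.pressure_dbar)


@dataclass
class MldResult:
    """Mixed-layer depth with its surface reference density.

    ``crossed`` records whether the density threshold was exceeded within
    the cast; when it was not, ``mld`` equals the deepest measured depth.
    """

    mld: float
    reference_density: float
    crossed: bool


def sigma_theta(salinity, temperature, pressure=0.0):
    """Potential density anomaly (kg m-3) from the EOS-80 polynomial.

    One-atmosphere UNESCO 1983 equation of state evaluated at reference
    pressure 0; ``pressure`` is accepted for interface symmetry but does
    not enter the surface-referenced density.  Inputs may be scalars or
    arrays; out-of-range values raise with the offending field named.
    """
    S = np.asarray(salinity, dtype=float)
    T = np.asarray(temperature, dtype=float)
    if np.any(S < _S_RANGE[0]) or np.any(S > _S_RANGE[1]):
        raise ValueError(f"salinity outside EOS-80 range {_S_RANGE}")
    if np.any(T < _T_RANGE[0]) or np.any(T > _T_RANGE[1]):
        raise ValueError(f"temperature outside EOS-80 range {_T_RANGE}")

    # density of standard mean ocean water (pure water limit)
    rho_w = (999.842594
             + 6.793952e-2 * T
             - 9.095290e-3 * T**2
             + 1.001685e-4 * T**3
             - 1.120083e-6 * T**4
             + 6.536332e-9 * T**5)
    A = (8.24493e-1
         - 4.0899e-3 * T
         + 7.6438e-5 * T**2
         - 8.2467e-7 * T**3
         + 5.3875e-9 * T**4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    rho = rho_w + A * S + B * S**1.5 + C * S**2
    out = rho - 1000.0
    if out.ndim == 0:
        return float(out)
    return out


def mld_from_density(depth_m, sigma, threshold: float = 0.125) -> MldResult:
    """Mixed-layer depth from a density profile.

    The reference is the shallowest level's sigma-theta.  The crossing of
    ``delta sigma > threshold`` is located by linear interpolation between
    the last level at or below the threshold and the first above it.
    Only density differences matter, so the result is invariant under a
    constant offset of the whole profile.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(depth_m, dtype=float)
    s = np.asarray(sigma, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 levels")
    if not np.all(np.diff(z) > 0):
        raise ValueError("depths must be strictly increasing")
    ref = float(s[0])
    delta = s - ref
    above = delta > threshold
    if not above.any():
        return MldResult(mld=float(z[-1]), reference_density=ref, crossed=False)
    i = int(np.argmax(above))  # first crossing index, i >= 1 since delta[0] = 0
    z0, z1 = z[i - 1], z[i]
    d0, d1 = delta[i - 1], delta[i]
    if d1 == d0:  # degenerate step recorded at identical densities
        mld = float(z1)
    else:
        mld = float(z0 + (threshold - d0) * (z1 - z0) / (d1 - d0))
    return MldResult(mld=mld, reference_density=ref, crossed=True)


def mixed_layer_depth(profile: CtdProfile, threshold: float = 0.125) -> MldResult:
    """Mixed-layer depth of a CTD cast under the density-threshold criterion."""
    return mld_from_density(profile.depth_m, profile.sigma_theta(), threshold)


def nutrient_availability(no3no2, po4, sio4):
    """Combined nutrient availability: cbrt([NO3+NO2] x [PO4] x [SiO4]).

    A geometric-mean-type index in uM: symmetric in its three inputs,
    homogeneous of degree one, and zero whenever any nutrient is depleted.
    """
    a = np.asarray(no3no2, dtype=float)
    b = np.asarray(po4, dtype=float)
    c = np.asarray(sio4, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0):
        raise ValueError("nutrient concentrations must be non-negative")
    out = np.cbrt(a * b * c)
    if out.ndim == 0:
        return float(out)
    return out


def write_ctd_csv(profile: CtdProfile, path, provenance: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"# cast_date={profile.cast_date.date().isoformat()} "
                 f"station_depth_m={profile.station_depth_m:g}\n")
        fh.write("depth_m,pressure_dbar,temperature_C,salinity_psu\n")
        for z, p, t, s in zip(profile.depth_m, profile.pressure_dbar,
                              profile.temperature_c, profile.salinity_psu):
            fh.write(f"{z:.10g},{p:.10g},{t:.10g},{s:.10g}\n")


def read_ctd_csv(path) -> CtdProfile:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, comment="#")
    return CtdProfile(
        cast_date=pd.Timestamp(meta.get("cast_date", "1970-01-01")),
        depth_m=df["depth_m"].to_numpy(),
        pressure_dbar=df["pressure_dbar"].to_numpy(),
        temperature_c=df["temperature_C"].to_numpy(),
        salinity_psu=df["salinity_psu"].to_numpy(),
        station_depth_m=float(meta.get("station_depth_m", 40.0)),
    )
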