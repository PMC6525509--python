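"""Water-column stability: density profiles and Brunt-Vaisala frequency.

Thermal stratification strength is summarized by the maximum squared
buoyancy frequency N^2 = (g/rho_bar) * d(rho)/dz over a site's temperature
profile (z positive downward, so warm-over-cold columns are stable,
N^2 > 0).  Following common limnological reporting, the statistic is
quoted in s^-2 (i.e. N^2, not N) and unstable interfaces are floored at 0
for the per-site maximum only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "StabilityResult",
    "water_density",
    "buoyancy_frequency",
    "read_profiles_csv",
]

GRAVITY_M_S2 = 9.80665


@dataclass(frozen=True)
class DepthProfile:
    """Sonde casts at ~0.5 m spacing from the surface to the sediment."""

    site_id: str
    depths_m: tuple[float, ...]
    temperatures_c: tuple[float, ...]
    salinity: tuple[float, ...] | None = None
    do_pct_sat: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        z = tuple(float(v) for v in self.depths_m)
        t = tuple(float(v) for v in self.temperatures_c)
        object.__setattr__(self, "depths_m", z)
        object.__setattr__(self, "temperatures_c", t)
        if len(z) < 2:
            raise ValueError("profile needs >= 2 depths")
        if len(z) != len(t):
            raise ValueError("depths and temperatures differ in length")
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError("depths must be strictly increasing (duplicates?)")
        for name in ("salinity", "do_pct_sat"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != len(z):
                raise ValueError(f"{name} length does not match depths")

    @property
    def surface_do(self) -> float | None:
        return None if self.do_pct_sat is None else float(self.do_pct_sat[0])

    @property
    def bottom_do(self) -> float | None:
        return None if self.do_pct_sat is None else float(self.do_pct_sat[-1])


@dataclass(frozen=True)
class StabilityResult:
    site_id: str
    interface_depths_m: tuple[float, ...]
    n_squared_s2: tuple[float, ...]
    max_buoyancy_frequency_s2: float


def water_density(temperature_c: float, salinity: float = 0.0) -> float:
    """Freshwater density (kg m-3) from temperature, with optional salinity.

    Standard limnological polynomial (maximum near 4 degC); the salinity
    term is a simple linear haline contraction adequate for the low
    salinities of inland waters and is off (0) by default.
    """
    t = float(temperature_c)
    if not -2.0 <= t <= 40.0:
        raise ValueError(f"temperature {t} degC outside [-2, 40]")
    rho = 1000.0 * (
        1.0 - (t + 288.9414) / (508929.2 * (t + 68.12963)) * (t - 3.9863) ** 2
    )
    return rho + 0.8054 * float(salinity)


def buoyancy_frequency(
    profile: DepthProfile,
    scheme: Literal["midpoint", "centered"] = "midpoint",
    use_salinity: bool = False,
) -> StabilityResult:
    """Brunt-Vaisala N^2 profile and its non-negative maximum.

    ``midpoint`` evaluates (g/rho_bar) * delta(rho)/delta(z) between
    adjacent samples, placing each value at the layer midpoint;
    ``centered`` uses centered differences at interior sample depths.
    Raw interface values retain their sign; only the per-site maximum is
    floored at zero (an unstable or isothermal column has max N^2 = 0).
    """
    z = np.asarray(profile.depths_m)
    sal = (
        np.asarray(profile.salinity)
        if (use_salinity and profile.salinity is not None)
        else np.zeros_like(z)
    )
    rho = np.array(
        [water_density(t, s) for t, s in zip(profile.temperatures_c, sal)]
    )
    if scheme == "midpoint":
        drho = np.diff(rho)
        dz = np.diff(z)
        rho_bar = 0.5 * (rho[:-1] + rho[1:])
        n2 = GRAVITY_M_S2 / rho_bar * drho / dz
        at = 0.5 * (z[:-1] + z[1:])
    elif scheme == "centered":
        grad = np.gradient(rho, z)
        n2 = GRAVITY_M_S2 / rho * grad
        at = z
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    max_bf = max(0.0, float(n2.max()))
    return StabilityResult(
        site_id=profile.site_id,
        interface_depths_m=tuple(float(v) for v in at),
        n_squared_s2=tuple(float(v) for v in n2),
        max_buoyancy_frequency_s2=max_bf,
    )


def read_profiles_csv(path) -> list[DepthProfile]:
    """Long-format profile reader.

    Columns: site_id, depth_m, temp_c, plus optional do_pct_sat, salinity.
    Surface and bottom dissolved oxygen for the driver analysis come from
    the shallowest and deepest rows of each site.
    """
    df = pd.read_csv(path)
    required = {"site_id", "depth_m", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for site, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("depth_m")
        profiles.append(
            DepthProfile(
                site_id=str(site),
                depths_m=tuple(grp["depth_m"].astype(float)),
                temperatures_c=tuple(grp["temp_c"].astype(float)),
                salinity=(
                    tuple(grp["salinity"].astype(float))
                    if "salinity" in grp.columns
                    else None
                ),
                do_pct_sat=(
                    tuple(grp["do_pct_sat"].astype(float))
                    if "do_pct_sat" in grp.columns
                    else None
                ),
            )
        )
    return profiles
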