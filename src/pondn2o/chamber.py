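"""Gas transfer velocity from floating-chamber incubations.

A floating chamber (default 0.23 m2 area, 0.046 m3 volume) accumulates gas
from the water surface; five headspace samples taken every 2.5 min over
10 min give a concentration time series.  The workflow is:

1. ordinary least-squares slope of chamber concentration vs time,
2. quality control: reject series whose total change is within analyzer
   accuracy, whose regression r2 is below threshold, or which show a
   step-like jump indicating an ebullition (bubble) event,
3. flux from the slope and chamber geometry (ideal-gas molar volume),
4. inversion of Fick's law to the CH4 transfer velocity k_CH4,
5. Schmidt-number conversion to k_N2O,
6. fleet averaging over accepted incubations.

N2O accumulation in a 10-min deployment is usually below analyzer accuracy,
so k is derived from the co-measured CH4 series and converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from statistics import fmean, stdev
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gases import (
    Gas,
    WaterState,
    convert_k,
    molar_volume,
    schmidt_number,
    solubility_coefficient,
)

__all__ = [
    "ChamberIncubation",
    "QcReason",
    "QcVerdict",
    "KEstimate",
    "fit_slope",
    "qc_incubation",
    "chamber_flux",
    "k_from_flux",
    "analyze_incubation",
    "fleet_k",
    "read_chamber_csv",
    "estimates_to_frame",
]

DEFAULT_TIMES_MIN = (0.0, 2.5, 5.0, 7.5, 10.0)
MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class ChamberIncubation:
    """One floating-chamber time series with geometry and site state.

    ``concentrations_uatm`` are chamber partial pressures (uatm ~ ppm at
    1 atm); ``water_partial_pressure_uatm`` is the dissolved-gas partial
    pressure of the surface water and ``ambient_uatm`` the atmospheric one.
    """

    site_id: str
    gas: Gas
    times_min: tuple[float, ...]
    concentrations_uatm: tuple[float, ...]
    water_partial_pressure_uatm: float
    ambient_uatm: float
    state: WaterState
    chamber_area_m2: float = 0.23
    chamber_volume_m3: float = 0.046
    air_temperature_c: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gas", Gas.parse(self.gas))
        t = tuple(float(v) for v in self.times_min)
        c = tuple(float(v) for v in self.concentrations_uatm)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "concentrations_uatm", c)
        if len(t) != len(c) or len(t) < 3:
            raise ValueError("need >= 3 paired (time, concentration) points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if self.chamber_area_m2 <= 0 or self.chamber_volume_m3 <= 0:
            raise ValueError("chamber area and volume must be > 0")

    @property
    def air_temp_c(self) -> float:
        """Air temperature for the molar volume; falls back to water temperature."""
        if self.air_temperature_c is not None:
            return self.air_temperature_c
        return self.state.temperature


class QcReason(str, Enum):
    OK = "ok"
    LOW_R2 = "low_r2"
    BELOW_ACCURACY = "below_accuracy"
    EBULLITION_STEP = "ebullition_step"


@dataclass(frozen=True)
class QcVerdict:
    accepted: bool
    reason: QcReason

    def __post_init__(self) -> None:
        if self.accepted != (self.reason is QcReason.OK):
            raise ValueError("accepted must be True iff reason is 'ok'")


@dataclass(frozen=True)
class KEstimate:
    """Slope, flux and gas transfer velocities for one incubation."""

    site_id: str
    slope_uatm_min: float
    r_squared: float
    verdict: QcVerdict
    flux_umol_m2_d: float | None = None
    k_ch4_m_d: float | None = None
    k_n2o_m_d: float | None = None
    flags: tuple[str, ...] = ()


def fit_slope(incubation: ChamberIncubation) -> tuple[float, float]:
    """OLS slope (uatm min-1) and r2 of chamber concentration vs time.

    A zero-variance (constant) response has r2 defined as 0, so the QC
    accuracy/r2 rules reject it rather than dividing 0/0.
    """
    t = np.asarray(incubation.times_min)
    c = np.asarray(incubation.concentrations_uatm)
    t_c = t - t.mean()
    c_c = c - c.mean()
    sxx = float(t_c @ t_c)
    syy = float(c_c @ c_c)
    slope = float(t_c @ c_c) / sxx
    r2 = 0.0 if syy == 0 else slope * slope * sxx / syy
    return slope, r2


def qc_incubation(
    incubation: ChamberIncubation,
    slope: float,
    r_squared: float,
    accuracy_fraction: float = 0.02,
    r2_min: float = 0.7,
    step_multiplier: float = 3.0,
) -> QcVerdict:
    """Apply the three rejection rules, reporting the first that fires.

    Order: (1) total concentration change within analyzer accuracy
    (|last - first| <= accuracy_fraction * series mean), (2) regression
    r2 < r2_min, (3) a single between-sample increment exceeding
    ``step_multiplier`` times the median absolute increment (a scale-free
    step/ebullition detector for short series).
    """
    c = np.asarray(incubation.concentrations_uatm)
    total_change = abs(c[-1] - c[0])
    if total_change <= accuracy_fraction * abs(c.mean()):
        return QcVerdict(False, QcReason.BELOW_ACCURACY)
    if r_squared < r2_min:
        return QcVerdict(False, QcReason.LOW_R2)
    increments = np.abs(np.diff(c))
    med = float(np.median(increments))
    if med > 0 and float(increments.max()) > step_multiplier * med:
        return QcVerdict(False, QcReason.EBULLITION_STEP)
    return QcVerdict(True, QcReason.OK)


def chamber_flux(slope_uatm_min: float, incubation: ChamberIncubation) -> float:
    """Flux (umol m-2 d-1) from the chamber slope.

    flux = s * V[L] / (Vm[L mol-1] * A[m2]) * 1440, with the ideal-gas molar
    volume at local pressure and air temperature.  A uatm min-1 slope over a
    Vm molar volume yields umol min-1 per litre of chamber.
    """
    vm = molar_volume(incubation.air_temp_c, incubation.state.pressure)
    volume_l = incubation.chamber_volume_m3 * 1000.0
    return (
        slope_uatm_min * volume_l / (vm * incubation.chamber_area_m2) * MINUTES_PER_DAY
    )


def k_from_flux(flux_umol_m2_d: float, incubation: ChamberIncubation) -> float:
    """Invert Fick's law for the transfer velocity (m d-1).

    k = flux / (K0 * (p_water - p_air)) * 1e-3: K0 in mol L-1 atm-1 times a
    uatm gradient gives umol L-1; dividing the areal flux by it leaves
    L m-2 d-1, i.e. 1e-3 m d-1.  The result is negative when the flux
    opposes the gradient (caller should flag such incubations).
    """
    delta_p = incubation.water_partial_pressure_uatm - incubation.ambient_uatm
    if delta_p == 0:
        raise ZeroDivisionError("k undefined for zero air-water gradient")
    k0 = solubility_coefficient(incubation.gas, incubation.state).value
    return flux_umol_m2_d / (k0 * delta_p) * 1e-3


def analyze_incubation(
    incubation: ChamberIncubation,
    accuracy_fraction: float = 0.02,
    r2_min: float = 0.7,
    step_multiplier: float = 3.0,
    schmidt_exponent: float = 0.67,
) -> KEstimate:
    """Full per-incubation workflow: fit, QC, flux, k_CH4, k_N2O."""
    slope, r2 = fit_slope(incubation)
    verdict = qc_incubation(
        incubation, slope, r2, accuracy_fraction, r2_min, step_multiplier
    )
    if not verdict.accepted:
        return KEstimate(incubation.site_id, slope, r2, verdict)
    flux = chamber_flux(slope, incubation)
    k_gas = k_from_flux(flux, incubation)
    flags: tuple[str, ...] = ()
    if k_gas < 0:
        flags = ("sign_mismatch",)
    t = min(max(incubation.state.temperature, 0.0), 35.0)
    sc_gas = schmidt_number(incubation.gas, t)
    sc_n2o = schmidt_number(Gas.N2O, t)
    if incubation.gas is Gas.N2O:
        k_ch4 = convert_k(abs(k_gas), sc_gas, schmidt_number(Gas.CH4, t), schmidt_exponent)
        k_n2o = abs(k_gas)
    else:
        k_ch4 = abs(k_gas)
        k_n2o = convert_k(abs(k_gas), sc_gas, sc_n2o, schmidt_exponent)
    return KEstimate(
        site_id=incubation.site_id,
        slope_uatm_min=slope,
        r_squared=r2,
        verdict=verdict,
        flux_umol_m2_d=flux,
        k_ch4_m_d=k_ch4,
        k_n2o_m_d=k_n2o,
        flags=flags,
    )


def fleet_k(estimates: Iterable[KEstimate]) -> tuple[float, float, int]:
    """Mean and SD of k_N2O over accepted, unflagged incubations.

    Returns (mean, sd, n_used).  Sites without their own chamber deployment
    inherit this fleet mean downstream.
    """
    ks = [
        e.k_n2o_m_d
        for e in estimates
        if e.verdict.accepted and e.k_n2o_m_d is not None and not e.flags
    ]
    if not ks:
        raise ValueError("no accepted chamber incubations")
    mean = fmean(ks)
    sd = stdev(ks) if len(ks) > 1 else 0.0
    return mean, sd, len(ks)


def read_chamber_csv(series_path, sidecar_path) -> list[ChamberIncubation]:
    """Read long-format chamber series plus a per-incubation sidecar.

    ``series_path`` columns: incubation_id, time_min, conc_uatm.
    ``sidecar_path`` columns: incubation_id, site_id, gas, water_puatm,
    ambient_uatm, water_temp_c, plus optional salinity, pressure_atm,
    area_m2, volume_m3, air_temp_c.
    """
    series = pd.read_csv(series_path)
    meta = pd.read_csv(sidecar_path).set_index("incubation_id")
    incubations: list[ChamberIncubation] = []
    for inc_id, grp in series.groupby("incubation_id", sort=False):
        if inc_id not in meta.index:
            raise ValueError(f"incubation {inc_id!r} missing from sidecar")
        m = meta.loc[inc_id]
        grp = grp.sort_values("time_min")
        state = WaterState(
            temperature=float(m["water_temp_c"]),
            salinity=float(m.get("salinity", 0.0) or 0.0),
            pressure=float(m.get("pressure_atm", 1.0) or 1.0),
        )
        air_t = m.get("air_temp_c")
        incubations.append(
            ChamberIncubation(
                site_id=str(m["site_id"]),
                gas=Gas.parse(m["gas"]),
                times_min=tuple(grp["time_min"].astype(float)),
                concentrations_uatm=tuple(grp["conc_uatm"].astype(float)),
                water_partial_pressure_uatm=float(m["water_puatm"]),
                ambient_uatm=float(m["ambient_uatm"]),
                state=state,
                chamber_area_m2=float(m.get("area_m2", 0.23) or 0.23),
                chamber_volume_m3=float(m.get("volume_m3", 0.046) or 0.046),
                air_temperature_c=None if pd.isna(air_t) else float(air_t),
            )
        )
    return incubations


def estimates_to_frame(estimates: Sequence[KEstimate]) -> pd.DataFrame:
    """Per-incubation results as a tidy frame (one row per incubation)."""
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in estimates],
            "slope_uatm_min": [e.slope_uatm_min for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "accepted": [e.verdict.accepted for e in estimates],
            "qc_reason": [e.verdict.reason.value for e in estimates],
            "flux_umol_m2_d": [e.flux_umol_m2_d for e in estimates],
            "k_ch4_m_d": [e.k_ch4_m_d for e in estimates],
            "k_n2o_m_d": [e.k_n2o_m_d for e in estimates],
        }
    )
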