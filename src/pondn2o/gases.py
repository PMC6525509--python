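"""Physical chemistry of dissolved N2O and CH4.

Solubility coefficients (Henry-law K0, mol L-1 atm-1), Schmidt numbers,
atmospheric-equilibrium concentrations, and Schmidt-scaling of gas transfer
velocities between gases.  Coefficient tables are shipped as a plain-text
data file (``data/gas_coefficients.csv``) so alternative parameterizations
can be swapped without touching the formulas.

Conventions
-----------
* K0 follows the seawater-scale solubility fits: N2O directly in
  mol L-1 atm-1 (Weiss & Price 1980), CH4 via the Bunsen coefficient
  (Yamamoto et al. 1976) divided by the STP molar volume 22.414 L mol-1.
* Schmidt numbers use the freshwater third-order polynomials of
  Wanninkhof (1992); a salinity-interpolated variant is available.
* Gas transfer velocities scale as k ~ Sc**(-n); converting k from a source
  gas to a target gas multiplies by (Sc_target/Sc_source)**(-n), with
  n = 0.67 for a turbulent chamber-derived exchange.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from functools import lru_cache

__all__ = [
    "Gas",
    "WaterState",
    "SolubilityCoefficient",
    "SchmidtNumber",
    "solubility_coefficient",
    "schmidt_number",
    "equilibrium_concentration",
    "convert_k",
    "water_vapor_pressure",
    "molar_volume",
    "GasDomainError",
]

#: STP molar volume used to convert Bunsen coefficients to K0, L mol-1.
STP_MOLAR_VOLUME_L = 22.414

#: Ideal-gas constant in L atm mol-1 K-1.
R_L_ATM = 0.0820573


class GasDomainError(ValueError):
    """An input falls outside the physical/validity range of a gas formula."""


class Gas(str, Enum):
    """Supported gas species."""

    N2O = "N2O"
    CH4 = "CH4"

    @classmethod
    def parse(cls, name: "Gas | str") -> "Gas":
        if isinstance(name, Gas):
            return name
        try:
            return cls(str(name).strip().upper().replace("₂", "2").replace("₄", "4"))
        except ValueError:
            raise GasDomainError(
                f"unsupported gas {name!r}; supported: N2O, CH4"
            ) from None


@dataclass(frozen=True)
class WaterState:
    """Temperature/salinity/pressure state of a water sample.

    Parameters
    ----------
    temperature : float
        Water temperature, degrees C.  Must lie in [-2, 40].
    salinity : float
        Practical salinity (dimensionless), >= 0.  Farm reservoirs are
        treated as fresh water (0) unless a sonde salinity is supplied.
    pressure : float
        Total (local atmospheric) pressure, atm.  Survey use restricts
        this to (0.5, 1.5).
    """

    temperature: float
    salinity: float = 0.0
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not -2.0 <= self.temperature <= 40.0:
            raise GasDomainError(
                f"temperature {self.temperature} degC outside [-2, 40]"
            )
        if self.salinity < 0:
            raise GasDomainError(f"salinity {self.salinity} must be >= 0")
        if not 0.5 < self.pressure < 1.5:
            raise GasDomainError(
                f"pressure {self.pressure} atm outside (0.5, 1.5)"
            )

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class SolubilityCoefficient:
    """Henry-law solubility K0 in mol L-1 atm-1 for a gas in a water state."""

    value: float
    gas: Gas
    state: WaterState


@dataclass(frozen=True)
class SchmidtNumber:
    """Dimensionless Schmidt number (kinematic viscosity / gas diffusivity)."""

    value: float
    gas: Gas
    temperature: float


@lru_cache(maxsize=1)
def _coefficient_table() -> dict[tuple[str, str], dict[str, float]]:
    table: dict[tuple[str, str], dict[str, float]] = {}
    path = resources.files("pondn2o.data").joinpath("gas_coefficients.csv")
    with path.open("r", newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["gas"], row["set"])
            table.setdefault(key, {})[row["coefficient"]] = float(row["value"])
    return table


def water_vapor_pressure(temperature: float, salinity: float = 0.0) -> float:
    """Saturation vapor pressure over (sea)water, atm.

    Weiss & Price (1980) companion fit: ln p = A + B*(100/T) + C*ln(T/100)
    + D*S, T in kelvin.
    """
    c = _coefficient_table()[("H2O", "vapor_pressure")]
    t = temperature + 273.15
    return math.exp(
        c["A"] + c["B"] * (100.0 / t) + c["C"] * math.log(t / 100.0) + c["D"] * salinity
    )


def molar_volume(temperature: float, pressure: float = 1.0) -> float:
    """Ideal-gas molar volume, L mol-1, at the given air temperature/pressure."""
    if pressure <= 0:
        raise GasDomainError(f"pressure {pressure} atm must be > 0")
    if not -40.0 <= temperature <= 60.0:
        raise GasDomainError(f"air temperature {temperature} degC implausible")
    return R_L_ATM * (temperature + 273.15) / pressure


def solubility_coefficient(gas: Gas | str, state: WaterState) -> SolubilityCoefficient:
    """Henry-law K0 (mol L-1 atm-1) at the sample temperature and salinity.

    N2O uses the Weiss & Price (1980) K0 fit; CH4 uses the Yamamoto et
    al. (1976) Bunsen-coefficient fit divided by 22.414 L mol-1.  Both share
    the functional form ln X = A1 + A2*(100/T) + A3*ln(T/100)
    + S*(B1 + B2*(T/100) + B3*(T/100)^2).
    """
    gas = Gas.parse(gas)
    t = state.kelvin
    if gas is Gas.N2O:
        c = _coefficient_table()[("N2O", "solubility_k0")]
    else:
        c = _coefficient_table()[("CH4", "solubility_bunsen")]
    th = t / 100.0
    ln_x = (
        c["A1"]
        + c["A2"] / th
        + c["A3"] * math.log(th)
        + state.salinity * (c["B1"] + c["B2"] * th + c["B3"] * th * th)
    )
    value = math.exp(ln_x)
    if gas is Gas.CH4:
        value /= STP_MOLAR_VOLUME_L
    return SolubilityCoefficient(value=value, gas=gas, state=state)


def schmidt_number(
    gas: Gas | str, temperature: float, salinity: float = 0.0
) -> SchmidtNumber:
    """Schmidt number at a water temperature (degC) on 0-35 degC.

    Freshwater polynomials by default; when ``salinity`` > 0 the value is
    linearly interpolated between the freshwater and seawater (S=35)
    polynomials, the usual brackish-water approximation.
    """
    gas = Gas.parse(gas)
    if not 0.0 <= temperature <= 35.0:
        raise GasDomainError(
            f"temperature {temperature} degC outside Schmidt validity [0, 35]"
        )
    if salinity < 0:
        raise GasDomainError(f"salinity {salinity} must be >= 0")

    def poly(setname: str) -> float:
        c = _coefficient_table()[(gas.value, setname)]
        t = temperature
        return c["A"] + c["B"] * t + c["C"] * t * t + c["D"] * t ** 3

    fresh = poly("schmidt_freshwater")
    if salinity == 0:
        value = fresh
    else:
        sea = poly("schmidt_seawater")
        w = min(salinity, 35.0) / 35.0
        value = (1 - w) * fresh + w * sea
    return SchmidtNumber(value=value, gas=gas, temperature=temperature)


def equilibrium_concentration(
    gas: Gas | str,
    state: WaterState,
    mixing_ratio_uatm: float,
    moist_air: bool = True,
) -> float:
    """Dissolved concentration (nM) in equilibrium with the atmosphere.

    ``mixing_ratio_uatm`` is the dry molar fraction in ppm (numerically the
    partial pressure in uatm at 1 atm of dry air).  With ``moist_air`` the
    dry fraction is referenced to total pressure minus saturation vapor
    pressure, matching how dry GC readings relate to in-situ partial
    pressure over a water surface.
    """
    gas = Gas.parse(gas)
    if mixing_ratio_uatm < 0:
        raise GasDomainError(f"mixing ratio {mixing_ratio_uatm} must be >= 0")
    k0 = solubility_coefficient(gas, state).value
    p_dry = state.pressure
    if moist_air:
        p_dry = state.pressure - water_vapor_pressure(state.temperature, state.salinity)
    partial_atm = mixing_ratio_uatm * 1e-6 * p_dry
    return k0 * partial_atm * 1e9  # mol/L -> nmol/L


def convert_k(
    k_source: float,
    sc_source: SchmidtNumber | float,
    sc_target: SchmidtNumber | float,
    exponent: float = 0.67,
) -> float:
    """Convert a gas transfer velocity between gases via Schmidt scaling.

    k_target = k_source * (Sc_target / Sc_source)**(-exponent), the standard
    k ~ Sc**(-n) convention.  ``exponent=0.67`` suits a freely turbulent
    (chamber) surface.
    """
    s_src = sc_source.value if isinstance(sc_source, SchmidtNumber) else float(sc_source)
    s_tgt = sc_target.value if isinstance(sc_target, SchmidtNumber) else float(sc_target)
    if s_src <= 0 or s_tgt <= 0:
        raise GasDomainError("Schmidt numbers must be > 0")
    if k_source < 0:
        raise GasDomainError(f"k_source {k_source} must be >= 0")
    return k_source * (s_tgt / s_src) ** (-exponent)
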