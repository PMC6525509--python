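"""Headspace-equilibration back-calculation of dissolved gas concentration.

A water sample fills a serum bottle (default 1.2 L), ambient air (default
60 mL) is added as a headspace, and the sealed bottle is shaken to
equilibrium.  The GC reports the dry molar fraction (ppm) of the
equilibrated headspace; together with the ambient-air molar fraction this
determines the original dissolved concentration by a two-compartment mole
balance:

    C0 * Vw + x_air * n_dry * (Vg/RT)  =  K0 * p_f * Vw + x_hs * n_dry * (Vg/RT)

where p_f is the post-equilibration partial pressure implied by the
measured headspace fraction.  Replicates are back-calculated individually
and averaged; their standard deviation is the per-site analytical
uncertainty used downstream as the sink/source classification band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean, stdev
from typing import Iterable

import pandas as pd

from .gases import (
    Gas,
    R_L_ATM,
    WaterState,
    equilibrium_concentration,
    solubility_coefficient,
    water_vapor_pressure,
)

__all__ = [
    "DissolvedGasSample",
    "ConcentrationResult",
    "back_calculate",
    "forward_equilibrate",
    "fleet_uncertainty",
    "read_headspace_csv",
]

#: Back-calculated concentrations below this (nM) are flagged, not clamped.
NEGATIVE_TOLERANCE_NM = -1e-6


@dataclass(frozen=True)
class DissolvedGasSample:
    """One site's headspace measurement (possibly replicated).

    ``headspace_ppm_replicates`` and ``air_ppm`` are dry molar fractions in
    ppm as reported by the GC.  Geometry defaults follow the field protocol
    (1.2 L bottle, 60 mL added air headspace).
    """

    site_id: str
    gas: Gas
    headspace_ppm_replicates: tuple[float, ...]
    air_ppm: float
    equilibration_state: WaterState
    bottle_volume_l: float = 1.2
    headspace_volume_l: float = 0.060

    def __post_init__(self) -> None:
        object.__setattr__(self, "gas", Gas.parse(self.gas))
        reps = tuple(float(v) for v in self.headspace_ppm_replicates)
        object.__setattr__(self, "headspace_ppm_replicates", reps)
        if len(reps) < 1:
            raise ValueError("at least one headspace replicate is required")
        if any(v < 0 for v in reps) or self.air_ppm < 0:
            raise ValueError("ppm values must be >= 0")
        if not 0 < self.headspace_volume_l < self.bottle_volume_l:
            raise ValueError("need 0 < headspace volume < bottle volume")

    @property
    def water_volume_l(self) -> float:
        return self.bottle_volume_l - self.headspace_volume_l


@dataclass(frozen=True)
class ConcentrationResult:
    """Back-calculated dissolved concentration for one site, in nM."""

    site_id: str
    gas: Gas
    concentration_nm: float
    uncertainty_nm: float
    equilibrium_nm: float
    replicate_nm: tuple[float, ...] = field(default_factory=tuple)
    quality: str = "ok"  # "ok" | "negative_concentration"

    @property
    def saturation_ratio(self) -> float:
        if self.equilibrium_nm <= 0:
            raise ValueError("saturation ratio undefined for zero equilibrium")
        return self.concentration_nm / self.equilibrium_nm


def _mole_balance_terms(
    sample: DissolvedGasSample, moist_air: bool
) -> tuple[float, float, float]:
    """Return (k0, dry-pressure factor, headspace moles per ppm)."""
    state = sample.equilibration_state
    k0 = solubility_coefficient(sample.gas, state).value
    p_dry = state.pressure
    if moist_air:
        p_dry -= water_vapor_pressure(state.temperature, state.salinity)
    # moles of analyte in headspace per ppm of dry molar fraction
    gas_moles_per_ppm = 1e-6 * p_dry * sample.headspace_volume_l / (R_L_ATM * state.kelvin)
    return k0, p_dry, gas_moles_per_ppm


def _back_calculate_one(
    sample: DissolvedGasSample, headspace_ppm: float, moist_air: bool
) -> float:
    k0, p_dry, g = _mole_balance_terms(sample, moist_air)
    vw = sample.water_volume_l
    p_final_atm = headspace_ppm * 1e-6 * p_dry
    # mol in final water + net mol moved into the headspace, per L of water
    c0_mol_l = k0 * p_final_atm + (headspace_ppm - sample.air_ppm) * g / vw
    return c0_mol_l * 1e9  # nM


def back_calculate(sample: DissolvedGasSample, moist_air: bool = True) -> ConcentrationResult:
    """Solve the equilibration mole balance for the in-situ concentration.

    Each analytical replicate is back-calculated individually; the result is
    their mean with the (population) standard deviation as uncertainty.  A
    concentration more negative than numerical tolerance is flagged
    ``negative_concentration`` (possible leak or GC error) rather than
    silently clamped.
    """
    reps = tuple(
        _back_calculate_one(sample, ppm, moist_air)
        for ppm in sample.headspace_ppm_replicates
    )
    conc = fmean(reps)
    sigma = stdev(reps) if len(reps) > 1 else 0.0
    c_eq = equilibrium_concentration(
        sample.gas, sample.equilibration_state, sample.air_ppm, moist_air=moist_air
    )
    quality = "ok" if conc >= NEGATIVE_TOLERANCE_NM else "negative_concentration"
    return ConcentrationResult(
        site_id=sample.site_id,
        gas=sample.gas,
        concentration_nm=conc,
        uncertainty_nm=sigma,
        equilibrium_nm=c_eq,
        replicate_nm=reps,
        quality=quality,
    )


def forward_equilibrate(
    c0_nm: float, sample: DissolvedGasSample, moist_air: bool = True
) -> float:
    """Simulate the equilibration forward: initial C0 (nM) -> headspace ppm.

    The exact inverse of :func:`back_calculate` for a single replicate; used
    by the synthetic generator and the round-trip tests.
    """
    k0, p_dry, g = _mole_balance_terms(sample, moist_air)
    vw = sample.water_volume_l
    total_mol = c0_nm * 1e-9 * vw + sample.air_ppm * g
    # total = x_hs * (k0 * 1e-6 * p_dry * vw + g)
    return total_mol / (k0 * 1e-6 * p_dry * vw + g)


def fleet_uncertainty(results: Iterable[ConcentrationResult]) -> float:
    """Mean of per-site replicate standard deviations (nM).

    This fleet-average analytical uncertainty is the half-width of the
    sink/source/equilibrium classification band.
    """
    sigmas = [r.uncertainty_nm for r in results]
    if not sigmas:
        raise ValueError("fleet_uncertainty requires at least one result")
    return fmean(sigmas)


def read_headspace_csv(path) -> list[DissolvedGasSample]:
    """Read one-row-per-replicate headspace data into samples.

    Expected columns: site_id, gas, headspace_ppm, air_ppm, water_temp_c,
    salinity, pressure_atm, and optional bottle_vol_l / headspace_vol_l
    (defaulting to 1.2 / 0.060).
    """
    df = pd.read_csv(path)
    required = {"site_id", "gas", "headspace_ppm", "air_ppm", "water_temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"headspace CSV missing columns: {sorted(missing)}")
    samples: list[DissolvedGasSample] = []
    for (site, gas), grp in df.groupby(["site_id", "gas"], sort=False):
        first = grp.iloc[0]
        state = WaterState(
            temperature=float(first["water_temp_c"]),
            salinity=float(first.get("salinity", 0.0) or 0.0),
            pressure=float(first.get("pressure_atm", 1.0) or 1.0),
        )
        samples.append(
            DissolvedGasSample(
                site_id=str(site),
                gas=Gas.parse(gas),
                headspace_ppm_replicates=tuple(grp["headspace_ppm"].astype(float)),
                air_ppm=float(first["air_ppm"]),
                equilibration_state=state,
                bottle_volume_l=float(first.get("bottle_vol_l", 1.2) or 1.2),
                headspace_volume_l=float(first.get("headspace_vol_l", 0.060) or 0.060),
            )
        )
    return samples
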