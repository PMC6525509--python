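"""Literature N2O emission models and observed-vs-predicted comparison.

Three model families are supported:

* ``ipcc_ef`` — the IPCC indirect-emission EF(B) method: dissolved N2O-N is
  an emission factor (default 0.0025) times the NOx-N concentration; the
  predicted concentration is routed through the bulk flux relation with the
  fleet gas transfer velocity.
* ``area_chla_linear`` — a linear flux model in waterbody surface area and
  chlorophyll-a (coefficients must be supplied via configuration; they are
  published elsewhere and are deliberately not shipped).
* ``nox_linear`` — a linear flux model in NOx alone (likewise configured).

Throughout, "N2O-N" denotes the nitrogen mass within N2O: 28 g N per mol
N2O (two N atoms); converting N2O-N mass to N2O mass multiplies by 44/28.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fluxes import FluxEstimate, n2o_flux

__all__ = [
    "EmissionModelName",
    "EmissionModel",
    "ipcc_predicted_concentration",
    "predicted_flux",
    "compare",
    "ModelComparison",
    "co2_equivalent",
    "N_G_PER_MOL_N2O",
    "N2O_G_PER_MOL",
]

#: grams of nitrogen per mole of N2O (two N atoms).
N_G_PER_MOL_N2O = 28.0134
#: grams of N2O per mole.
N2O_G_PER_MOL = 44.0128

DEFAULT_IPCC_EF = 0.0025


class EmissionModelName(str, Enum):
    IPCC_EF = "ipcc_ef"
    AREA_CHLA_LINEAR = "area_chla_linear"
    NOX_LINEAR = "nox_linear"


@dataclass(frozen=True)
class EmissionModel:
    """A literature emission model with configured coefficients.

    ``coefficients`` for the linear models must include ``intercept`` plus
    one slope per covariate (``area_m2``/``log_area``, ``chla``/``log_chla``,
    ``nox``/``log_nox`` are recognized); units of the linear predictor are
    declared via ``output_units`` ("mg_n_m2_d" or "umol_m2_d").
    """

    name: EmissionModelName
    coefficients: Mapping[str, float] = field(default_factory=dict)
    reference: str = ""
    output_units: str = "mg_n_m2_d"

    def __post_init__(self) -> None:
        if self.name is EmissionModelName.IPCC_EF:
            ef = self.coefficients.get("emission_factor", DEFAULT_IPCC_EF)
            if ef < 0:
                raise ValueError("emission factor must be >= 0")
        else:
            if "intercept" not in self.coefficients:
                raise ValueError(
                    f"model {self.name.value!r} requires an 'intercept' coefficient"
                )


def ipcc_predicted_concentration(
    no3_n_ug_l: float, emission_factor: float = DEFAULT_IPCC_EF
) -> float:
    """EF(B) dissolved N2O-N (ug N L-1) from NOx-N concentration."""
    if no3_n_ug_l < 0:
        raise ValueError(f"NOx-N {no3_n_ug_l} must be >= 0")
    if emission_factor < 0:
        raise ValueError(f"emission factor {emission_factor} must be >= 0")
    return emission_factor * no3_n_ug_l


def n2o_n_ug_l_to_nm(n2o_n_ug_l: float) -> float:
    """ug N2O-N per litre -> nM of N2O (divide by 28 g N per mol N2O)."""
    return n2o_n_ug_l / N_G_PER_MOL_N2O * 1e3


def umol_m2_d_to_mg_n_m2_d(flux_umol: float) -> float:
    """umol N2O m-2 d-1 -> mg N2O-N m-2 d-1 (x 28.0134 g N / mol / 1000)."""
    return flux_umol * N_G_PER_MOL_N2O * 1e-3


def mg_n_m2_d_to_umol_m2_d(flux_mg_n: float) -> float:
    return flux_mg_n / N_G_PER_MOL_N2O * 1e3


def predicted_flux(
    model: EmissionModel,
    site: Mapping[str, float],
    k_m_d: float,
    c_eq_nm: float | None = None,
) -> dict[str, float]:
    """Predicted N2O flux for one site, in both comparison units.

    The EF(B) route converts the predicted dissolved concentration to nM
    and applies f = k (C_pred - C_eq); with zero NOx the model predicts
    zero dissolved N2O so the flux is an influx, k * (0 - C_eq).  Linear
    models return their linear predictor directly as a flux.
    Returns ``{"flux_umol_m2_d": ..., "flux_mg_n_m2_d": ...}``.
    """
    if model.name is EmissionModelName.IPCC_EF:
        if "nox" not in site:
            raise ValueError("ipcc_ef requires site covariate 'nox' (ug N L-1)")
        if c_eq_nm is None:
            raise ValueError("ipcc_ef requires the site equilibrium concentration")
        ef = model.coefficients.get("emission_factor", DEFAULT_IPCC_EF)
        conc_nm = n2o_n_ug_l_to_nm(ipcc_predicted_concentration(site["nox"], ef))
        flux_umol = n2o_flux(conc_nm, c_eq_nm, k_m_d)
        return {
            "flux_umol_m2_d": flux_umol,
            "flux_mg_n_m2_d": umol_m2_d_to_mg_n_m2_d(flux_umol),
        }
    pred = model.coefficients["intercept"]
    for key, slope in model.coefficients.items():
        if key in ("intercept", "emission_factor"):
            continue
        if key.startswith("log_"):
            raw = key[4:]
            if raw not in site:
                raise ValueError(f"model {model.name.value} missing covariate {raw!r}")
            if site[raw] <= 0:
                raise ValueError(f"covariate {raw!r} must be > 0 for a log term")
            pred += slope * float(np.log10(site[raw]))
        else:
            if key not in site:
                raise ValueError(f"model {model.name.value} missing covariate {key!r}")
            pred += slope * site[key]
    if model.output_units == "mg_n_m2_d":
        return {
            "flux_umol_m2_d": mg_n_m2_d_to_umol_m2_d(pred),
            "flux_mg_n_m2_d": pred,
        }
    if model.output_units == "umol_m2_d":
        return {
            "flux_umol_m2_d": pred,
            "flux_mg_n_m2_d": umol_m2_d_to_mg_n_m2_d(pred),
        }
    raise ValueError(f"unknown output units {model.output_units!r}")


@dataclass
class ModelComparison:
    """Per-site observed vs predicted fluxes for one model."""

    model: str
    table: pd.DataFrame  # site_id, observed, predicted, difference (umol m-2 d-1)
    fold_min: float
    fold_mean: float
    fold_max: float


def compare(
    observed: Sequence[FluxEstimate],
    predicted: Mapping[str, float],
    model_name: str = "",
) -> ModelComparison:
    """Align predicted fluxes with observations and summarize the mismatch.

    ``predicted`` maps site_id -> predicted flux (umol m-2 d-1).  Fold
    overestimates are |predicted|/|observed| per site, restricted to sites
    where both are nonzero, summarized by min/mean/max.
    """
    obs_ids = [e.site_id for e in observed]
    missing = [s for s in obs_ids if s not in predicted]
    if missing:
        raise ValueError(f"predictions missing for sites: {missing[:5]}")
    rows = []
    folds = []
    for e in observed:
        pred = float(predicted[e.site_id])
        rows.append(
            {
                "site_id": e.site_id,
                "observed_umol_m2_d": e.flux_umol_m2_d,
                "predicted_umol_m2_d": pred,
                "difference_umol_m2_d": pred - e.flux_umol_m2_d,
            }
        )
        if e.flux_umol_m2_d != 0 and pred != 0:
            folds.append(abs(pred) / abs(e.flux_umol_m2_d))
    if not folds:
        fold_min = fold_mean = fold_max = float("nan")
    else:
        fold_min, fold_mean, fold_max = (
            float(np.min(folds)),
            float(np.mean(folds)),
            float(np.max(folds)),
        )
    return ModelComparison(
        model=model_name,
        table=pd.DataFrame(rows),
        fold_min=fold_min,
        fold_mean=fold_mean,
        fold_max=fold_max,
    )


def co2_equivalent(flux_n2o_n_mass: float, gwp_n2o: float) -> float:
    """CO2-equivalent mass from an N2O-N mass flux.

    Converts N2O-N to N2O (x 44.0128/28.0134) then applies the configured
    global warming potential.  Any consistent mass/time units pass through.
    """
    if gwp_n2o <= 0:
        raise ValueError(f"GWP {gwp_n2o} must be > 0")
    return flux_n2o_n_mass * (N2O_G_PER_MOL / N_G_PER_MOL_N2O) * gwp_n2o
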