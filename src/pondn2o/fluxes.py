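"""Air-water N2O flux and sink/source classification.

Flux follows the bulk transfer relation f = k * (C_water - C_eq); with
C in nM (= umol m-3 * 1e-3... strictly nmol L-1 = umol m-3) and k in m d-1
the product is directly umol m-2 d-1.  Negative flux means the waterbody
takes up atmospheric N2O (a sink).

Classification uses the fleet-average analytical uncertainty sigma of the
headspace replicates as a closed band: sites within +/- sigma of their
equilibrium concentration cannot be distinguished from equilibrium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SaturationLabel",
    "FluxEstimate",
    "n2o_flux",
    "classify_site",
    "summarize_fleet",
    "write_flux_outputs",
]

#: Fleet-average replicate uncertainty (nM) used as default class band.
DEFAULT_SIGMA_NM = 1.25


class SaturationLabel(str, Enum):
    SINK = "sink"
    SOURCE = "source"
    EQUILIBRIUM = "equilibrium"


@dataclass(frozen=True)
class FluxEstimate:
    site_id: str
    flux_umol_m2_d: float
    c_water_nm: float
    c_eq_nm: float
    k_m_d: float
    label: SaturationLabel


def n2o_flux(c_water_nm: float, c_eq_nm: float, k_m_d: float) -> float:
    """Bulk flux k*(C_water - C_eq), umol m-2 d-1; negative = uptake."""
    if k_m_d < 0:
        raise ValueError(f"k {k_m_d} must be >= 0")
    return k_m_d * (c_water_nm - c_eq_nm)


def classify_site(
    c_water_nm: float, c_eq_nm: float, sigma_nm: float = DEFAULT_SIGMA_NM
) -> SaturationLabel:
    """Sink / source / equilibrium with a closed +/- sigma band.

    Boundary ties (departure exactly equal to sigma) classify as
    equilibrium: such sites cannot be considered distinct sinks or sources.
    """
    if sigma_nm < 0:
        raise ValueError(f"sigma {sigma_nm} must be >= 0")
    if c_water_nm < c_eq_nm - sigma_nm:
        return SaturationLabel.SINK
    if c_water_nm > c_eq_nm + sigma_nm:
        return SaturationLabel.SOURCE
    return SaturationLabel.EQUILIBRIUM


def estimate_site_flux(
    site_id: str,
    c_water_nm: float,
    c_eq_nm: float,
    k_m_d: float,
    sigma_nm: float = DEFAULT_SIGMA_NM,
) -> FluxEstimate:
    """Flux plus classification for one site."""
    return FluxEstimate(
        site_id=site_id,
        flux_umol_m2_d=n2o_flux(c_water_nm, c_eq_nm, k_m_d),
        c_water_nm=c_water_nm,
        c_eq_nm=c_eq_nm,
        k_m_d=k_m_d,
        label=classify_site(c_water_nm, c_eq_nm, sigma_nm),
    )


def summarize_fleet(estimates: Sequence[FluxEstimate]) -> dict:
    """Median flux, per-label counts/fractions and per-label flux ranges."""
    if not estimates:
        raise ValueError("summarize_fleet requires at least one estimate")
    fluxes = np.array([e.flux_umol_m2_d for e in estimates])
    summary: dict = {
        "n_sites": len(estimates),
        "median_flux_umol_m2_d": float(np.median(fluxes)),
        "labels": {},
    }
    for label in SaturationLabel:
        sel = [e.flux_umol_m2_d for e in estimates if e.label is label]
        entry = {
            "count": len(sel),
            "fraction": len(sel) / len(estimates),
        }
        if sel:
            entry["flux_min"] = float(min(sel))
            entry["flux_max"] = float(max(sel))
        summary["labels"][label.value] = entry
    return summary


def write_flux_outputs(estimates: Sequence[FluxEstimate], csv_path, json_path) -> None:
    """Per-site CSV plus a JSON fleet summary."""
    pd.DataFrame(
        {
            "site_id": [e.site_id for e in estimates],
            "c_water_nM": [e.c_water_nm for e in estimates],
            "c_eq_nM": [e.c_eq_nm for e in estimates],
            "k_m_d": [e.k_m_d for e in estimates],
            "flux_umol_m2_d": [e.flux_umol_m2_d for e in estimates],
            "label": [e.label.value for e in estimates],
        }
    ).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(summarize_fleet(estimates), fh, indent=2, sort_keys=True)
        fh.write("\n")
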