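"""End-to-end survey pipeline: CSVs in, per-stage artifacts and summary out.

Stage order follows the measurement chain: depth profiles -> stratification;
headspace bottles -> dissolved concentrations; chamber incubations ->
fleet gas transfer velocity; bulk flux + sink/source classification; the
Gamma GAM of environmental drivers; literature-model comparison.  Outputs
are plain CSV/JSON, written deterministically (a rerun on identical inputs
and configuration produces identical files).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chamber import analyze_incubation, estimates_to_frame, fleet_k, read_chamber_csv
from .fluxes import (
    FluxEstimate,
    estimate_site_flux,
    summarize_fleet,
    write_flux_outputs,
)
from .gam import (
    SiteRecord,
    fit_gam,
    n2o_gam_specification,
    screen_collinearity,
    transform_covariates,
)
from .gases import Gas, WaterState, equilibrium_concentration
from .headspace import back_calculate, fleet_uncertainty, read_headspace_csv
from .literature import (
    DEFAULT_IPCC_EF,
    EmissionModel,
    EmissionModelName,
    compare,
    predicted_flux,
)
from .stratification import buoyancy_frequency, read_profiles_csv
from .synthetic import N2O_AIR_PPM

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]

SURVEY_REQUIRED = (
    "site_id",
    "water_temp_c",
    "surf_do",
    "deep_do",
    "sed_cn",
    "chla",
    "surf_ph",
    "n_to_p",
    "din",
)

RANGE_CHECKS = {
    "surf_ph": (4.0, 11.0),
    "water_temp_c": (-2.0, 40.0),
    "chla": (0.0, np.inf),
    "din": (0.0, np.inf),
    "surf_do": (0.0, 400.0),
}


@dataclass
class RunConfig:
    """Paths and module options for one pipeline run."""

    survey_csv: str
    headspace_csv: str
    out_dir: str
    profiles_csv: str | None = None
    chamber_series_csv: str | None = None
    chamber_sidecar_csv: str | None = None
    sigma_nm: float | None = None  # None: fleet-average replicate sigma
    n2o_air_ppm: float = N2O_AIR_PPM
    qc_accuracy_fraction: float = 0.02
    qc_r2_min: float = 0.7
    qc_step_multiplier: float = 3.0
    schmidt_exponent: float = 0.67
    use_fleet_mean_k: bool = True
    fallback_k_m_d: float = 1.64  # used only when no chamber data supplied
    gam_basis_size: int = 9
    gam_tensor_margins: tuple[int, int] = (4, 4)
    gam_random_intercept: bool = True
    gam_double_penalty: bool = True
    collinearity_threshold: float = 0.8
    gwp_n2o: float = 273.0
    literature_models: list[dict] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "gam_tensor_margins" in known:
            known["gam_tensor_margins"] = tuple(known["gam_tensor_margins"])
        return cls(**known)

    def digest(self) -> str:
        # identifies the analysis (inputs + options); output location excluded
        payload = {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
            if k != "out_dir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> dict:
    """Per-file column checks plus row-level range warnings.

    Missing files or missing required columns are hard errors (listed by
    name); out-of-range rows produce warnings referencing the site.
    """
    errors: list[str] = []
    warnings: list[str] = []
    survey_path = Path(config.survey_csv)
    if not survey_path.exists():
        errors.append(f"survey file not found: {survey_path}")
    else:
        survey = pd.read_csv(survey_path)
        if survey.empty:
            errors.append(f"survey file is empty: {survey_path}")
        missing = [c for c in SURVEY_REQUIRED if c not in survey.columns]
        if missing:
            errors.append(f"survey missing required columns: {missing}")
        else:
            for col, (lo, hi) in RANGE_CHECKS.items():
                if col not in survey.columns:
                    continue
                bad = survey[(survey[col] < lo) | (survey[col] > hi)]
                for _, row in bad.iterrows():
                    warnings.append(
                        f"site {row['site_id']}: {col}={row[col]} outside [{lo}, {hi}]"
                    )
    for name, path in (
        ("headspace", config.headspace_csv),
        ("profiles", config.profiles_csv),
        ("chamber series", config.chamber_series_csv),
        ("chamber sidecar", config.chamber_sidecar_csv),
    ):
        if path is not None and not Path(path).exists():
            errors.append(f"{name} file not found: {path}")
    return {"errors": errors, "warnings": warnings}


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary report (also written to disk)."""
    report_validation = validate_inputs(config)
    if report_validation["errors"]:
        raise ValueError(
            "input validation failed: " + "; ".join(report_validation["errors"])
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey = pd.read_csv(config.survey_csv).set_index("site_id", drop=False)

    # -- stratification ----------------------------------------------------
    if config.profiles_csv is not None:
        profiles = read_profiles_csv(config.profiles_csv)
        bf_rows = []
        for prof in profiles:
            stab = buoyancy_frequency(prof)
            bf_rows.append(
                {
                    "site_id": prof.site_id,
                    "bf_max_s2": stab.max_buoyancy_frequency_s2,
                    "surface_do": prof.surface_do,
                    "bottom_do": prof.bottom_do,
                }
            )
        bf = pd.DataFrame(bf_rows).set_index("site_id")
        bf.to_csv(out / "stratification.csv")
        survey = survey.join(bf[["bf_max_s2"]], how="left")
        survey["bf_max"] = survey.get("bf_max", pd.Series(dtype=float)).combine_first(
            survey["bf_max_s2"]
        )
    if "bf_max" not in survey.columns:
        raise ValueError("no buoyancy frequency: provide profiles_csv or a bf_max column")

    # -- dissolved concentrations -----------------------------------------
    samples = read_headspace_csv(config.headspace_csv)
    conc = {s.site_id: back_calculate(s) for s in samples if s.gas is Gas.N2O}
    sigma = (
        config.sigma_nm
        if config.sigma_nm is not None
        else fleet_uncertainty(conc.values())
    )
    conc_df = pd.DataFrame(
        {
            "site_id": list(conc),
            "c_water_nM": [r.concentration_nm for r in conc.values()],
            "sigma_nM": [r.uncertainty_nm for r in conc.values()],
            "c_eq_nM": [r.equilibrium_nm for r in conc.values()],
            "quality": [r.quality for r in conc.values()],
        }
    )
    conc_df.to_csv(out / "concentrations.csv", index=False)

    # -- gas transfer velocity --------------------------------------------
    if config.chamber_series_csv is not None:
        incubations = read_chamber_csv(
            config.chamber_series_csv, config.chamber_sidecar_csv
        )
        estimates = [
            analyze_incubation(
                inc,
                accuracy_fraction=config.qc_accuracy_fraction,
                r2_min=config.qc_r2_min,
                step_multiplier=config.qc_step_multiplier,
                schmidt_exponent=config.schmidt_exponent,
            )
            for inc in incubations
        ]
        estimates_to_frame(estimates).to_csv(out / "k_estimates.csv", index=False)
        k_mean, k_sd, k_n = fleet_k(estimates)
    else:
        estimates = []
        k_mean, k_sd, k_n = config.fallback_k_m_d, float("nan"), 0

    # -- flux and classification ------------------------------------------
    flux_estimates: list[FluxEstimate] = []
    for site_id, res in conc.items():
        if site_id not in survey.index:
            continue
        row = survey.loc[site_id]
        state = WaterState(temperature=float(row["water_temp_c"]))
        c_eq = equilibrium_concentration(Gas.N2O, state, config.n2o_air_ppm)
        flux_estimates.append(
            estimate_site_flux(
                site_id=site_id,
                c_water_nm=res.concentration_nm,
                c_eq_nm=c_eq,
                k_m_d=k_mean,
                sigma_nm=sigma,
            )
        )
    write_flux_outputs(flux_estimates, out / "fluxes.csv", out / "flux_summary.json")
    flux_summary = summarize_fleet(flux_estimates)

    # -- driver GAM --------------------------------------------------------
    gam_table = survey.loc[[e.site_id for e in flux_estimates]].copy()
    gam_table["n2o_nm"] = [conc[e.site_id].concentration_nm for e in flux_estimates]
    records = [
        SiteRecord(
            site_id=str(r["site_id"]),
            n2o_nm=float(r["n2o_nm"]),
            surf_do=float(r["surf_do"]),
            deep_do=float(r["deep_do"]),
            sed_cn=float(r["sed_cn"]),
            chla=float(r["chla"]),
            surf_ph=float(r["surf_ph"]),
            n_to_p=float(r["n_to_p"]),
            bf_max=float(r["bf_max"]),
            din=float(r["din"]),
        )
        for _, r in gam_table.iterrows()
    ]
    table = transform_covariates(records)
    _, collinearity_report = screen_collinearity(
        table, threshold=config.collinearity_threshold
    )
    collinearity_report.to_csv(out / "collinearity.csv", index=False)
    # a reservoir random intercept is unidentifiable when every reservoir
    # contributes a single row (it trades off freely against the Gamma
    # scale and absorbs all residual deviance); drop it in that case
    use_ri = config.gam_random_intercept and table["site_id"].duplicated().any()
    spec = n2o_gam_specification(
        basis_size=config.gam_basis_size,
        tensor_margins=config.gam_tensor_margins,
        random_intercept=use_ri,
        double_penalty=config.gam_double_penalty,
    )
    fit = fit_gam(table, spec)
    gam_summary = fit.summary()
    _write_json(out / "gam_summary.json", gam_summary)
    for term in fit.design.terms:
        if term.kind == "random_intercept":
            continue
        pe = fit.partial_effect(term.name, grid=40)
        pd.DataFrame(
            {
                **{c: pe.grid[c] for c in term.covariates},
                "effect": pe.effect,
                "se": pe.se,
            }
        ).to_csv(out / f"partial_{term.name.replace('(', '_').replace(')', '').replace(',', '_')}.csv", index=False)

    # -- literature comparison --------------------------------------------
    comparisons = {}
    models = [
        EmissionModel(EmissionModelName.IPCC_EF, {"emission_factor": DEFAULT_IPCC_EF})
    ]
    for raw in config.literature_models:
        models.append(
            EmissionModel(
                name=EmissionModelName(raw["name"]),
                coefficients=raw.get("coefficients", {}),
                reference=raw.get("reference", ""),
                output_units=raw.get("output_units", "mg_n_m2_d"),
            )
        )
    by_site = {e.site_id: e for e in flux_estimates}
    for model in models:
        preds = {}
        skipped = False
        for e in flux_estimates:
            row = survey.loc[e.site_id]
            covs = {
                k: float(row[k])
                for k in ("nox", "chla", "area_m2", "din")
                if k in row.index and pd.notna(row[k])
            }
            if model.name is EmissionModelName.IPCC_EF and "nox" not in covs:
                covs["nox"] = float(row["din"])  # NOx unreported: DIN upper bound
            try:
                preds[e.site_id] = predicted_flux(
                    model, covs, k_m_d=e.k_m_d, c_eq_nm=e.c_eq_nm
                )["flux_umol_m2_d"]
            except ValueError:
                skipped = True
                break
        if skipped or not preds:
            continue
        cmp_result = compare(flux_estimates, preds, model_name=model.name.value)
        cmp_result.table.to_csv(out / f"comparison_{model.name.value}.csv", index=False)
        comparisons[model.name.value] = {
            "fold_min": cmp_result.fold_min,
            "fold_mean": cmp_result.fold_mean,
            "fold_max": cmp_result.fold_max,
        }

    summary = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "n_sites": flux_summary["n_sites"],
        "sigma_nm": sigma,
        "median_n2o_nm": float(conc_df["c_water_nM"].median()),
        "median_flux_umol_m2_d": flux_summary["median_flux_umol_m2_d"],
        "label_fractions": {
            k: v["fraction"] for k, v in flux_summary["labels"].items()
        },
        "label_counts": {k: v["count"] for k, v in flux_summary["labels"].items()},
        "k_n2o_mean_m_d": k_mean,
        "k_n2o_sd_m_d": k_sd,
        "k_incubations_used": k_n,
        "gam_deviance_explained": gam_summary["deviance_explained"],
        "gam_edf_by_term": gam_summary["edf_by_term"],
        "literature_fold_overestimate": comparisons,
        "validation_warnings": report_validation["warnings"],
    }
    _write_json(out / "summary.json", summary)
    return summary
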