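"""Synthetic survey generator with known ground truth.

Emulates the statistical structure of a late-summer spatial survey of
small agricultural reservoirs: ~101 sites whose nutrient and chlorophyll
covariates span two to three orders of magnitude (drawn log-uniformly over
the survey ranges), dissolved N2O generated from known smooth covariate
effects through a Gamma observation model, headspace bottles
forward-equilibrated from the true concentrations with GC noise, floating
chamber time series with planted quality-control violations, and
stratified/unstratified temperature profiles.

Ground truth (per-site linear predictor decomposition, true transfer
velocities, planted violations) is returned alongside the data and is
never consumed by the pipeline under test.

All randomness derives from a single integer seed fanned out to per-site
substreams (seed-sequence spawning keyed by site index), so enlarging the
fleet does not perturb existing sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .chamber import DEFAULT_TIMES_MIN, ChamberIncubation
from .gases import Gas, R_L_ATM, WaterState, solubility_coefficient
from .headspace import DissolvedGasSample, forward_equilibrate
from .gam.model import SiteRecord
from .stratification import DepthProfile, water_density, GRAVITY_M_S2

__all__ = [
    "SurveyGeneratorConfig",
    "GroundTruth",
    "generate_survey",
    "generate_headspace_samples",
    "generate_chamber_series",
    "generate_chamber_fleet",
    "generate_profile",
    "profile_for_bf_max",
    "N2O_AIR_PPM",
    "CH4_AIR_UATM",
]

#: Global-average dry mixing ratios for a mid-2017 sampling window.
N2O_AIR_PPM = 0.33
CH4_AIR_UATM = 1.85


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# --- true covariate effects on the log-concentration scale ----------------
# Shapes chosen to emulate the survey's findings: dissolved N2O declines as
# surface waters become O2-supersaturated and chlorophyll-rich, and high
# DIN raises N2O only in unstratified or weakly stratified columns.

def effect_surf_do(do_pct):
    return -0.6 * _sigmoid((np.asarray(do_pct, float) - 110.0) / 15.0)


def effect_log_chla(log_chla):
    return -0.5 * _sigmoid((np.asarray(log_chla, float) - math.log(60.0)) / 0.9)


def interaction_bf_din(sqrt_bf, log_din):
    """Saturating ramp in log DIN gated by a decaying function of sqrt(BF)."""
    ramp = _sigmoid((np.asarray(log_din, float) - math.log(2500.0)) / 0.55)
    gate = np.exp(-((np.asarray(sqrt_bf, float) / 0.075) ** 2))
    return 2.65 * ramp * gate


def _zero_effect(x):
    return np.zeros_like(np.asarray(x, float))


@dataclass(frozen=True)
class SurveyGeneratorConfig:
    """Study conditions for the synthetic fleet.

    Covariate ranges default to the survey's printed ranges; the response
    model is mu = exp(alpha + effects + interaction + reservoir intercept)
    with Gamma noise of the configured shape, clipped to the survey
    concentration range.
    """

    n_sites: int = 101
    seed: int = 0
    tdn_range: tuple[float, float] = (417.0, 14280.0)
    din_range: tuple[float, float] = (32.0, 7688.0)
    chla_range: tuple[float, float] = (2.2, 2484.0)
    n2o_clip_nm: tuple[float, float] = (1.14, 110.0)
    alpha: float = math.log(9.8)
    gamma_shape: float = 14.0
    random_intercept_sd: float = 0.12
    replicates_per_site: int = 1
    water_temp_mean_c: float = 19.5
    water_temp_sd_c: float = 2.2
    surf_do_effect: Callable = effect_surf_do
    chla_effect: Callable = effect_log_chla
    bf_din_interaction: Callable = interaction_bf_din
    deep_do_effect: Callable = _zero_effect
    sed_cn_effect: Callable = _zero_effect
    ph_effect: Callable = _zero_effect
    np_effect: Callable = _zero_effect

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        for name in ("tdn_range", "din_range", "chla_range", "n2o_clip_nm"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be positive and increasing")


@dataclass
class GroundTruth:
    """Per-site generator internals; never read by the pipeline under test."""

    frame: pd.DataFrame
    config: SurveyGeneratorConfig


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def generate_survey(
    config: SurveyGeneratorConfig,
) -> tuple[list[SiteRecord], GroundTruth]:
    """Draw the synthetic fleet: covariates, true smooth effects, Gamma N2O."""
    cfg = config
    rows = []
    for i in range(cfg.n_sites):
        rng = np.random.default_rng([cfg.seed, i])
        din = _log_uniform(rng, *cfg.din_range)
        tdn = max(_log_uniform(rng, *cfg.tdn_range), din * 1.1)
        chla = _log_uniform(rng, *cfg.chla_range)
        n_to_p = _log_uniform(rng, 5.0, 300.0)
        surf_do = float(np.clip(rng.normal(105.0, 25.0), 40.0, 200.0))
        deep_do = float(np.clip(surf_do * rng.uniform(0.1, 0.9), 0.0, 160.0))
        sed_cn = float(np.clip(rng.normal(10.5, 2.0), 6.0, 18.0))
        surf_ph = float(np.clip(rng.normal(8.5, 0.5), 7.0, 10.0))
        if rng.uniform() < 0.28:
            bf_max = 0.0
        else:
            bf_max = float(_log_uniform(rng, 1e-3, 0.04))
        temp = float(np.clip(rng.normal(cfg.water_temp_mean_c, cfg.water_temp_sd_c), 14.0, 26.0))
        gamma_i = float(rng.normal(0.0, cfg.random_intercept_sd))

        log_chla = math.log(chla)
        log_din = math.log(din)
        sqrt_bf = math.sqrt(bf_max)
        parts = {
            "f_surf_do": float(cfg.surf_do_effect(surf_do)),
            "f_deep_do": float(cfg.deep_do_effect(deep_do)),
            "f_sed_cn": float(cfg.sed_cn_effect(sed_cn)),
            "f_log_chla": float(cfg.chla_effect(log_chla)),
            "f_surf_ph": float(cfg.ph_effect(surf_ph)),
            "f_log_np": float(cfg.np_effect(math.log(n_to_p))),
            "f_bf_din": float(cfg.bf_din_interaction(sqrt_bf, log_din)),
        }
        eta = cfg.alpha + sum(parts.values()) + gamma_i
        mu = math.exp(eta)
        n2o = float(
            np.clip(
                rng.gamma(cfg.gamma_shape, mu / cfg.gamma_shape), *cfg.n2o_clip_nm
            )
        )
        rows.append(
            {
                "site_id": f"S{i:03d}",
                "n2o_nm": n2o,
                "mu_nm": mu,
                "eta": eta,
                "alpha": cfg.alpha,
                "gamma_site": gamma_i,
                **parts,
                "surf_do": surf_do,
                "deep_do": deep_do,
                "sed_cn": sed_cn,
                "chla": chla,
                "surf_ph": surf_ph,
                "n_to_p": n_to_p,
                "bf_max": bf_max,
                "din": din,
                "tdn": tdn,
                "nox": din * float(np.random.default_rng([cfg.seed, i, 7]).uniform(0.3, 0.9)),
                "water_temp_c": temp,
            }
        )
    truth = pd.DataFrame(rows)
    records = [
        SiteRecord(
            site_id=r["site_id"],
            n2o_nm=r["n2o_nm"],
            surf_do=r["surf_do"],
            deep_do=r["deep_do"],
            sed_cn=r["sed_cn"],
            chla=r["chla"],
            surf_ph=r["surf_ph"],
            n_to_p=r["n_to_p"],
            bf_max=r["bf_max"],
            din=r["din"],
        )
        for r in rows
    ]
    return records, GroundTruth(frame=truth, config=cfg)


def generate_headspace_samples(
    truth: GroundTruth,
    replicates: int = 2,
    gc_noise_rel: float = 0.15,
) -> list[DissolvedGasSample]:
    """Forward-equilibrate each site's true N2O into headspace bottles.

    Each replicate perturbs the equilibrated headspace reading with
    multiplicative GC noise; the default noise level makes the fleet-mean
    replicate standard deviation land near the survey's analytical
    uncertainty (~1.25 nM).
    """
    samples = []
    cfg = truth.config
    for i, row in truth.frame.iterrows():
        rng = np.random.default_rng([cfg.seed, int(i), 11])
        state = WaterState(temperature=float(row["water_temp_c"]))
        template = DissolvedGasSample(
            site_id=row["site_id"],
            gas=Gas.N2O,
            headspace_ppm_replicates=(0.0,),
            air_ppm=N2O_AIR_PPM,
            equilibration_state=state,
        )
        x_hs = forward_equilibrate(float(row["n2o_nm"]), template)
        reps = tuple(
            max(float(x_hs * (1.0 + rng.normal(0.0, gc_noise_rel))), 0.0)
            for _ in range(replicates)
        )
        samples.append(
            DissolvedGasSample(
                site_id=row["site_id"],
                gas=Gas.N2O,
                headspace_ppm_replicates=reps,
                air_ppm=N2O_AIR_PPM,
                equilibration_state=state,
            )
        )
    return samples


# --- chamber series -------------------------------------------------------

PlantKind = Literal["flat", "low_r2", "ebullition"]


def generate_chamber_series(
    k_true_m_d: float,
    state: WaterState,
    water_puatm: float = 500.0,
    noise_frac: float = 0.01,
    plant: PlantKind | None = None,
    seed: int = 0,
    site_id: str = "C000",
    gas: Gas = Gas.CH4,
    ambient_uatm: float = CH4_AIR_UATM,
) -> tuple[ChamberIncubation, dict]:
    """One floating-chamber series from the two-film accumulation model.

    The chamber partial pressure relaxes exponentially toward the water
    value with rate (A/V) * k * K0 * RT; over a 10-min deployment this is
    essentially the linear early-time regime.  ``noise_frac`` scales
    additive Gaussian noise by the total accumulation signal.  ``plant``
    optionally injects a QC violation: a zero-gradient (flat) series, a
    scrambled non-linear series, or an ebullition step jump.

    Returns the incubation plus a truth dict (k_true, planted violation).
    """
    if k_true_m_d < 0:
        raise ValueError("k_true must be >= 0")
    rng = np.random.default_rng([seed, 13])
    times = np.array(DEFAULT_TIMES_MIN)
    area, volume = 0.23, 0.046
    k0 = solubility_coefficient(gas, state).value
    rt = R_L_ATM * state.kelvin
    # (A/V)[m-1] * k[m d-1] * K0*RT[-] -> relaxation rate, per day
    rate_per_min = (area / volume) * k_true_m_d * k0 * rt / 1440.0
    if plant == "flat":
        water_puatm = ambient_uatm
    series = water_puatm + (ambient_uatm - water_puatm) * np.exp(-rate_per_min * times)
    signal = abs(series[-1] - series[0])
    if plant == "flat":
        signal = max(signal, 1e-3 * ambient_uatm)
    series = series + rng.normal(0.0, noise_frac * signal, size=times.size)
    if plant == "low_r2":
        # large total change but visibly non-linear accumulation
        delta = max(signal, 0.2 * abs(water_puatm - ambient_uatm), 1.0)
        series = ambient_uatm + delta * np.array([0.0, 0.8, 0.2, 1.0, 0.4])
    elif plant == "ebullition":
        jump = max(10.0 * signal, 0.5 * abs(water_puatm - ambient_uatm), 5.0)
        series = series + np.where(times >= times[3], jump, 0.0)
    incubation = ChamberIncubation(
        site_id=site_id,
        gas=gas,
        times_min=tuple(times),
        concentrations_uatm=tuple(series),
        water_partial_pressure_uatm=water_puatm,
        ambient_uatm=ambient_uatm,
        state=state,
        chamber_area_m2=area,
        chamber_volume_m3=volume,
    )
    return incubation, {"k_true_m_d": k_true_m_d, "plant": plant}


def generate_chamber_fleet(
    seed: int,
    n_incubations: int = 30,
    n_flat: int = 2,
    n_low_r2: int = 2,
    n_ebullition: int = 3,
    k_mean_m_d: float = 1.64,
    k_sd_m_d: float = 1.24,
    noise_frac: float = 0.01,
) -> tuple[list[ChamberIncubation], list[dict]]:
    """A chamber campaign: clean incubations plus planted QC violations.

    True transfer velocities are lognormal with the configured fleet mean
    and SD; defaults plant 7 violations among 30 incubations.
    """
    n_bad = n_flat + n_low_r2 + n_ebullition
    if n_bad > n_incubations:
        raise ValueError("more planted violations than incubations")
    sigma2 = math.log(1.0 + (k_sd_m_d / k_mean_m_d) ** 2)
    mu_log = math.log(k_mean_m_d) - sigma2 / 2.0
    plants: list[PlantKind | None] = (
        ["flat"] * n_flat + ["low_r2"] * n_low_r2 + ["ebullition"] * n_ebullition
        + [None] * (n_incubations - n_bad)
    )
    incubations, truths = [], []
    for i, plant in enumerate(plants):
        rng = np.random.default_rng([seed, i, 17])
        k_true = float(np.exp(rng.normal(mu_log, math.sqrt(sigma2))))
        temp = float(np.clip(rng.normal(19.5, 2.0), 14.0, 26.0))
        water_p = float(_log_uniform(rng, 100.0, 3000.0))
        inc, truth = generate_chamber_series(
            k_true_m_d=k_true,
            state=WaterState(temperature=temp),
            water_puatm=water_p,
            noise_frac=noise_frac,
            plant=plant,
            seed=int(rng.integers(0, 2**31 - 1)),
            site_id=f"C{i:03d}",
        )
        incubations.append(inc)
        truths.append(truth)
    return incubations, truths


# --- depth profiles -------------------------------------------------------

ProfileKind = Literal["isothermal", "two_layer", "continuous_thermocline"]


def generate_profile(
    kind: ProfileKind,
    site_id: str = "P000",
    depth_m: float = 3.0,
    step_m: float = 0.5,
    t_top_c: float = 22.0,
    t_bottom_c: float = 14.0,
    interface_m: float = 1.5,
    thermocline_width_m: float = 0.6,
    noise_sd_c: float = 0.0,
    seed: int = 0,
) -> DepthProfile:
    """Temperature profile of a requested shape, sampled every ``step_m``."""
    if depth_m <= 0:
        raise ValueError("depth range must be > 0")
    rng = np.random.default_rng([seed, 19])
    z = np.arange(0.0, depth_m + step_m / 2, step_m)
    if kind == "isothermal":
        t = np.full_like(z, t_top_c)
    elif kind == "two_layer":
        t = np.where(z < interface_m, t_top_c, t_bottom_c)
    elif kind == "continuous_thermocline":
        t = t_bottom_c + (t_top_c - t_bottom_c) * _sigmoid(
            (interface_m - z) / thermocline_width_m
        )
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    if noise_sd_c > 0:
        t = t + rng.normal(0.0, noise_sd_c, size=z.size)
    return DepthProfile(
        site_id=site_id,
        depths_m=tuple(z),
        temperatures_c=tuple(t),
    )


def profile_for_bf_max(
    site_id: str,
    target_bf_s2: float,
    t_top_c: float = 24.0,
    depth_m: float = 3.0,
    step_m: float = 0.5,
) -> DepthProfile:
    """Two-layer profile whose midpoint-scheme BF max equals the target.

    Solves for the bottom temperature by bisection on the single-interface
    buoyancy frequency; a zero target yields an isothermal column.  Used to
    make end-to-end pipeline fixtures where the stratification stage must
    recover a known per-site BF.
    """
    if target_bf_s2 < 0:
        raise ValueError("target BF must be >= 0")
    if target_bf_s2 == 0:
        return generate_profile(
            "isothermal", site_id=site_id, depth_m=depth_m, step_m=step_m, t_top_c=t_top_c
        )

    rho_top = water_density(t_top_c)

    def n2_for(t_bot: float) -> float:
        rho_bot = water_density(t_bot)
        rho_bar = 0.5 * (rho_top + rho_bot)
        return GRAVITY_M_S2 / rho_bar * (rho_bot - rho_top) / step_m

    lo, hi = 4.0, t_top_c  # densest at ~4 C: n2_for(lo) is the max achievable
    if n2_for(lo) < target_bf_s2:
        raise ValueError(f"target BF {target_bf_s2} unreachable below {t_top_c} C surface")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if n2_for(mid) > target_bf_s2:
            lo = mid
        else:
            hi = mid
    t_bot = 0.5 * (lo + hi)
    interface = depth_m / 2.0
    return generate_profile(
        "two_layer",
        site_id=site_id,
        depth_m=depth_m,
        step_m=step_m,
        t_top_c=t_top_c,
        t_bottom_c=t_bot,
        interface_m=interface + step_m / 4.0,
    )
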