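"""Independent oracles for the test suite.

Everything here is coded separately from the package implementation:
published coefficient tables retyped from their sources, textbook formulas
written directly, and brute-force numerical inversions.  Tests compare
package output against these, never the other way round.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

# --- solubility: Weiss & Price (1980) N2O K0, mol/(L atm) -----------------
_WP80_N2O = (-62.7062, 97.3066, 24.1406, -0.058420, 0.033193, -0.0051313)
# --- Yamamoto et al. (1976) CH4 Bunsen coefficient ------------------------
_Y76_CH4 = (-67.1962, 99.1624, 27.9015, -0.072909, 0.041674, -0.0064603)


def k0_n2o(temp_c: float, sal: float = 0.0) -> float:
    a1, a2, a3, b1, b2, b3 = _WP80_N2O
    th = (temp_c + 273.15) / 100.0
    return math.exp(a1 + a2 / th + a3 * math.log(th) + sal * (b1 + b2 * th + b3 * th**2))


def k0_ch4(temp_c: float, sal: float = 0.0) -> float:
    a1, a2, a3, b1, b2, b3 = _Y76_CH4
    th = (temp_c + 273.15) / 100.0
    bunsen = math.exp(
        a1 + a2 / th + a3 * math.log(th) + sal * (b1 + b2 * th + b3 * th**2)
    )
    return bunsen / 22.414


def vapor_pressure_atm(temp_c: float, sal: float = 0.0) -> float:
    t = temp_c + 273.15
    return math.exp(
        24.4543 - 67.4509 * (100.0 / t) - 4.8489 * math.log(t / 100.0) - 0.000544 * sal
    )


# --- Schmidt numbers: Wanninkhof (1992) fresh water, 3rd order ------------
_SC_FRESH = {
    "N2O": (2055.6, -137.11, 4.3173, -0.054350),
    "CH4": (1897.8, -114.28, 3.2902, -0.039061),
}


def schmidt_fresh(gas: str, temp_c: float) -> float:
    a, b, c, d = _SC_FRESH[gas]
    return a + b * temp_c + c * temp_c**2 + d * temp_c**3


# --- freshwater density polynomial ----------------------------------------
def density_kg_m3(temp_c: float) -> float:
    t = temp_c
    return 1000.0 * (
        1.0 - (t + 288.9414) * (t - 3.9863) ** 2 / (508929.2 * (t + 68.12963))
    )


# --- headspace mole balance, inverted numerically -------------------------
def headspace_back_calc(
    x_hs_ppm: float,
    air_ppm: float,
    temp_c: float,
    bottle_l: float = 1.2,
    headspace_l: float = 0.060,
    pressure_atm: float = 1.0,
    sal: float = 0.0,
) -> float:
    """Brute-force inversion: find C0 (nM) whose forward equilibration
    reproduces the observed headspace ppm.  Forward model written from the
    two-compartment balance directly."""

    vw = bottle_l - headspace_l
    t_k = temp_c + 273.15
    p_dry = pressure_atm - vapor_pressure_atm(temp_c, sal)
    k0 = k0_n2o(temp_c, sal)
    r = 0.0820573

    def forward(c0_nm: float) -> float:
        total_mol = c0_nm * 1e-9 * vw + air_ppm * 1e-6 * p_dry * headspace_l / (r * t_k)
        # total = x*(1e-6*p_dry) * (k0*vw + headspace_l/(r*t_k))
        return total_mol / (1e-6 * p_dry * (k0 * vw + headspace_l / (r * t_k)))

    return brentq(lambda c: forward(c) - x_hs_ppm, -1e4, 1e7, xtol=1e-12)


# --- ordinary least squares via normal equations --------------------------
def ols_slope_r2(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, c, rcond=None)
    resid = c - A @ coef
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(coef[1]), r2


# --- Gamma deviance, written from the formula -----------------------------
def gamma_deviance_direct(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


# --- Pearson r via covariance definition ----------------------------------
def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac @ bc) / math.sqrt((ac @ ac) * (bc @ bc)))


# --- two-pass mean/standard deviation -------------------------------------
def mean_sd(values) -> tuple[float, float]:
    v = np.asarray(list(values), float)
    m = float(v.mean())
    if v.size < 2:
        return m, 0.0
    return m, float(math.sqrt(np.sum((v - m) ** 2) / (v.size - 1)))
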