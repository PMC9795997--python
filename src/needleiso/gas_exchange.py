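"""Half-hourly shoot gas exchange for Scots pine needles.

A Farquhar-von Caemmerer-Berry two-limitation photosynthesis core with
Bernacchi temperature responses, a Medlyn-form stomatal model, a fixed
boundary-layer conductance (needles are well coupled to the atmosphere), a
mesophyll conductance that co-varies with assimilation so that the
chloroplast CO2 draw-down is a fixed fraction of C_i (C_c = 0.8 C_i), and a
linear soil-moisture limitation ramp applied to photosynthetic capacity and
stomatal slope.  The leaf is assumed to be at air temperature; ternary
corrections are ignored.  All rates are per all-sided needle area.

Each half-hourly step is closed by bracketed root iteration on C_i so that
the diffusive supply A_n = g_t (C_a - C_i) matches the biochemical demand to
within 1e-6 umol mol-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure (kPa) over water, Magnus form.

    Valid for leaf-relevant temperatures; raises for inputs outside
    [-40, 50] degC.
    """
    t = np.asarray(t_air, dtype=float)
    if np.any(t < -40.0) or np.any(t > 50.0):
        raise ValueError("T_air outside [-40, 50] degC")
    return 0.6112 * np.exp(17.62 * t / (243.12 + t))


@dataclass(frozen=True)
class GasExchangeParams:
    """Parameters of the shoot gas-exchange model (all-sided needle area)."""

    vcmax25: float = 30.0          # umol m-2 s-1
    jmax25: float = 57.0           # umol m-2 s-1
    rd25: float = 0.8              # umol m-2 s-1
    quantum_yield: float = 0.15    # mol e- (mol photons)-1, incident, all-sided
    theta_j: float = 0.9           # curvature of the light response
    ha_vcmax: float = 65_330.0     # J mol-1 activation energies (Bernacchi)
    ha_jmax: float = 43_540.0
    ha_rd: float = 46_390.0
    g0: float = 0.01               # mol m-2 s-1 (CO2), residual conductance
    g1: float = 1.8                # kPa^0.5, Medlyn slope
    gb: float = 0.5                # mol m-2 s-1 (CO2), boundary layer
    cc_ci_ratio: float = 0.8       # mesophyll closure: g_m co-varies with
                                   # assimilation so that C_c = ratio * C_i,
                                   # the emergent relation the model family
                                   # is built around; calibrated once, frozen
    o2: float = 210.0              # mmol mol-1
    theta_fc: float = 0.20         # m3 m-3, no limitation at/above
    theta_wilt: float = 0.06       # m3 m-3, full limitation at/below
    d_min: float = 0.05            # kPa floor for VPD in the stomatal model

    def __post_init__(self):
        if self.gb <= 0 or self.g0 < 0:
            raise ValueError("conductances must be positive")
        if self.vcmax25 < 0 or self.jmax25 < 0:
            raise ValueError("capacities must be non-negative")


@dataclass
class GasExchangeState:
    """Converged per-step state (umol, mol, kPa units as in the fields)."""

    A_n: float          # net CO2 exchange, umol m-2 s-1
    r_d: float          # mitochondrial respiration, umol m-2 s-1
    E: float            # transpiration, mol m-2 s-1
    g_s: float          # stomatal conductance (CO2), mol m-2 s-1
    g_b: float          # boundary-layer conductance (CO2), mol m-2 s-1
    g_m: float          # mesophyll conductance, mol m-2 s-1
    C_a: float
    C_s: float
    C_i: float
    C_c: float          # umol mol-1
    Gamma_star: float   # umol mol-1
    k: float            # carboxylation efficiency (A_n + r_d)/(C_c - Gamma*), mol m-2 s-1
    w_a: float          # mol mol-1
    w_i: float          # mol mol-1
    beta_soil: float
    converged: bool


def arrhenius(k25: float, ha: float, t_air: float) -> float:
    tk = t_air + 273.15
    return k25 * np.exp(ha * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def gamma_star(t_air):
    """CO2 compensation point without mitochondrial respiration (umol mol-1)."""
    tk = np.asarray(t_air, dtype=float) + 273.15
    return 42.75 * np.exp(37_830.0 * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def michaelis_menten_co2(t_air: float, o2: float = 210.0) -> float:
    """Effective Michaelis constant Kc(1 + O/Ko) in umol mol-1."""
    kc = arrhenius(404.9, 79_430.0, t_air)
    ko = arrhenius(278.4, 36_380.0, t_air)  # mmol mol-1
    return kc * (1.0 + o2 / ko)


def soil_moisture_limiter(theta, params: GasExchangeParams):
    """Unitless water-availability factor in [0, 1], linear ramp in theta."""
    th = np.asarray(theta, dtype=float)
    return np.clip(
        (th - params.theta_wilt) / (params.theta_fc - params.theta_wilt), 0.0, 1.0
    )


def mesophyll_conductance(a_n: float, c_i: float, g_m: float) -> tuple[float, float]:
    """Chloroplast CO2 after mesophyll draw-down: C_c = C_i - A_n/g_m."""
    if g_m <= 0:
        raise ValueError("g_m must be positive")
    return g_m, c_i - a_n / g_m


def electron_transport(par: float, jmax: float, params: GasExchangeParams) -> float:
    """Non-rectangular hyperbola light response of electron transport."""
    i2 = params.quantum_yield * par
    if jmax <= 0.0 or i2 <= 0.0:
        return 0.0
    th = params.theta_j
    s = i2 + jmax
    return (s - np.sqrt(s * s - 4.0 * th * i2 * jmax)) / (2.0 * th)


def _demand(c_i, vcmax, j, rd, cc_ratio, gs_t, km):
    """Net assimilation demanded at intercellular CO2 ``c_i``.

    The mesophyll closure C_c = cc_ratio * C_i makes the demand explicit:
    A = V (C_c - Gamma*)/(C_c + K) - rd for each limitation, minimum taken.
    """
    c_c = cc_ratio * c_i
    a_c = vcmax * (c_c - gs_t) / (c_c + km) - rd
    a_j = (j / 4.0) * (c_c - gs_t) / (c_c + 2.0 * gs_t) - rd
    return min(a_c, a_j)


def solve_step(
    t_air: float,
    par: float,
    e_a: float,
    c_a: float,
    theta: float,
    p_atm: float,
    params: GasExchangeParams,
    tol: float = 1e-6,
) -> GasExchangeState:
    """Solve one half-hourly step of shoot gas exchange."""
    beta = float(soil_moisture_limiter(theta, params))
    gs_t = float(gamma_star(t_air))
    km = michaelis_menten_co2(t_air, params.o2)
    rd = arrhenius(params.rd25, params.ha_rd, t_air)
    vcmax = beta * arrhenius(params.vcmax25, params.ha_vcmax, t_air)
    jmax = beta * arrhenius(params.jmax25, params.ha_jmax, t_air)
    j = electron_transport(par, jmax, params)

    e_sat = float(saturation_vapor_pressure(t_air))
    w_i = e_sat / p_atm
    w_a = e_a / p_atm
    vpd = max(e_sat - e_a, params.d_min)

    def stomatal(a_n):
        # the soil factor closes stomata (whole slope term), so drought
        # lowers g_s and C_i/C_a together, as observed in the field
        return params.g0 + beta * (1.0 + params.g1 / np.sqrt(vpd)) * max(a_n, 0.0) / c_a

    def transpiration(g_s):
        g_tw = 1.6 * g_s * params.gb / (g_s + params.gb)
        return max(g_tw * (w_i - w_a), 0.0)

    dark = par <= 0.0 or j <= 0.0 or vcmax <= 0.0
    if not dark:

        def residual(c_i):
            a_n = _demand(c_i, vcmax, j, rd, params.cc_ci_ratio, gs_t, km)
            g_s = stomatal(a_n)
            g_tc = g_s * params.gb / (g_s + params.gb)
            return c_a - a_n / g_tc - c_i

        lo, hi = gs_t + 1e-3, c_a
        converged = True
        if residual(hi) >= 0.0:
            # demand at C_i = C_a is non-positive: effectively dark
            dark = True
        else:
            c_i = brentq(residual, lo, hi, xtol=tol * 1e-2, rtol=8.9e-16)
            a_n = _demand(c_i, vcmax, j, rd, params.cc_ci_ratio, gs_t, km)
            g_s = stomatal(a_n)

    if dark:
        a_n = -rd
        g_s = params.g0
        g_tc = g_s * params.gb / (g_s + params.gb)
        c_i = c_a - a_n / g_tc
        converged = True

    if a_n > 0.0:
        c_c = params.cc_ci_ratio * c_i
        gm = a_n / (c_i - c_c)  # conductance implied by the mesophyll closure
    else:
        c_c, gm = c_i, np.nan   # no draw-down without net uptake
    c_s = c_a - a_n / params.gb
    k = (a_n + rd) / (c_c - gs_t) if abs(c_c - gs_t) > 1e-12 else 0.0
    if dark:
        k = 0.0
    return GasExchangeState(
        A_n=a_n, r_d=rd, E=transpiration(g_s), g_s=g_s, g_b=params.gb, g_m=gm,
        C_a=c_a, C_s=c_s, C_i=c_i, C_c=c_c, Gamma_star=gs_t, k=k,
        w_a=w_a, w_i=w_i, beta_soil=beta, converged=converged,
    )


def solve_series(meteo: pd.DataFrame, params: GasExchangeParams | None = None) -> pd.DataFrame:
    """Run :func:`solve_step` over a driver table; one row per step."""
    params = params or GasExchangeParams()
    rows = []
    for row in meteo.itertuples():
        st = solve_step(row.T_air, row.PAR, row.e_a, row.C_a, row.theta, row.P_atm, params)
        rows.append(
            (st.A_n, st.r_d, st.E, st.g_s, st.g_b, st.g_m, st.C_a, st.C_s,
             st.C_i, st.C_c, st.Gamma_star, st.k, st.w_a, st.w_i, st.beta_soil,
             st.converged)
        )
    cols = ["A_n", "r_d", "E", "g_s", "g_b", "g_m", "C_a", "C_s", "C_i", "C_c",
            "Gamma_star", "k", "w_a", "w_i", "beta_soil", "converged"]
    out = pd.DataFrame(rows, columns=cols, index=meteo.index)
    out.insert(0, "T_air", meteo["T_air"].to_numpy())
    out.insert(1, "PAR", meteo["PAR"].to_numpy())
    return out
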