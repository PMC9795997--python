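"""Season orchestrator: drivers -> gas exchange -> leaf water -> pools.

``run_season`` chains the modules at the native half-hourly step for one
variant configuration and returns a per-step table with gas exchange, leaf
water delta18O, 13C discrimination, and the sugar/WSC pool isotope signals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .carbon13 import C13Params, C13_VARIANTS
from .conversions import R_VPDB, R_VSMOW, delta_to_ratio, ratio_to_delta
from .gas_exchange import GasExchangeParams, solve_series
from .oxygen18 import (
    EPSILON_WC_MODES,
    LEAF_WATER_MODELS,
    O18Params,
    leaf_water_series,
)
from .sugar_pool import PoolParams, mix_wsc, update_pool_c13, update_pool_o18

DT = 1800.0  # s


@dataclass(frozen=True)
class VariantConfig:
    """Switches selecting one model variant.

    Mirrors the published variant grid: leaf-water model x steadiness x
    epsilon_wc mode x 13C formulation x mesophyll treatment x pool size.
    """

    leaf_water: str = "peclet"          # craig_gordon | two_pool | peclet
    nonsteady: bool = True
    epsilon_wc: str = "temperature"     # constant | temperature
    c13_variant: str = "full_mito"      # see carbon13.C13_VARIANTS
    mesophyll: bool = True
    pool_size: str = "observed"         # observed | negligible

    def __post_init__(self):
        if self.leaf_water not in LEAF_WATER_MODELS:
            raise ValueError(f"unknown leaf water model {self.leaf_water!r}")
        if self.epsilon_wc not in EPSILON_WC_MODES:
            raise ValueError(f"unknown epsilon_wc mode {self.epsilon_wc!r}")
        if self.c13_variant not in C13_VARIANTS:
            raise ValueError(f"unknown c13 variant {self.c13_variant!r}")
        if self.pool_size not in ("observed", "negligible"):
            raise ValueError(f"unknown pool size {self.pool_size!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "VariantConfig":
        """Build from flat config keys (``leafwater.model`` style accepted)."""
        key = {
            "leafwater.model": "leaf_water",
            "leafwater.steady": "nonsteady",
            "o18.epsilon_wc": "epsilon_wc",
            "c13.variant": "c13_variant",
            "c13.mesophyll": "mesophyll",
            "pool.size": "pool_size",
        }
        kwargs = {}
        for k, v in cfg.items():
            name = key.get(k, k)
            if name == "nonsteady" and isinstance(v, str):
                v = v == "nonsteady"
            if name == "mesophyll" and isinstance(v, str):
                v = v == "on"
            kwargs[name] = v
        return cls(**kwargs)


def _c13_params(variant: VariantConfig) -> C13Params:
    return C13Params.for_variant(variant.c13_variant, use_mesophyll=variant.mesophyll)


def run_season(
    meteo: pd.DataFrame,
    forcings: pd.DataFrame,
    variant: VariantConfig | None = None,
    gx_params: GasExchangeParams | None = None,
    o18_params: O18Params | None = None,
    c13_params: C13Params | None = None,
    pool_params: PoolParams | None = None,
    gas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full isotope model over one synthetic (or measured) season.

    ``gas`` may carry a precomputed gas-exchange table (for variant grids the
    physics is shared across variants).  Returns the gas-exchange columns
    plus leaf-water and pool isotope columns in delta space.
    """
    variant = variant or VariantConfig()
    o18 = replace(o18_params or O18Params(), epsilon_wc_mode=variant.epsilon_wc)
    c13 = c13_params or _c13_params(variant)
    pool = (pool_params or PoolParams()).with_size(variant.pool_size)

    if gas is None:
        gas = solve_series(meteo, gx_params or GasExchangeParams())
    lw = leaf_water_series(
        gas, forcings, o18, model=variant.leaf_water, nonsteady=variant.nonsteady, dt=DT
    )

    n = len(gas)
    a_n = gas["A_n"].to_numpy()
    r_d = gas["r_d"].to_numpy()
    r_lw = delta_to_ratio(lw["delta18O_lw"].to_numpy(), R_VSMOW)
    alpha_wc = 1.0 + lw["epsilon_wc"].to_numpy() / 1000.0
    r_assim_o = alpha_wc * r_lw
    r_atm = delta_to_ratio(forcings["delta13C_atm"].to_numpy(), R_VPDB)

    r_pin_o = delta_to_ratio(pool.delta18o_pin, R_VSMOW)
    r_pin_c = delta_to_ratio(pool.delta13c_pin, R_VPDB)

    from .carbon13 import discrimination

    # spin-up initial conditions: first-day mean assimilate signal
    day0 = slice(0, min(48, n))
    day_mask = a_n[day0] + r_d[day0] > 0
    r_sug_o = (
        r_assim_o[day0][day_mask].mean() if day_mask.any() else r_assim_o[0]
    )
    r_sug_c = r_atm[0] / 1.020  # provisional ~20 permil discrimination

    rows_o = np.empty(n)
    rows_c = np.empty(n)
    delta13 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    gas_rows = list(gas.itertuples())
    for i in range(n):
        st = gas_rows[i]
        res = discrimination(st, r_atm[i], r_sug_c, c13)
        delta13[i] = res.Delta13
        valid[i] = res.valid
        q = a_n[i]
        r_sug_o = update_pool_o18(r_sug_o, r_assim_o[i], a_n[i], r_d[i], q, pool.s_sug, DT)
        if res.valid:
            r_sug_c = update_pool_c13(r_sug_c, r_atm[i], res.Delta13, a_n[i], q, pool.s_sug, DT)
        rows_o[i] = r_sug_o
        rows_c[i] = r_sug_c

    out = gas.copy()
    out["RH"] = np.clip(gas["w_a"] / gas["w_i"], 0.0, 1.0) * 100.0
    out["CiCa"] = gas["C_i"] / gas["C_a"]
    for col in lw.columns:
        out[col] = lw[col].to_numpy()
    out["delta18O_assim"] = ratio_to_delta(r_assim_o, R_VSMOW)
    out["Delta13_permil"] = delta13 * 1000.0
    out["delta13C_assim"] = ratio_to_delta(
        r_atm / (1.0 + delta13), R_VPDB
    )
    out["valid_mask"] = valid
    out["delta18O_sug"] = ratio_to_delta(rows_o, R_VSMOW)
    out["delta13C_sug"] = ratio_to_delta(rows_c, R_VPDB)
    out["delta18O_wsc"] = ratio_to_delta(
        mix_wsc(rows_o, r_pin_o, pool.s_sug, pool.s_pin), R_VSMOW
    )
    out["delta13C_wsc"] = ratio_to_delta(
        mix_wsc(rows_c, r_pin_c, pool.s_sug, pool.s_pin), R_VPDB
    )
    return out
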