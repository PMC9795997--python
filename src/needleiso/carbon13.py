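"""13C discrimination of net CO2 exchange.

The discrimination of the net flux follows the Wingate-type modification of
the classical Farquhar model, in which the substrate of mitochondrial
respiration is the needle sugar pool rather than current assimilates, so the
expression stays valid at night (k = 0), where it reduces to the
discrimination of dark respiration:

    13Delta = kCa/(kCa - rd) * [ ab (Ca-Cs)/Ca + as (Cs-Ci)/Ca
                                 + am (Ci-Cc)/Ca + b Cc/Ca - f Gamma*/Ca ]
              - rd/(kCa - rd) * [ (Ra/Rsug)(1 + e) - 1 ]

with k = (A_n + r_d)/(C_c - Gamma*).  Fractionation factors are stored as
dimensionless fractions internally (29 permil -> 0.029).  Steps where
k*Ca - rd approaches zero (day/night transitions) are numerically noisy and
are masked rather than propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

C13_VARIANTS = ("simple_b27", "diffusion_carbox", "plus_photoresp", "full_mito")


@dataclass(frozen=True)
class C13Params:
    """Fractionation factors (permil) and structural switches."""

    a_b: float = 2.9       # diffusion through the boundary layer
    a_s: float = 4.4       # diffusion through stomata
    a_m: float = 1.8       # transfer through mesophyll
    b: float = 29.0        # carboxylation
    f: float = 8.0         # photorespiration
    e: float = -6.0        # mitochondrial respiration
    use_mesophyll: bool = True    # C_c distinct from C_i
    use_photoresp: bool = True
    use_mito_resp: bool = True
    mask_tol: float = 0.15  # umol m-2 s-1 on |k Ca - rd|; masks the noisy
                            # day/night transitions (<2% of a season) while
                            # keeping cold nights (|k Ca - rd| = rd) valid

    @classmethod
    def for_variant(cls, variant: str, use_mesophyll: bool = True) -> "C13Params":
        """Preset parameter sets for the published model variants."""
        if variant == "simple_b27":
            # lower b implicitly absorbs mesophyll and respiratory effects
            return cls(b=27.0, f=0.0, use_photoresp=False, use_mito_resp=False,
                       use_mesophyll=False)
        if variant == "diffusion_carbox":
            return cls(f=0.0, use_photoresp=False, use_mito_resp=False,
                       use_mesophyll=use_mesophyll)
        if variant == "plus_photoresp":
            return cls(use_mito_resp=False, use_mesophyll=use_mesophyll)
        if variant == "full_mito":
            return cls(use_mesophyll=use_mesophyll)
        raise ValueError(f"unknown c13 variant {variant!r}")

    def without_respiration(self) -> "C13Params":
        return replace(self, use_mito_resp=False)


@dataclass
class DiscriminationResult:
    Delta13: float      # dimensionless discrimination (0.020 = 20 permil)
    R_assim: float      # isotope ratio of net CO2 exchange, R_a/(1 + Delta)
    valid: bool


def photosynthetic_term(c_a, c_s, c_i, c_c, gamma_star, params: C13Params) -> float:
    """Diffusion + carboxylation (+ photorespiration) part of the
    discrimination, per unit C_a, as a dimensionless fraction."""
    p = params
    a_b, a_s, a_m, b = (x / 1000.0 for x in (p.a_b, p.a_s, p.a_m, p.b))
    f = p.f / 1000.0 if p.use_photoresp else 0.0
    return (
        a_b * (c_a - c_s) / c_a
        + a_s * (c_s - c_i) / c_a
        + a_m * (c_i - c_c) / c_a
        + b * c_c / c_a
        - f * gamma_star / c_a
    )


def discrimination(state, r_a: float, r_sug: float, params: C13Params) -> DiscriminationResult:
    """13C discrimination of net CO2 exchange for one gas-exchange state.

    ``state`` provides A_n, r_d, C_a, C_s, C_i, C_c, Gamma_star (attribute or
    mapping access).  ``r_sug`` is the sugar-pool ratio at the previous step
    (the respiratory substrate).  Returns a masked result when
    |k Ca - rd| is below the noise tolerance.
    """
    get = state.__getattribute__ if hasattr(state, "A_n") else state.__getitem__
    a_n, r_d = get("A_n"), get("r_d")
    c_a, c_s, c_i, c_c, g_star = (
        get("C_a"), get("C_s"), get("C_i"), get("C_c"), get("Gamma_star")
    )
    if not params.use_mesophyll:
        c_c = c_i
    rd_eff = r_d if params.use_mito_resp else 0.0
    k = (a_n + r_d) / (c_c - g_star) if abs(c_c - g_star) > 1e-12 else 0.0

    denom = k * c_a - rd_eff
    if abs(denom) < params.mask_tol:
        return DiscriminationResult(np.nan, np.nan, False)

    e = params.e / 1000.0
    phot = photosynthetic_term(c_a, c_s, c_i, c_c, g_star, params)
    delta = (k * c_a * phot - rd_eff * (r_a / r_sug * (1.0 + e) - 1.0)) / denom
    if 1.0 + delta == 0.0:
        return DiscriminationResult(np.nan, np.nan, False)
    return DiscriminationResult(delta, r_a / (1.0 + delta), True)


def assimilate_ratio(r_a: float, delta13: float) -> float:
    """Isotope ratio of net CO2 exchange, R_a/(1 + 13Delta)."""
    if np.isnan(delta13):
        return np.nan
    return r_a / (1.0 + delta13)
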