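"""Leaf-water 18O: fractionation factors, steady/non-steady models, epsilon_wc."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from needleiso.conversions import R_VSMOW, delta_to_ratio, ratio_to_delta
from needleiso.oxygen18 import (
    C_MOLAR,
    D_H218O,
    O18Params,
    bulk_leaf_water_ss,
    epsilon_wc,
    equilibrium_fractionation,
    evaporative_site_ratio,
    kinetic_fractionation,
    leaf_water_nonsteady_step,
    leaf_water_series,
    nonsteady_rate,
    peclet_f1,
)

PAR = O18Params()


# --- fractionation factors -----------------------------------------------------

def test_majoube_equilibrium_oracle():
    """Direct evaluation of the Majoube (1971) expression at 25 degC."""
    tk = 298.15
    expected = np.exp(1137.0 / tk**2 - 0.4156 / tk - 2.0667e-3)
    assert equilibrium_fractionation(25.0) == pytest.approx(expected, rel=1e-12)
    assert (expected - 1.0) * 1000 == pytest.approx(9.3, abs=0.15)
    t = np.linspace(-10, 45, 100)
    a = equilibrium_fractionation(t)
    assert (np.diff(a) < 0).all() and (a > 1).all()
    with pytest.raises(ValueError):
        equilibrium_fractionation(50.0)


@pytest.mark.parametrize(
    "g_s, g_b, expected",
    [(1e-12, 0.5, 1.028), (1e6, 0.5, 1.019), (0.2, 0.2, 1.0235)],
)
def test_kinetic_fractionation_limits(g_s, g_b, expected):
    assert kinetic_fractionation(g_s, g_b, PAR) == pytest.approx(expected, abs=1e-6)


def test_kinetic_fractionation_rejects_zero_conductance():
    with pytest.raises(ValueError):
        kinetic_fractionation(0.0, 0.0, PAR)


# --- evaporative sites and bulk leaf water -------------------------------------

def test_evaporative_site_limits():
    a_plus, a_k = 1.0095, 1.025
    r_s, r_v = delta_to_ratio(-12.0, R_VSMOW), delta_to_ratio(-20.0, R_VSMOW)
    # saturated air: gradient term vanishes
    assert evaporative_site_ratio(r_s, r_v, 0.02, 0.02, a_plus, a_k) == pytest.approx(
        a_plus * r_v, rel=1e-14
    )
    # dry air limit
    assert evaporative_site_ratio(r_s, r_v, 0.0, 0.02, a_plus, a_k) == pytest.approx(
        a_plus * a_k * r_s, rel=1e-14
    )
    with pytest.raises(ValueError):
        evaporative_site_ratio(r_s, r_v, 0.01, 0.0, a_plus, a_k)


def test_evaporative_site_hand_oracle():
    """delta_s=-12, delta_v=-20, RH=60%, T=20 degC, g_s=g_b=0.2."""
    t = 20.0
    a_plus = float(equilibrium_fractionation(t))
    a_k = float(kinetic_fractionation(0.2, 0.2, PAR))
    w_i = 0.6112 * np.exp(17.62 * t / (243.12 + t)) / 101.3
    w_a = 0.6 * w_i
    r_s = R_VSMOW * (1 - 12e-3)
    r_v = R_VSMOW * (1 - 20e-3)
    expected = a_plus * (a_k * 0.4 * r_s + 0.6 * r_v)  # hand evaluation
    got = evaporative_site_ratio(r_s, r_v, w_a, w_i, a_plus, a_k)
    assert got == pytest.approx(expected, rel=1e-14)
    # sanity anchor: ~14 permil enrichment over source under these conditions
    assert 5.0 < ratio_to_delta(got, R_VSMOW) - (-12.0) < 25.0


def test_peclet_factor():
    assert peclet_f1(0.0, PAR) == 1.0
    # Peclet number of exactly 1
    e_unit = C_MOLAR * D_H218O / PAR.L
    assert peclet_f1(e_unit, PAR) == pytest.approx(1 - np.exp(-1), rel=1e-12)
    # direct arithmetic: E = 1e-3 mol m-2 s-1, L = 0.03 m
    pe = 1e-3 * 0.03 / (C_MOLAR * D_H218O)
    assert pe == pytest.approx(0.203, abs=0.001)
    assert peclet_f1(1e-3, PAR) == pytest.approx(0.905, abs=0.001)
    with pytest.raises(ValueError):
        peclet_f1(-1e-3, PAR)


def test_two_pool_delta_arithmetic():
    r_e = delta_to_ratio(15.0, R_VSMOW)
    r_s = delta_to_ratio(-12.0, R_VSMOW)
    assert ratio_to_delta(bulk_leaf_water_ss(r_e, r_s, 0.93), R_VSMOW) == pytest.approx(
        0.93 * 27.0 - 12.0, rel=1e-12
    )
    assert bulk_leaf_water_ss(r_e, r_s, 1.0) == r_e
    assert bulk_leaf_water_ss(r_e, r_s, 0.0) == r_s


# --- non-steady state ----------------------------------------------------------

def test_nonsteady_zero_transpiration_frozen():
    r = delta_to_ratio(5.0, R_VSMOW)
    r_ss = delta_to_ratio(20.0, R_VSMOW)
    out = leaf_water_nonsteady_step(r, r_ss, 0.0, 0.01, 0.02, 1.0095, 1.025, 0.9, 5.6, 1800)
    assert out == r


def test_nonsteady_converges_to_steady_state():
    r = delta_to_ratio(-12.0, R_VSMOW)
    r_ss = delta_to_ratio(18.0, R_VSMOW)
    for _ in range(3000):
        r = leaf_water_nonsteady_step(r, r_ss, 1e-3, 0.01, 0.02, 1.0095, 1.025, 0.9, 5.6, 1800)
    assert abs(r - r_ss) < 1e-9 * r_ss


def test_nonsteady_against_fine_ode_oracle(gas30, forcings30):
    """Implicit update vs adaptive ODE integration over ten diurnal cycles."""
    p = O18Params()
    gas = gas30.iloc[: 48 * 10]
    f = forcings30.iloc[: 48 * 10]
    r_s = delta_to_ratio(f["delta18O_source"].to_numpy(), R_VSMOW)
    r_v = delta_to_ratio(f["delta18O_vapor"].to_numpy(), R_VSMOW)
    t = np.clip(gas["T_air"].to_numpy(), -10, 45)
    a_plus = equilibrium_fractionation(t)
    a_k = kinetic_fractionation(gas["g_s"].to_numpy(), gas["g_b"].to_numpy(), p)
    e_flux, w_a, w_i = (gas[c].to_numpy() for c in ("E", "w_a", "w_i"))
    f1 = np.asarray(peclet_f1(e_flux, p))
    r_e = evaporative_site_ratio(r_s, r_v, w_a, w_i, a_plus, a_k)
    r_ss = bulk_leaf_water_ss(r_e, r_s, f1)

    r_be = r_ode = r_ss[0]
    worst = 0.0
    for i in range(len(gas)):
        lam = nonsteady_rate(e_flux[i], w_a[i], w_i[i], a_plus[i], a_k[i], f1[i], p.W)
        r_be = leaf_water_nonsteady_step(
            r_be, r_ss[i], e_flux[i], w_a[i], w_i[i], a_plus[i], a_k[i], f1[i], p.W, 1800
        )
        sol = solve_ivp(
            lambda _, y: lam * (r_ss[i] - y), (0, 1800), [r_ode],
            rtol=1e-10, atol=1e-18,
        )
        r_ode = sol.y[0, -1]
        worst = max(worst, abs(r_be - r_ode))
    assert worst / R_VSMOW * 1000 < 0.05  # permil


def test_nonsteady_lags_steady(season90):
    """Cross-correlation of non-steady vs steady leaf water peaks at lag > 0."""
    a = season90["delta18O_lw"].to_numpy()
    b = season90["delta18O_lw_ss"].to_numpy()
    lags = np.arange(0, 12)
    cc = [np.corrcoef(a[l:], b[: len(b) - l] if l else b)[0, 1] for l in lags]
    assert int(np.argmax(cc)) > 0


# --- epsilon_wc ----------------------------------------------------------------

def test_epsilon_wc_constant():
    assert epsilon_wc(12.3, "constant") == 27.0


@pytest.mark.parametrize("t, expected", [(-2.9, 34.6), (30.7, 25.4)])
def test_epsilon_wc_seasonal_anchors(t, expected):
    assert epsilon_wc(t, "temperature") == pytest.approx(expected, abs=0.05)


def test_epsilon_wc_shape():
    t = np.linspace(-10, 45, 500)
    e = epsilon_wc(t, "temperature")
    assert (np.diff(e) <= 1e-12).all()  # non-increasing
    # steeper decline below 20 degC than above
    low = epsilon_wc(0.0, "temperature") - epsilon_wc(10.0, "temperature")
    high = epsilon_wc(20.0, "temperature") - epsilon_wc(30.0, "temperature")
    assert low > high > 0
    with pytest.raises(ValueError):
        epsilon_wc(10.0, "nope")


# --- cross-variant properties --------------------------------------------------

def test_variant_ordering(gas90, forcings90):
    """Craig-Gordon >= two-pool/Peclet >= source water whenever air is
    subsaturated (the Craig-Gordon model gives the highest enrichment)."""
    cg = leaf_water_series(gas90, forcings90, model="craig_gordon", nonsteady=False)
    tp = leaf_water_series(gas90, forcings90, model="two_pool", nonsteady=False)
    pe = leaf_water_series(gas90, forcings90, model="peclet", nonsteady=False)
    sub = (gas90["w_i"] - gas90["w_a"]) > 1e-5
    src = forcings90["delta18O_source"]
    assert (cg.loc[sub, "delta18O_lw_ss"] >= tp.loc[sub, "delta18O_lw_ss"] - 1e-9).all()
    assert (cg.loc[sub, "delta18O_lw_ss"] >= pe.loc[sub, "delta18O_lw_ss"] - 1e-9).all()
    assert (tp.loc[sub, "delta18O_lw_ss"] >= src[sub] - 1e-9).all()
    assert (pe.loc[sub, "delta18O_lw_ss"] >= src[sub] - 1e-9).all()


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.floats(min_value=-60.0, max_value=60.0))
def test_delta_ratio_round_trip(delta):
    assert ratio_to_delta(delta_to_ratio(delta, R_VSMOW), R_VSMOW) == pytest.approx(
        delta, abs=1e-9, rel=1e-12
    )
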