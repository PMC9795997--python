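"""Sugar pool mass balance, WSC mixing, formation-period weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needleiso.conversions import R_VSMOW, delta_to_ratio, ratio_to_delta
from needleiso.sugar_pool import (
    PoolParams,
    compute_weights,
    current_day_weight,
    mix_wsc,
    turnover_alpha,
    update_pool_c13,
    update_pool_o18,
    weighted_driver,
)

DT = 1800.0
S_SUG = 1.96e5
R0 = delta_to_ratio(30.0, R_VSMOW)
RA = delta_to_ratio(33.0, R_VSMOW)


def test_night_leaves_pool_unchanged():
    # A_n = -r_d: zero gross input, balanced output terms
    assert update_pool_o18(R0, RA, -0.5, 0.5, -0.5, S_SUG, DT) == R0
    assert update_pool_c13(R0, RA, 0.015, -0.5, -0.5, S_SUG, DT) == R0
    with pytest.raises(ValueError):
        update_pool_o18(R0, RA, 1.0, 0.5, 1.0, -1.0, DT)


def test_pool_converges_to_constant_input():
    r_o = r_c = R0
    for _ in range(4000):
        r_o = update_pool_o18(r_o, RA, 4.0, 0.5, 4.0, S_SUG, DT)
        r_c = update_pool_c13(r_c, RA, 0.020, 4.0, 4.0, S_SUG, DT)
    assert r_o == pytest.approx(RA, rel=1e-10)
    assert r_c == pytest.approx(RA / 1.020, rel=1e-10)


def test_one_step_matches_alpha_form():
    """The implicit update equals the alpha-recursion rearrangement."""
    a_n, r_d = 3.7, 0.6
    alpha = (a_n + r_d) / (S_SUG / DT + a_n + r_d)
    got = update_pool_o18(R0, RA, a_n, r_d, a_n, S_SUG, DT)
    assert got == pytest.approx(alpha * RA + (1 - alpha) * R0, rel=1e-14)


def test_two_step_geometric_recursion():
    """Closed-form two-step unroll of the 13C update with constant forcing."""
    a_n, delta = 4.0, 0.018
    beta = a_n / (S_SUG / DT + a_n)
    r_in = RA / (1 + delta)
    r1 = update_pool_c13(R0, RA, delta, a_n, a_n, S_SUG, DT)
    r2 = update_pool_c13(r1, RA, delta, a_n, a_n, S_SUG, DT)
    expected = (1 - beta) ** 2 * R0 + (1 - (1 - beta) ** 2) * r_in
    assert r2 == pytest.approx(expected, rel=1e-14)


def test_mix_wsc_examples():
    r_sug = delta_to_ratio(30.0, R_VSMOW)
    r_pin = delta_to_ratio(25.0, R_VSMOW)
    assert mix_wsc(r_sug, r_pin, 1.0, 0.0) == r_sug
    got = ratio_to_delta(mix_wsc(r_sug, r_pin, 1.0, 0.7), R_VSMOW)
    assert got == pytest.approx((30.0 + 0.7 * 25.0) / 1.7, rel=1e-12)
    assert mix_wsc(r_pin, r_pin, 1.0, 0.7) == pytest.approx(r_pin, rel=1e-15)
    with pytest.raises(ValueError):
        mix_wsc(r_sug, r_pin, 0.0, 0.0)


def test_weights_geometric_closed_form():
    """Constant alpha = 0.05: w_n = 0.05 * 0.95^n, tau = 58 steps (29 h)."""
    # alpha = g/(S/dt + g) = 0.05  =>  g = S/dt / 19
    g = S_SUG / DT / 19.0
    n = 200
    res = compute_weights(np.full(n, g), np.zeros(n), S_SUG, DT, cutoff=0.95)
    assert res.tau == 58
    assert res.formation_period_h == pytest.approx(29.0)
    expected = 0.05 * 0.95 ** np.arange(res.tau + 1)
    assert np.allclose(res.weights, expected, rtol=1e-10)


def test_instant_turnover_limit():
    """alpha = 1 at the latest step: all weight on now, tau = 0."""
    a_n = np.array([1.0, 1.0, 1e12])
    res = compute_weights(a_n, np.zeros(3), S_SUG, DT, cutoff=0.95)
    assert res.tau == 0
    assert res.weights[0] == pytest.approx(1.0)


def test_insufficient_history_raises():
    with pytest.raises(ValueError, match="look-back"):
        compute_weights(np.full(3, 0.5), np.zeros(3), S_SUG, DT, cutoff=0.95)


def test_expansion_matches_recursion(gas30):
    """Implicit pool recursion vs weighted expansion, within truncation."""
    a_n = gas30["A_n"].to_numpy()
    r_d = gas30["r_d"].to_numpy()
    rng = np.random.default_rng(0)
    r_in = delta_to_ratio(rng.uniform(25, 40, len(a_n)), R_VSMOW)

    r = r_in[0]
    trace = np.empty(len(a_n))
    for i in range(len(a_n)):
        alpha = float(turnover_alpha(a_n[i], r_d[i], S_SUG, DT))
        r = alpha * r_in[i] + (1 - alpha) * r
        trace[i] = r

    t = len(a_n) - 1
    res = compute_weights(a_n, r_d, S_SUG, DT, cutoff=0.95)
    approx = weighted_driver(r_in[: t + 1][::-1], res)
    # truncation leaves <= (1 - cutoff) of the dynamic range unexplained
    tol = (1 - 0.95) * (r_in.max() - r_in.min()) + 1e-15
    assert abs(approx - trace[t]) < tol


def test_weighted_driver_basics():
    w = compute_weights(np.full(300, 4.0), np.full(300, 0.5), S_SUG, DT, 0.95)
    assert weighted_driver(np.full(w.tau + 1, 70.0), w) == pytest.approx(70.0)
    delta_w = np.zeros(5)
    delta_w[2] = 1.0
    assert weighted_driver(np.arange(5.0), delta_w) == 2.0
    with pytest.raises(ValueError):
        weighted_driver(np.zeros(3), np.zeros(3))


def test_current_day_weight_partition():
    w = compute_weights(np.full(300, 4.0), np.full(300, 0.5), S_SUG, DT, 0.95)
    full = current_day_weight(w, 10**6)
    assert full == pytest.approx(1.0)
    part = current_day_weight(w, 27)  # sampled at 13:30
    assert 0.0 < part < full


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_pool_convexity_property(seed):
    """The pool ratio stays within the running envelope of its inputs."""
    rng = np.random.default_rng(seed)
    n = 300
    a_n = rng.uniform(0.0, 8.0, n)
    r_d = rng.uniform(0.1, 1.0, n)
    r_in = delta_to_ratio(rng.uniform(20, 40, n), R_VSMOW)
    r = r_in[0]
    lo = hi = r
    for i in range(n):
        r = update_pool_o18(r, r_in[i], a_n[i], r_d[i], a_n[i], S_SUG, DT)
        lo, hi = min(lo, r_in[i]), max(hi, r_in[i])
        assert lo - 1e-15 <= r <= hi + 1e-15


def test_pool_params_validation():
    with pytest.raises(ValueError):
        PoolParams(s_sug=-1.0)
    with pytest.raises(ValueError):
        PoolParams(cutoff=1.5)
    p = PoolParams()
    assert p.with_size("negligible").s_sug == pytest.approx(p.s_sug / 20.0)
    assert p.s_pin == pytest.approx(0.7 * p.s_sug)
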