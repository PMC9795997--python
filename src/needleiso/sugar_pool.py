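"""Well-mixed needle sugar pool: isotopic mass balance, mixing with pinitol
into bulk water-soluble carbohydrates (WSC), and the signal-formation-period
weighting machinery.

The pool has constant size S_sug, receives gross assimilation (A_n + r_d) at
the ratio of new assimilates, and loses carbon to respiration and phloem
export (q = A_n closure, so pool size stays constant).  The implicit update

    R_sug(t) = alpha_t R_assim(t) + (1 - alpha_t) R_sug(t-1),
    alpha_t = (A_n + r_d) / (S_sug/dt + A_n + r_d)

unrolls into a weighted mean over past assimilates with weights
w_n = alpha_{t-n} prod_{i<n} (1 - alpha_{t-i}); the smallest look-back tau
whose cumulative weight reaches the cutoff (0.95) defines the formation
period tau*dt of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PoolParams:
    """Sugar/pinitol pool sizes and compositions."""

    s_sug: float = 1.96e5          # umol C m-2, observed needle sugar pool
    pinitol_ratio: float = 0.7     # S_pin / S_sug
    delta13c_pin: float = -30.5    # permil VPDB, invariant pinitol
    delta18o_pin: float = 25.0     # permil VSMOW, invariant pinitol
    cutoff: float = 0.95           # cumulative-weight threshold
    negligible_factor: float = 20.0

    def __post_init__(self):
        if self.s_sug <= 0:
            raise ValueError("s_sug must be positive")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be in (0, 1)")

    @property
    def s_pin(self) -> float:
        return self.pinitol_ratio * self.s_sug

    def with_size(self, pool_size: str) -> "PoolParams":
        """``observed`` keeps S_sug; ``negligible`` divides it 20-fold."""
        if pool_size == "observed":
            return self
        if pool_size == "negligible":
            from dataclasses import replace
            return replace(self, s_sug=self.s_sug / self.negligible_factor)
        raise ValueError(f"unknown pool size {pool_size!r}")


@dataclass
class WeightingResult:
    weights: np.ndarray        # w_0 (current step) .. w_tau (oldest retained)
    tau: int                   # steps retained to reach the cutoff
    formation_period_h: float  # tau * dt in hours
    total_weight: float        # sum of raw (unnormalized) weights


def turnover_alpha(a_n, r_d, s_sug: float, dt: float):
    """Per-step new-assimilate fraction alpha; clamped to 0 when the gross
    input A_n + r_d is not positive (the weights are derived for input >= 0)."""
    gross = np.clip(np.asarray(a_n, dtype=float) + np.asarray(r_d, dtype=float), 0.0, None)
    return gross / (s_sug / dt + gross)


def update_pool_o18(r_sug_prev, r_assim, a_n, r_d, q, s_sug, dt):
    """Implicit update of the sugar-pool 18O ratio (oxygen mass balance).

    d(S_sug R_sug)/dt = (A_n + r_d) R_assim - r_d R_sug - q R_sug; with the
    q = A_n closure this is the alpha-form recursion.  Night steps
    (A_n + r_d <= 0) leave the ratio unchanged.
    """
    if s_sug <= 0:
        raise ValueError("s_sug must be positive")
    gross = a_n + r_d
    if not np.isfinite(gross) or gross <= 0.0:
        return r_sug_prev
    return (s_sug / dt * r_sug_prev + gross * r_assim) / (s_sug / dt + r_d + q)


def update_pool_c13(r_sug_prev, r_a, delta13, a_n, q, s_sug, dt):
    """Implicit update of the sugar-pool 13C ratio (carbon mass balance).

    d(S_sug R_sug)/dt = A_n R_a/(1 + 13Delta) - q R_sug.  Masked
    discrimination steps and steps with A_n <= 0 contribute no update.
    """
    if s_sug <= 0:
        raise ValueError("s_sug must be positive")
    if not np.isfinite(delta13) or a_n <= 0.0:
        return r_sug_prev
    return (s_sug / dt * r_sug_prev + a_n * r_a / (1.0 + delta13)) / (s_sug / dt + q)


def mix_wsc(r_sug, r_pin, s_sug, s_pin):
    """Concentration-weighted WSC ratio: (S_sug R_sug + S_pin R_pin)/(S_sug + S_pin)."""
    total = s_sug + s_pin
    if total <= 0:
        raise ValueError("total carbohydrate concentration must be positive")
    return (s_sug * np.asarray(r_sug, dtype=float) + s_pin * r_pin) / total


def compute_weights(a_n, r_d, s_sug: float, dt: float, cutoff: float = 0.95) -> WeightingResult:
    """Weights of past assimilation steps in the current sugar-pool signal.

    ``a_n`` and ``r_d`` are history series ending at the current step (last
    element = now).  Raises if the available history is too short for the
    cumulative weight to reach ``cutoff``.
    """
    alpha = np.asarray(turnover_alpha(a_n, r_d, s_sug, dt), dtype=float)[::-1]
    # alpha[0] is the current step; survival is the product of (1 - alpha)
    survival = np.cumprod(1.0 - alpha)
    weights = alpha * np.concatenate(([1.0], survival[:-1]))
    csum = np.cumsum(weights)
    reached = np.nonzero(csum >= cutoff)[0]
    if reached.size == 0:
        raise ValueError(
            f"history of {alpha.size} steps reaches cumulative weight "
            f"{csum[-1]:.3f} < cutoff {cutoff}; extend the look-back"
        )
    tau = int(reached[0])
    w = weights[: tau + 1]
    return WeightingResult(
        weights=w, tau=tau, formation_period_h=tau * dt / 3600.0,
        total_weight=float(csum[tau]),
    )


def weighted_driver(driver, weighting: WeightingResult | np.ndarray) -> float:
    """Normalized weighted mean of a driver series over the retained window.

    ``driver`` is ordered like the weights: element 0 is the current step,
    element n the step n intervals back.
    """
    w = weighting.weights if isinstance(weighting, WeightingResult) else np.asarray(weighting)
    d = np.asarray(driver, dtype=float)[: w.size]
    if d.size != w.size:
        raise ValueError("driver shorter than the weight window")
    total = w.sum()
    if total <= 0.0:
        raise ValueError("all-zero weights")
    return float(np.dot(w, d) / total)


def current_day_weight(weighting: WeightingResult, steps_since_midnight: int) -> float:
    """Summed (unnormalized) weight of the steps within the current day."""
    w = weighting.weights
    n = min(steps_since_midnight + 1, w.size)
    return float(w[:n].sum() / max(weighting.total_weight, 1e-300))
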