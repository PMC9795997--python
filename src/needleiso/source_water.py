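"""Daily source-water delta18O from a single well-mixed soil bucket.

Precipitation mixes instantly into the plant-available water store (amount-
weighted in depth x ratio space), excess above capacity overflows at the
mixed composition, and evapotranspiration removes water at the stored
composition (root uptake does not fractionate).  Both the water and the
isotope balances close exactly each day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SourceWaterParams:
    capacity_mm: float = 120.0
    initial_depth_mm: float = 100.0
    initial_delta: float = -12.0   # permil VSMOW

    def __post_init__(self):
        if self.capacity_mm <= 0 or self.initial_depth_mm < 0:
            raise ValueError("bucket sizes must be non-negative")
        if self.initial_depth_mm > self.capacity_mm:
            raise ValueError("initial depth exceeds capacity")


@dataclass
class SourceWaterState:
    pool_depth: float        # mm of plant-available water
    delta18O_source: float   # permil VSMOW


def step_source_water(
    state: SourceWaterState,
    precip_mm: float,
    precip_delta: float,
    et_mm: float,
    capacity_mm: float = 120.0,
) -> SourceWaterState:
    """Advance the bucket by one day."""
    if precip_mm < 0 or et_mm < 0:
        raise ValueError("fluxes must be non-negative")
    depth = state.pool_depth + precip_mm
    if depth > 0:
        delta = (state.pool_depth * state.delta18O_source + precip_mm * precip_delta) / depth
    else:
        delta = state.delta18O_source
    depth = min(depth, capacity_mm)            # overflow at the mixed delta
    depth = max(depth - min(et_mm, depth), 0.0)  # ET capped at available water
    return SourceWaterState(pool_depth=depth, delta18O_source=delta)


def run_source_water(
    daily: pd.DataFrame, params: SourceWaterParams | None = None
) -> pd.DataFrame:
    """Run the bucket over a daily table with columns ``precip_mm``,
    ``precip_delta18O`` and ``et_mm``; returns daily depth and delta."""
    p = params or SourceWaterParams()
    state = SourceWaterState(p.initial_depth_mm, p.initial_delta)
    depths = np.empty(len(daily))
    deltas = np.empty(len(daily))
    for i, row in enumerate(daily.itertuples()):
        state = step_source_water(
            state, row.precip_mm, row.precip_delta18O, row.et_mm, p.capacity_mm
        )
        depths[i] = state.pool_depth
        deltas[i] = state.delta18O_source
    return pd.DataFrame(
        {"pool_depth": depths, "delta18O_source": deltas}, index=daily.index
    )


def to_halfhourly(daily_delta: pd.Series, grid: pd.DatetimeIndex) -> pd.Series:
    """Join a daily source-water series onto the half-hourly grid (forward fill)."""
    return daily_delta.reindex(grid.normalize()).set_axis(grid).ffill().bfill()
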