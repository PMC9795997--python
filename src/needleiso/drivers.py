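"""Synthetic half-hourly meteorological and isotopic forcing for a boreal
growing season.

The generator emulates the statistical structure of mid-boreal (ca. 61.8 N)
growing-season weather: a solar-geometry PAR cycle, diurnal temperature and
humidity cycles lagging PAR, first-order autoregressive day-to-day anomalies,
a prescribed late-summer soil-moisture dry-down, seasonally varying water
vapor and source water delta18O (vapor anomalies coupled negatively to the
vapor pressure deficit), and near-constant atmospheric delta13C around
-8.5 permil.  Everything is driven by a single integer seed and is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gas_exchange import saturation_vapor_pressure

STEP_SECONDS = 1800
STEPS_PER_DAY = 48

METEO_COLUMNS = ["T_air", "PAR", "e_a", "C_a", "theta", "P_atm"]
FORCING_COLUMNS = ["delta18O_vapor", "delta18O_source", "delta13C_atm"]

_METEO_HEADER = (
    "# half-hourly meteorological drivers: T_air [degC], PAR [umol m-2 s-1], "
    "e_a [kPa], C_a [umol mol-1], theta [m3 m-3], P_atm [kPa]\n"
)
_FORCING_HEADER = (
    "# isotopic forcing: delta18O_vapor [permil VSMOW, 6-hourly blocks], "
    "delta18O_source [permil VSMOW, daily], delta13C_atm [permil VPDB, weekly]\n"
)


@dataclass(frozen=True)
class BorealScenario:
    """Scenario parameters for the synthetic growing season.

    Seasonal anchors follow the climatology of a southern-Finland pine stand:
    temperature and VPD peaking in July, PAR peaking near the June solstice,
    and a dry-down of the shallow mineral-soil moisture in late summer.
    """

    start_month: int = 5
    start_day: int = 1
    year: int = 2018
    latitude_deg: float = 61.85
    p_atm: float = 101.3  # kPa, low-elevation site, held constant

    # temperature (degC)
    t_mean: float = 13.0
    t_seasonal_amplitude: float = 6.0   # around the July peak
    t_diurnal_amplitude: float = 4.5
    t_peak_doy: float = 200.0
    t_diurnal_peak_hour: float = 14.0   # lags solar noon
    t_noise_sd: float = 2.5             # day-level AR(1) anomaly
    t_noise_rho: float = 0.7

    # synoptic weather: one AR(1) index per day couples the anomalies the way
    # frontal systems do (clear days are warm and dry, overcast days humid
    # and cool); loadings give the share of each anomaly carried by it
    synoptic_rho: float = 0.65
    t_syn_load: float = 0.5
    rh_syn_load: float = -0.8

    # PAR (umol m-2 s-1)
    par_clear_sky: float = 1500.0
    cloud_min: float = 0.25

    # humidity (fractional RH used to build e_a; RH itself is never stored)
    rh_night: float = 0.92
    rh_day: float = 0.55
    rh_noise_sd: float = 0.07
    rh_noise_rho: float = 0.7

    # CO2 (umol mol-1)
    ca_mean: float = 402.0
    ca_diurnal_amplitude: float = 8.0
    ca_noise_sd: float = 1.5

    # soil moisture (m3 m-3): monotone dry-down over a stated window
    theta_wet: float = 0.30
    theta_dry: float = 0.10
    drydown_start_frac: float = 0.55    # fraction of the season
    drydown_end_frac: float = 0.85

    # vapor delta18O (permil VSMOW, 6-hourly)
    vapor_mean: float = -17.0
    vapor_seasonal_amplitude: float = 2.5
    vapor_vpd_coupling: float = 2.0     # permil per kPa of block-mean VPD anomaly
    vapor_noise_sd: float = 1.0
    vapor_noise_rho: float = 0.5

    # source water delta18O (permil VSMOW, daily)
    source_mean: float = -12.0
    source_seasonal_amplitude: float = 1.2
    source_noise_sd: float = 0.25
    source_noise_rho: float = 0.9

    # atmospheric CO2 delta13C (permil VPDB, weekly)
    atm_d13c_mean: float = -8.5
    atm_d13c_sd: float = 0.15

    def quiet(self) -> "BorealScenario":
        """A degenerate copy with all diurnal/seasonal/noise amplitudes zero."""
        return replace(
            self,
            t_seasonal_amplitude=0.0, t_diurnal_amplitude=0.0, t_noise_sd=0.0,
            rh_day=self.rh_night, rh_noise_sd=0.0,
            ca_diurnal_amplitude=0.0, ca_noise_sd=0.0,
            vapor_seasonal_amplitude=0.0, vapor_vpd_coupling=0.0,
            vapor_noise_sd=0.0,
            source_seasonal_amplitude=0.0, source_noise_sd=0.0,
            atm_d13c_sd=0.0,
            theta_dry=self.theta_wet,
        )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    z = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = z[0] * sd
    innov = sd * np.sqrt(max(1.0 - rho * rho, 0.0))
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov * z[i]
    return out


def solar_elevation_sine(doy: np.ndarray, hour: np.ndarray, latitude_deg: float) -> np.ndarray:
    """sin(solar elevation) from day of year and local solar hour."""
    lat = np.deg2rad(latitude_deg)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    return np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)


def generate_meteo(n_days: int, seed: int, scenario: BorealScenario | None = None) -> pd.DataFrame:
    """Generate a half-hourly driver table for ``n_days`` days.

    Returns a DataFrame indexed by timestamp with columns ``T_air`` (degC),
    ``PAR`` (umol m-2 s-1), ``e_a`` (kPa), ``C_a`` (umol mol-1), ``theta``
    (m3 m-3) and ``P_atm`` (kPa).  Identical (seed, scenario) pairs give
    identical output.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    sc = scenario or BorealScenario()
    rng = np.random.default_rng(seed)

    n = n_days * STEPS_PER_DAY
    index = pd.date_range(
        start=pd.Timestamp(year=sc.year, month=sc.start_month, day=sc.start_day),
        periods=n, freq="30min", name="timestamp",
    )
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    day_idx = np.arange(n) // STEPS_PER_DAY

    # day-level anomalies: a synoptic AR(1) index (positive = clear/warm/dry)
    # plus independent residuals, expanded onto the half-hourly grid
    synoptic = _ar1(rng, n_days, sc.synoptic_rho, 1.0)
    t_resid = _ar1(rng, n_days, sc.t_noise_rho, 1.0)
    rh_resid = _ar1(rng, n_days, sc.rh_noise_rho, 1.0)
    t_anom = sc.t_noise_sd * (
        sc.t_syn_load * synoptic + np.sqrt(1.0 - sc.t_syn_load**2) * t_resid
    )[day_idx]
    rh_anom = sc.rh_noise_sd * (
        sc.rh_syn_load * synoptic + np.sqrt(1.0 - sc.rh_syn_load**2) * rh_resid
    )[day_idx]
    cloud_raw = synoptic[day_idx]
    ca_anom = _ar1(rng, n_days, 0.5, sc.ca_noise_sd)[day_idx]

    sin_elev = solar_elevation_sine(doy, hour, sc.latitude_deg)
    sun = np.clip(sin_elev, 0.0, None)
    # cloudiness factor in [cloud_min, 1], skewed toward clear days
    cloud = sc.cloud_min + (1.0 - sc.cloud_min) / (1.0 + np.exp(-(1.0 + cloud_raw)))
    par = sc.par_clear_sky * sun * cloud
    par[sin_elev <= 0.0] = 0.0

    t_season = sc.t_mean + sc.t_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - sc.t_peak_doy) / 365.0
    )
    t_diurnal = sc.t_diurnal_amplitude * np.cos(
        2.0 * np.pi * (hour - sc.t_diurnal_peak_hour) / 24.0
    )
    t_air = t_season + t_diurnal + t_anom

    # relative humidity: high at night, low at midday, day-level anomalies
    daylight = sun / max(np.max(sun), 1e-9)
    rh = sc.rh_night - (sc.rh_night - sc.rh_day) * daylight + rh_anom
    rh = np.clip(rh, 0.15, 1.0)
    e_sat = saturation_vapor_pressure(t_air)
    e_a = rh * e_sat
    if np.any(e_a <= 0.0):
        raise ValueError("scenario produced non-positive vapor pressure")

    c_a = sc.ca_mean - sc.ca_diurnal_amplitude * daylight + ca_anom

    frac = (day_idx + 0.5) / n_days
    ramp = np.clip(
        (frac - sc.drydown_start_frac)
        / max(sc.drydown_end_frac - sc.drydown_start_frac, 1e-9),
        0.0, 1.0,
    )
    theta = sc.theta_wet - (sc.theta_wet - sc.theta_dry) * ramp

    return pd.DataFrame(
        {
            "T_air": t_air,
            "PAR": par,
            "e_a": e_a,
            "C_a": c_a,
            "theta": theta,
            "P_atm": np.full(n, sc.p_atm),
        },
        index=index,
    )


def generate_isotope_forcings(
    meteo: pd.DataFrame, seed: int, scenario: BorealScenario | None = None
) -> pd.DataFrame:
    """Generate isotopic forcing aligned to a driver table.

    Vapor delta18O is piecewise-constant over 6-hourly blocks and co-varies
    negatively with the block-mean vapor pressure deficit; source-water
    delta18O changes only at day boundaries; atmospheric delta13C changes
    weekly around the scenario mean.
    """
    sc = scenario or BorealScenario()
    rng = np.random.default_rng(seed)
    n = len(meteo)
    if n == 0 or n % STEPS_PER_DAY:
        raise ValueError("meteo must cover whole days on the half-hourly grid")

    step = np.arange(n)
    block6h = step // 12
    day_idx = step // STEPS_PER_DAY
    week_idx = step // (7 * STEPS_PER_DAY)
    doy = meteo.index.dayofyear.to_numpy().astype(float)

    vpd = saturation_vapor_pressure(meteo["T_air"].to_numpy()) - meteo["e_a"].to_numpy()
    n_blocks = int(block6h[-1]) + 1
    vpd_block = np.bincount(block6h, weights=vpd, minlength=n_blocks) / np.bincount(
        block6h, minlength=n_blocks
    )
    vpd_anom = vpd_block - vpd_block.mean()

    vapor_block = (
        sc.vapor_mean
        + sc.vapor_seasonal_amplitude
        * np.cos(2.0 * np.pi * (np.bincount(block6h, weights=doy, minlength=n_blocks)
                                / np.bincount(block6h, minlength=n_blocks) - sc.t_peak_doy) / 365.0)
        - sc.vapor_vpd_coupling * vpd_anom
        + _ar1(rng, n_blocks, sc.vapor_noise_rho, sc.vapor_noise_sd)
    )
    vapor = np.clip(vapor_block, -40.0, -5.0)[block6h]

    n_days = int(day_idx[-1]) + 1
    doy_day = doy[::STEPS_PER_DAY]
    source_day = (
        sc.source_mean
        + sc.source_seasonal_amplitude * np.cos(2.0 * np.pi * (doy_day - sc.t_peak_doy) / 365.0)
        + _ar1(rng, n_days, sc.source_noise_rho, sc.source_noise_sd)
    )
    source = np.clip(source_day, -16.0, -8.0)[day_idx]

    n_weeks = int(week_idx[-1]) + 1
    d13c_week = sc.atm_d13c_mean + sc.atm_d13c_sd * rng.standard_normal(n_weeks)
    d13c = np.clip(d13c_week, -10.0, -7.0)[week_idx]

    return pd.DataFrame(
        {"delta18O_vapor": vapor, "delta18O_source": source, "delta13C_atm": d13c},
        index=meteo.index,
    )


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a driver/forcing table as CSV with a unit-documenting comment line."""
    if header_comment is None:
        header_comment = (
            _METEO_HEADER if "T_air" in df.columns else _FORCING_HEADER
        )
    with open(path, "w") as fh:
        fh.write(header_comment)
        df.to_csv(fh, float_format="%.6f")


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#", index_col="timestamp", parse_dates=True)
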