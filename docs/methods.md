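# Methods

`needleiso` simulates how the oxygen and carbon isotope composition of the
sugars in conifer needles forms from half-hourly environmental conditions.
The target system is a boreal Scots pine canopy: needle sugars turn over on a
timescale of days, so the isotopic signal sampled in the field is neither the
instantaneous signal of new assimilates nor a season-long mean, but a
flux-weighted integral over a "formation period" of roughly two days to a
week. The package makes that integration explicit and quantifiable.

## Model chain

1. **Drivers.** Air temperature, PAR, ambient vapor pressure, atmospheric
   CO2, volumetric soil moisture on a regular 1800-s grid; isotopic forcing
   (water-vapor delta18O at 6-hourly resolution, source-water delta18O
   daily, atmospheric delta13C weekly) aligned to the same grid.
2. **Gas exchange** (`gas_exchange`). Farquhar-von Caemmerer-Berry
   two-limitation photosynthesis with Bernacchi temperature responses, a
   Medlyn-form stomatal model, fixed boundary-layer conductance, and a
   mesophyll closure C_c = 0.8 C_i. Leaf temperature equals air temperature;
   ternary effects are ignored throughout (consistently in gas exchange and
   discrimination). Each step closes supply A_n = g_t(C_a - C_i) against
   biochemical demand by bracketed root iteration to 1e-6 umol mol-1.
3. **Leaf water 18O** (`oxygen18`). Evaporative-site enrichment from the
   steady-state Craig-Gordon relation with Majoube equilibrium and
   conductance-weighted kinetic fractionation (28 permil stomata, 19 permil
   boundary layer); reduction to bulk mesophyll water by a constant two-pool
   factor f1 = 0.93 or a transpiration-dependent Peclet factor
   (L = 0.03 m, C = 55.5e3 mol m-3, D = 2.66e-9 m2 s-1); optional non-steady
   relaxation of bulk leaf water with pool size W = 5.6 mol m-2.
4. **New assimilates.** R_assim = alpha_wc * R_lw with the biochemical
   water-carbonyl fractionation epsilon_wc, either constant 27 permil or
   temperature dependent (below).
5. **13C discrimination** (`carbon13`). Net-flux discrimination in the
   Wingate form, where mitochondrial respiration draws on the needle sugar
   pool rather than on current assimilates, so the expression remains valid
   at night (k = 0 reduces it to the discrimination of dark respiration).
   Fractionation constants: a_b 2.9, a_s 4.4, a_m 1.8, b 29 (27 in the
   simple variant), f 8, e -6 permil.
6. **Pools** (`sugar_pool`). A well-mixed sugar pool of constant size
   S_sug = 1.96e5 umol C m-2 (phloem export q = A_n keeps it constant)
   integrated implicitly at the native step; bulk WSC is the
   concentration-weighted mixture of that pool with an invariant pinitol
   pool (S_pin = 0.7 S_sug, delta13C -30.5, delta18O +25 permil).
7. **Weights** (`sugar_pool`). The implicit pool update unrolls into weights
   w_n = alpha_{t-n} * prod_{i<n}(1 - alpha_{t-i}) over past steps; the
   smallest look-back reaching cumulative weight 0.95 defines the formation
   period, and the same weights turn RH and C_i/C_a into
   formation-period-weighted drivers.

All isotope arithmetic is in ratio space; per-mil values appear only at I/O
(VSMOW 18O/16O = 2005.20e-6, VPDB 13C/12C = 11180.2e-6). Fractionations are
stored as dimensionless fractions (29 permil = 0.029).

## epsilon_wc(T)

The temperature-dependent mode is a quadratic in Celsius temperature with
the Sternberg-Ellsworth curvature (0.0084 permil degC-2) whose linear and
constant coefficients are solved so the curve passes exactly through the two
seasonal anchor values (34.6 permil at -2.9 degC and 25.4 permil at
30.7 degC). The decline is steepest below 20 degC. Above the quadratic's
vertex (~30.2 degC) the curve is clamped flat so epsilon_wc is non-increasing
over the whole admissible range; the clamp costs <0.002 permil at the warm
anchor.

## Numerical choices

- **Non-steady leaf water.** The relaxation rate times the 1800-s step
  reaches ~0.6 at midday transpiration, where a single backward-Euler step
  is visibly over-damped (up to 0.35 permil trajectory error against the
  exact relaxation). The update therefore takes 10 implicit sub-steps per
  half hour with frozen forcing: still unconditionally stable through
  near-zero-transpiration nights, and within 0.05 permil of an adaptive ODE
  integration. When w_i - w_a < 1e-6 mol mol-1 only the division is guarded;
  the steady-state target stays defined by the Craig-Gordon relation.
- **Discrimination mask.** Near day/night transitions k*C_a - r_d crosses
  zero and the net-flux discrimination blows up as pure numerical noise.
  Steps with |k*C_a - r_d| < 0.15 umol m-2 s-1 are masked (<2% of a season;
  0.03% on the reference season) and contribute no pool update — the
  carbon flux there is negligible by construction. The tolerance sits below
  the night-time value of r_d so cold nights remain valid.
- **Pool updates.** Implicit (unconditionally stable) one-step updates; on
  steps with non-positive gross input (A_n + r_d <= 0 for oxygen, A_n <= 0 or
  masked discrimination for carbon) the pool is left unchanged, because the
  weight expansion is derived for non-negative input flux.
- **Respiratory substrate coupling.** The discrimination at step t uses the
  sugar-pool 13C ratio from step t-1 (explicit coupling). With the pool
  turning over in days and steps of 30 min, the lag error is far below the
  mask noise floor.
- **Flux-form identity.** The net-flux form of the 13C pool balance,
  A_n R_a/(1+Delta), matches the gross form
  (A_n+r_d) R_assim - r_d(1-e) R_sug only to first order in the
  fractionations; the residual is below 1% of the respiratory isoflux
  r_d R_a and is asserted at that scale in the tests, not at machine
  precision.

## Synthetic season

No field data ship with the package; every analysis runs on a generated
season designed to have the statistical structure of a mid-boreal (61.8 N)
growing season:

- solar-geometry PAR with day-level cloudiness; diurnal temperature lagging
  solar noon by ~2 h; RH high at night, low at midday;
- day-to-day anomalies from a synoptic AR(1) index that couples the
  variables the way frontal systems do (clear = warm and dry, overcast =
  humid and cool), plus independent residuals;
- a monotone late-season soil-moisture dry-down (0.30 to 0.10 m3 m-3 over a
  stated window) that throttles photosynthesis through a linear
  water-availability ramp applied to capacity and stomatal slope;
- vapor delta18O in 6-hourly blocks co-varying negatively with the vapor
  pressure deficit; source water varying slowly around -12 permil;
  atmospheric delta13C in weekly blocks around -8.5 permil.

Defaults were fixed once against the physiology the model family reports:
midday A_n of ~4-6 umol m-2 s-1 on an all-sided needle-area basis, daytime
C_i/C_a median ~0.75, C_c/C_i = 0.8, and a mid-season formation period of
about two days, lengthening beyond five days when assimilation is low.

What the generator does **not** emulate: gap structure and sensor noise of
real eddy-covariance/chamber records, rain-event soil-moisture recovery,
within-day humidity weather, isotopic memory between vapor and source water,
and needle-generation differences. A green behavioral test therefore
establishes that the mechanisms (pool damping, lag, formation-period
weighting, variant ordering) operate as described — not that the package
reproduces any particular field season.

## Evaluation design

Midday samples are means over step start times 12:00-15:00, mirroring the
early-afternoon collection window; sampling days default to every 7th
simulated day (about the cadence of ~20 collections over two seasons);
the first 7 days are spin-up and excluded. Pseudo-observations add Gaussian
noise at the stated analytical precisions (0.3 permil water delta18O,
0.2 permil carbohydrate isotopes). R2 is 1 - SSE/SST about the observation
mean; Pearson r and the least-squares line are reported alongside.

Two demonstrations deserve a caveat. (1) The weighted-driver comparison
(|r| of pool signal vs weighted driver >= vs sampling-day driver) is run on
a season whose variance is day-to-day weather: under a season-long monotone
drought trend both drivers see the same trend and the comparison becomes
uninformative; the drought response is instead covered by the
formation-period lengthening. (2) C_i/C_a declines with drying soil over
the moderate-stress part of the ramp; near the compensation point C_i must
climb back toward C_a as assimilation vanishes, so the monotone C_i/C_a
response is asserted only for moderate stress.

## Known limitations

- The supplement with the source study's exact gas-exchange equations and
  parameter values is not publicly available; the `gas_exchange` module is a
  standard FvCB/Medlyn implementation with parameters chosen once for the
  stated emergent behavior, and the source-water bucket is a minimal
  mass-balance model with configurable capacity.
- One well-mixed sugar pool of constant size: no fast/slow sucrose
  transport pools, no starch, no diurnal or seasonal concentration change.
- No leaf energy balance, no ternary corrections, no isotopically
  disconnected respiration, no deuterium.
- The Peclet factor uses instantaneous transpiration; at night E ~ 0 drives
  f1 to 1 instantaneously, which is irrelevant in the non-steady variant
  because the relaxation rate is proportional to E.
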