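# Methods

`stormflux` packages the diagnostics used to quantify how intense tropical
cyclones (TCs) perturb the surface-ocean carbon cycle: detection and
tracking of storms from 2-D pressure/wind fields, air–sea CO₂ exchange and
carbonate chemistry, along-track composites, a Takahashi-style decomposition
of surface-pCO₂ changes, tracer-budget closure with a temperature
counterfactual for remineralization — plus a seeded synthetic TC–ocean
scenario generator that supplies gridded inputs with known ground truth.

## Cyclone tracking

Candidates are mean-sea-level-pressure minima below 1,010 hPa, extracted by
iteratively taking the global minimum of a snapshot and masking an 800-km
disc around it until no cell remains below threshold; any two candidates in
a snapshot are therefore more than 800 km apart. The wind attributed to a
candidate is the maximum within 200 km of the pressure minimum (the wind
maximum sits at the radius of maximum wind, not at the centre; the radius is
configurable). Stitching is greedy: the earliest candidate with winds of at
least 17 m s⁻¹ inside the genesis band (absolute latitude 0–35°, optionally
northern-hemisphere only) starts a track; extension searches snapshot by
snapshot from the next time step out to 24 h (inclusive) and stops at the
first snapshot containing any qualifying point within 100 km (inclusive);
among same-time matches the lowest MSLP wins and the losing points are
discarded, which makes the construction invariant to storage order.
Retained tracks must have lifetime strictly greater than 24 h and
lifetime-maximum intensity strictly above hurricane strength (33 m s⁻¹).
Distances are haversine on a 6,371-km sphere. Note the stitching radius sets
a resolution floor: grids coarser than ~0.9° cannot be tracked because
adjacent-cell jumps exceed 100 km.

## Carbonate system and gas exchange

The air–sea flux is F = k_w · S_CO2 · (pCO₂ᵒᶜ − pCO₂ᵃᵗᵐ), positive upward.
k_w = 0.251 u₁₀² (Sc/660)^(−1/2) cm h⁻¹ (Wanninkhof 2014, with the 2014
Schmidt-number quartic, valid −2…40 °C), so k_w is exactly quadratic in
wind at fixed temperature. S_CO2 is the Weiss (1974) volumetric solubility,
converted to mol m⁻³ µatm⁻¹. pCO₂ᵃᵗᵐ = xCO₂ · (SLP − saturation water
vapour pressure), with the Weiss & Price (1980) vapour-pressure fit; the
default dry-air mole fraction (414 ppm) represents year-2020 conditions.

Surface pCO₂ is solved from DIC and total alkalinity on the total pH scale
with an OMIP-style constant set: K₁/K₂ from Lueker et al. (2000), K_B from
Dickson (1990), K_W from the Dickson et al. (2007) refit, total boron from
Uppström (1974), gravimetric K₀ from Weiss (1974), and a fugacity correction
from the CO₂ virial coefficients. The alkalinity balance (carbonate,
bicarbonate, borate, water) is solved for [H⁺] by bisection in log space on
pH ∈ [3, 12] — monotone, hence unconditionally bracketed — to an alkalinity
tolerance of 10⁻³ µmol kg⁻¹ within at most 100 iterations, fully vectorised
over grids. Sulfate and fluoride association are neglected in the balance;
at open-ocean pH their alkalinity contribution is below 10⁻² µmol kg⁻¹,
far inside the solver tolerance. Inputs are validated against
DIC < Alk < 2·DIC (the seawater regime in which the decomposition factors
below are defined). A DIC-from-pCO₂ inversion uses the same balance with
[CO₂*] fixed; the round trip recovers DIC to better than 10⁻² µmol kg⁻¹.

## pCO₂ decomposition

δpCO₂ is split into SST, SSS, DIC and alkalinity contributions with
γ_SST = 0.0423 °C⁻¹ (the SST term is absolute: γ_SST·pCO₂_ref·δSST),
γ_SSS = 1, and the analytic factors
γ_DIC = (3·Alk·DIC − 2·DIC²)/((2·DIC − Alk)(Alk − DIC)) (the Revelle-factor
approximation) and γ_Alk = −Alk²/((2·DIC − Alk)(Alk − DIC)), which satisfy
γ_DIC + γ_Alk = 1 identically. The reference state is the 200-km circle
average 24 h before passage (passage = time of closest approach of the
track centre); γ is evaluated at the reference state by default, with a
midpoint option. Known limitation: these two-factor expressions neglect
borate buffering, so they overestimate the full-chemistry logarithmic
sensitivities by roughly 16–20 % (e.g. γ_DIC = 11.37 at DIC = 2000,
Alk = 2300 µmol kg⁻¹ versus a central-difference solver sensitivity of
≈ 9.6). This bias is inherent to the approximation, not to the solver; it
is one reason the reconstruction residual along storm tracks is a few
percent of the total rather than zero. On slab-model runs with wake
perturbations of ≲ 2 °C and ≲ 1 % DIC the residual RMS stays below 15 % of
the total RMS (measured ≈ 2 %).

## Along-track composites

Circle averages use cells whose centres lie within the radius (200 km by
default), weighted by spherical cell area (uniform weighting is available).
The wake delta is the circle average 24 h after minus 24 h before passage at
a circle fixed on the track point. Along-track diagrams hold one circle per
track point over the whole period; the anomaly variant subtracts the value
12 h before passage. The fold-increase compares |circle-mean flux| at
passage with the time-mean |circle-mean flux| over a disjoint baseline
window (absolute values, because baseline fluxes change sign). Track-region
integrals sum flux·area·Δt over the moving circle (cells may be counted at
every time step; the footprint is the union of circles) and convert with
12.011 g mol⁻¹ and 1 TgC = 10¹² g. Mixed-layer depth interpolates linearly
to the depth where density first exceeds the surface value by 0.03 or
0.125 kg m⁻³ (bottom depth if never exceeded); N² = (g/ρ_ref)·dρ/dz with
centred differences; the inertial period is 2π/(2Ω sin|φ|),
Ω = 7.2921×10⁻⁵ s⁻¹. Where density is needed from T and S the package uses
a linear equation of state, ρ = ρ₀(1 − α(T−T₀) + β(S−S₀)) with
α = 2×10⁻⁴ K⁻¹, β = 7.6×10⁻⁴ psu⁻¹ — adequate for threshold and gradient
diagnostics and exactly invertible in tests.

## Budgets, remineralization, export

Budget closure works on the standard tendency decomposition (horizontal and
vertical advection, vertical diffusion, surface fluxes, biogeochemical
sources/sinks); the residual is tendency minus the term sum and is reported
pointwise plus as max|residual|/max|tendency|. Remineralization follows a
Q10 law, R = r₀ · Q10^((T−T_ref)/10) · C, defaults r₀ = 0.03 d⁻¹, Q10 = 2,
T_ref = 10 °C — an emulation choice; the host-model form is richer. The
temperature counterfactual recomputes R with temperatures frozen to the
pre-storm profile (24 h before passage, consistent with the decomposition
reference) and integrates ΔR over 0–100 m and 0–1,000 m by the trapezoid
rule with interpolated horizon endpoints. The export ratio is
∫export(t+lag) dt / ∫NPP(t) dt with a configurable lag (9 days for the
90-m export horizon of the full-depth problem; the slab scenario uses
3 days, matching its shallow export depth).

## Synthetic scenario generator

The generator emulates the study conditions, not the host model: a
translating category-4 hurricane over a warm, stratified, weakly
CO₂-supersaturated subtropical ocean.

**Vortex.** Holland (1980) radial structure: wind
V(r) = V_max·√(x·e^(1−x)), pressure deficit Δp·(1−e^(−x)) with
x = (R_mw/r)^B, B = 1.4, and the central deficit tied to intensity by
Δp = ρ_air·e·V_max²/B (≈ 86 hPa at 62 m s⁻¹). Two tapers keep the storm
compact: the tangential wind decays with a 3·R_mw e-folding beyond 5·R_mw,
and the pressure deficit carries a Gaussian envelope of scale 8·R_mw, so
both fields are environmental beyond ~10·R_mw. Intensity follows a
piecewise-linear ramp and the centre piecewise-linear waypoints. Multiple
storms combine by adding pressure deficits and taking the wind maximum.
The canonical scenario runs 18 days at 0.5° over 16–44° N, 76–52° W, with
genesis on day 2, a 62 m s⁻¹ plateau from day 5 to day 8, decay by day 10,
and ~4–5 m s⁻¹ translation on a recurving poleward track; the calm first
two days provide the non-storm baseline. Background wind is 7 m s⁻¹ with
0.8 m s⁻¹ white noise (0.2 hPa on pressure), all drawn from the single
scenario seed.

**Slab ocean.** Each cell integrates a well-mixed layer of depth h over a
fixed sub-layer profile, linear in depth and anchored at the initial state
with a jump across the base (defaults: T jump −0.6 °C and −0.08 °C m⁻¹;
S +0.08 and +0.0035 m⁻¹; DIC +5 µmol kg⁻¹ and +0.25 µmol kg⁻¹ m⁻¹;
nutrient +0.25 mmol m⁻³ and +0.035 mmol m⁻³ m⁻¹). Entrainment follows a
bulk law w_e = min(cap, 2m·u*³/(h·Δb)) with m = 1, cap = 3.5×10⁻⁴ m s⁻¹,
waterside u* from a capped drag law (C_d = min(10⁻³ + 4×10⁻⁵·U, 2.4×10⁻³)),
and Δb the buoyancy jump across the base from the linear EOS; h deepens
monotonically (no detrainment), which is what makes the cold wake persist.
The rightward wake shift is imposed kinematically — the stirring power is
multiplied by 1 + a·sin(θ) with θ the angle right of the storm motion and
a = 0.6 — because the underlying mechanism (inertial resonance) is not
resolved by a slab. The cap is applied before the asymmetry multiplier so
the left–right contrast survives under the saturated storm core.
Surface forcing: bulk latent heat flux ρ_air·L_v·C_E·U·q_sat(SST)(1−RH)
with C_E = 1.3×10⁻³ and RH = 0.8 (≈ 1,100 W m⁻² at category-4 winds, inside
the 400–2,000 W m⁻² observational envelope), a 10 % Bowen sensible
component, a constant 120 W m⁻² background warming that roughly balances
the calm-weather heat loss, evaporative salinification, and CO₂ exchange
with pCO₂ solved every step. Biology is one nutrient–phytoplankton pair
(Michaelis–Menten uptake µ = 0.7 d⁻¹, K_N = 0.3 mmol m⁻³, mortality
0.12 d⁻¹, Redfield C:N = 6.625, 12 % of the mortality flux exported).
The initial carbon state (DIC 2005, Alk 2350 µmol kg⁻¹ at 28.5 °C, S 36.5)
gives ≈ +5 µatm supersaturation, so the pre-storm ocean outgasses weakly and
the 1–1.5 °C wake cooling flips it to undersaturation — the regime in which
the storm's cumulative flux inverts from outgassing to uptake within the
run.

Integration is forward Euler on the hourly forcing step in tracer-content
form: C_new = C + Δt(F_surf + w_e(C_b − C) + B)/h_new with h_new = h + Δt·w_e.
This makes the per-tracer budget close exactly (the recorded tendency equals
the recorded surface + entrainment + biology terms to round-off; advection
is identically zero in a slab) and makes heat and carbon conservation
audits exact in content form. A negative concentration aborts the run — it
indicates a time-step/rate combination outside the scheme's stable range,
not a tolerable error. Outputs are float32 surface fields (SST, SSS, DIC,
alkalinity, nutrient, phytoplankton, NPP, export, MLD, pCO₂, CO₂ flux, LHF;
fluxes positive upward) on the forcing grid, with the planted tracks and
per-cell closest-approach times attached as ground truth.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real oceans: horizontal advection (no Gulf Stream
spreading of blooms or warm-advection wake recovery), near-inertial
oscillations and their vertical propagation, detrainment/restratification,
precipitation, mesoscale eddies, subsurface tracer evolution, and any
feedback of the ocean on the storm. Quantities that depend on the absolute
domain size (e.g. the track-region carbon integral, ≈ 0.1 TgC here) are
scaled down relative to a 5-km global simulation and are reported as
scenario-scale numbers, not reproductions.

## Numerical choices and problem sizes

Default grids run at 0.5° (tests use 0.75–1° where the physics allows);
the scenario is 432 hourly steps. The carbonate bisection (~70 iterations
to tolerance) dominates the generator's cost; a full scenario generates in
a few seconds. All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seed and configuration reproduce
bit-identical outputs. Ties in candidate selection are broken by lowest
MSLP, then latitude/longitude, making tracking deterministic under
permutation of same-time candidates.
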