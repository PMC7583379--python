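# Methods

`lakeshift` simulates the seasonal dynamics and long-run regime behaviour of
a small, shallow, eutrophic temperate lake, resolved vertically on a
hypsograph, and provides the machinery to ask the management question such
models exist for: at what external phosphorus load does the lake shift
between the turbid, phytoplankton-dominated state and the clear,
macrophyte-dominated state — and does the shift show hysteresis?

## Vertical structure

The basin is described by a hypsograph (level above the deepest point →
horizontal area). The water column is divided into `n_layers` layers whose
heights follow a geometric bottom-refinement `h_k ∝ (1 + zoom)^k`
(`zoom = 0.035` by default, giving 12–21 cm layers for a 16-layer, 2.6 m
column). Layer volumes are trapezoid integrals of the hypsograph; each
layer owns the benthic (sediment-contact) area between its bounding
interfaces, so benthic areas telescope exactly to the surface area. Every
layer carries its own 10 cm active sediment compartment. With
`n_layers = 1` the model collapses to the classical fully mixed box with a
single sediment — the configuration used as the 0-D reference in the
bifurcation contrast.

## State and processes

Per water layer (g/m³): NH₄, NO₃, PO₄, dissolved organic N and P,
particulate organic matter (dry mass, N, P), suspended inorganic matter,
dissolved oxygen, three phytoplankton groups (diatoms, cyanobacteria,
other edible algae; dry mass, N, P each), one zooplankton group, and three
layer-bound fish groups (juvenile and adult plankti-benthivorous,
piscivorous). Per sediment compartment (areal, g/m²): particulate organic
matter, refractory humus, inorganic matter, phosphate adsorbed to
iron-bearing inorganic matter (PAIMS), porewater NH₄/NO₃/PO₄ (g/m³),
detritivorous zoobenthos, and rooted macrophytes. Two per-layer ledger
pools (denitrified N₂; buried matter) make the nitrogen and phosphorus
cycles exactly closed and auditable: with zero in/outflow, total P is
invariant to better than 10⁻⁹ relative over multi-year runs, and total N
changes only by the amounts booked to the ledgers.

Functional forms:

- **Phytoplankton** grow by the Droop internal-stores law,
  `μ = μ_max f_T f_I min_q(1 − q_min/q)`, with quota-regulated
  Michaelis–Menten uptake `V = V_max (q_max − q)/(q_max − q_min) S/(S+K)`
  and ammonium preferred over nitrate by a fixed weight. Chlorophyll a is
  diagnostic: the chl:dry-mass ratio slides from `chl_dm_min`
  (light-saturated) to `chl_dm_max` (light-limited).
- **Zooplankton** filter with a rate that declines hyperbolically with
  effective food `F = Σ p_i C_i` (ranked preferences: diatoms > other
  algae > cyanobacteria > POM); intake saturates at `F_max f_T h_food`
  per unit grazer. A quadratic closure mortality stands in for unresolved
  predation — without it single-group grazer models are structurally
  unstable (boom–bust to tens of mg/L).
- **Fish** are layer-bound: juveniles eat zooplankton, adults eat
  zoobenthos, piscivores eat both fish groups with a sigmoidal dependence
  on macrophyte coverage (`cCovVegMin` floor, `hDVegPisc` half-saturation).
  Aging (juvenile→adult) occurs each Jan 1, spawning (adult→juvenile) on a
  fixed spring day, and an optional winter kill moves a configured
  fraction of all fish pools to sediment POM.
- **Macrophytes** are rooted, per-layer, and light-driven by the PAR at
  the *bottom* of their layer: production
  `p_max e^{c_p(T−20)} PAR/(PAR+H_L) (1 − B/B_max) f_nut` against
  maintenance respiration `r_m e^{c_r(T−20)}` with `c_r > c_p`, which
  yields an interior temperature optimum and winter die-back. Nutrients
  are taken partly from porewater (roots) and partly from the water
  column (shoots, fraction `mac_f_shoot = 0.3`); the shoot pathway is
  what lets dense vegetation intercept the external load and starve
  phytoplankton — the core clear-water feedback. Losses scale with the
  production temperature exponent, emulating an overwintering
  rootstock. Coverage per layer is `100(1 − e^{−B/B_cov})`; whole-lake
  coverage is the benthic-area-weighted mean, and the depth limit is the
  mid-depth of the deepest layer at ≥ 0.1% coverage.
- **Sediment**: settling (implicit upwind with exact benthic deposition
  per layer), wind-wave resuspension above a critical shear proxy (damped
  by vegetation cover), porewater↔water diffusion, first-order PO₄
  sorption toward an oxygen-dependent Langmuir-type equilibrium on
  inorganic matter (anoxia releases P), mineralization, humification,
  nitrification, denitrification, and burial of humus and inorganic
  matter to the ledger.
- **Oxygen**: photosynthetic source, mineralization and nitrification
  sinks (water and sediment), and wind-dependent surface reaeration
  toward temperature-dependent saturation.

## Physics

Turbulence closure is deliberately replaced by parameterizations, because
the depth-resolved mechanisms of interest live in the light field and the
benthic-area distribution, not in mixing details: temperature follows a
relaxation law toward an equilibrium derived from air temperature and
cloud cover, with a depth-damped response (polymictic behaviour for
shallow grids; no ice module — water is clamped at 0 °C); vertical mixing
is implicit conservative diffusion with `D = D₀ + c_w·wind³`; light is
Lambert–Beer with component-specific extinction (background, algae, POM,
inorganic matter, vegetation self-shading); surface PAR comes from solar
geometry × cloud attenuation (PAR = 50% of shortwave); and the
resuspension driver is a dimensionless shear proxy
`τ ∝ wind² √fetch · e^{−depth/λ}`.

## Time stepping

Biogeochemistry advances with the first-order modified Patankar scheme
for production–destruction systems: destruction terms are scaled by the
unknown ratio `c^{n+1}/c^n` of their source pool, which gives a linear
M-matrix system whose solution is strictly positive and conserves every
internal transfer to machine precision at any step size. External
sources are explicit; non-conserved sinks (respired dry mass, consumed
O₂) are scaled like destructions so positivity survives. Transport
(settling, mixing, flushing) uses implicit flux-form updates that are
unconditionally stable, positive, and conservative; inflow/outflow uses
an exact exponential update of the surface layer with exact boundary
bookkeeping. The default internal step is 0.25 d (0.5–1 d is used for
long sweeps and calibration); because every operator is implicit or
unconditionally positive there is no stability constraint from the
10-cm layers, only an accuracy trade-off.

Numerical details: pools are floored at 10⁻³⁰ inside the Patankar solve
(conservation is unaffected; positivity errors are bounded by the floor);
the mixing solution is re-expressed in interface-flux form so mass
conservation does not depend on the linear-solver residual; all
randomness flows from explicit integer seeds.

## Synthetic study conditions

The synthetic generator emulates the monitoring context of a small
Danish-type lowland lake: 0.91 km² surface, 1.2 m mean / 2.6 m maximum
depth (power-law hypsograph solved to match the mean depth), winter/summer
air-temperature means of 3.7/14.5 °C (3-hourly series with diurnal cycle
and AR(1) anomalies), ~803 mm precipitation implied by three inlets whose
seasonal discharge gives 16 d winter / 32 d summer hydraulic residence,
and annual loads of ~120 Mg N and ~3 Mg P (≈ 9 mg P·m⁻²·d⁻¹ areal).
Inlet nutrients are 75% organic in P and 90% organic in N; the organic
fraction is sub-partitioned into dissolved organic matter (75%),
particulate matter, and a small live plankton seed that keeps populations
recolonizable. Observations are depth-pooled from the surface to twice a
Secchi proxy (1.7/K_d, clipped to the 0.2–1.0 m band), once per winter
month (skipped under an ice proxy) and twice per summer month, with
multiplicative lognormal noise at the analytical error fractions (15%
nutrients, 20% chlorophyll). All generators are pure functions of
(spec, seed); the simulation runs on a canonical 365-day year (leap days
dropped) so scenario blocks tile exactly.

What the generator does *not* emulate: real weather spectra beyond AR(1),
inter-inlet chemical differences, loading trends, ice cover, and
observation error correlation — so green tests show internal consistency
and mechanism, not skill on any real lake.

## Bifurcation analysis

Scenarios scale the inflow phosphorus concentrations (PO₄ and all organic
P) by multipliers from −98% to +50% in 2% steps (75 values), applied to a
looped 5-year baseline (12 loops = 60 years at full scale). Each
multiplier is run from two initial states: the turbid end-of-history
state (oligotrophication branch) and a clear-water state established by
20 years at 2% load (eutrophication branch) — 150 runs at full scale.
Summer (May 1–Sep 30) means of the last five years, benthic-area-weighted
coverage, and the August depth limit (threshold 0.1%) are ranked by the
realized areal P load into load-response curves; the hysteresis interval
is the widest contiguous load range where the branches differ by more
than 20% (relative, on chlorophyll by default). A stability diagnostic
(relative change of summer means between the last two 5-year blocks) is
reported as a warning, never an error: the adsorbed sediment P pool
legitimately drifts for decades.

The packaged demonstration is scaled down: 15 multipliers spanning the
reduction range, 20 looped years per point, and a shared simulation of
each branch's history prefix (exact, because scenario forcings only
diverge afterwards). Under these conditions the 16-layer lake responds
gradually (coverage climbing step by step as the depth limit extends
downslope) while the 1-layer box with identical parameters holds 0%
coverage until a single-step jump to a vegetated state, with a non-empty
chlorophyll hysteresis interval between the branches — the structural
contrast between depth-resolved and fully mixed configurations.

## Calibration

Model–observation comparison depth-matches each pooled sample
(volume-weighted mean over the sampled slab at the nearest daily output)
and scores with R², MARE, RE, RMSE and percentage bias. The optimizer is
DE/rand/1/bin (F = 0.5, CR = 0.9) with reflection at bounds and seeded
determinism, maximizing a profiled Gaussian log-likelihood
`−(n/2) ln(SSR/n)` summed over target variables with equal weights. The
stepwise procedure runs DE on one process's parameters against that
process's variables, then narrows each parameter's range to the span of
the top decile of the final population (expanded by 10%, clipped to the
old range) before the next step.

The twin experiment perturbs eight parameters — one or two per process,
each with a direct observational signal (temperature relaxation gain,
reaeration velocity, nitrification and sediment denitrification rates,
porewater diffusion, diatom growth, zooplankton filtering, POM
settling) — and recovers them from noisy synthetic observations on the
fully mixed configuration over two years at a 1000-evaluation budget. A
design lesson worth recording: a final joint 8-parameter DE step
*degraded* parameter recovery through equifinality even as it improved
the objective; per-process steps with narrowed ranges recover parameters
better. Recovery of every parameter to high precision is not attainable
at this noise level and record length — the acceptance bar (6 of 8 within
20%, objective within 5% of truth) reflects what the information content
supports.

## Known limitations

- The default parameterization is this package's own, chosen for
  plausible magnitudes and the qualitative regime behaviour; it is not a
  published, lake-specific calibration, and absolute coverage levels in
  the turbid state are generous (vegetation persists in the top ~0.4 m).
- One zooplankton group and three coarse fish groups cannot reproduce
  observed seasonal succession in detail; closure mortalities stand in
  for unresolved food-web structure.
- The relaxation temperature model has no stratification physics beyond
  depth-damped response; the shear proxy is dimensionless and
  uncalibrated.
- Porewater chemistry is single-box per layer (no redox zonation); the
  sorption isotherm is a one-parameter Langmuir-type form.
- Sixty-year full-scale sweeps are supported but the packaged
  demonstrations use 20-year loops; slow sediment pools are then further
  from equilibrium, which is reported by the stability diagnostic.
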