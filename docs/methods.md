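# Methods

This note documents the model, its numerical choices, the synthetic forcing
and the demonstration community — what each piece assumes, which parameters
matter, and what passing the test suite does and does not establish.

## Individual energy budget

For an individual of somatic mass `w` (g), per year:

- **Ingestion.** Holling type-1 with a plateau:
  `I = min(κ·P, η·I_max·w^β)`, with accessible prey biomass `P` (g per
  cell), allometric exponent `β = 0.75`, and stage multiplier `η = η_early ∈
  [1.4, 1.9]` before age 1 and 1 afterwards. The clearance coefficient is
  `κ = I_max·w^β / P*`, where `P*` (the *satiety-threshold biomass*, g per
  cell) is a species constant. Two deliberate consequences: the prey density
  at which a fish satiates is the same at every body size (so food limitation
  tracks prey-field variability, not body size), and — because `κ` carries no
  stage multiplier — early-life fish, whose plateau is `η_early` times
  higher, need `η_early`-times denser prey to satiate. That single assumption
  (higher demand at unchanged search capacity) is what makes first-year fish
  intrinsically the most food-limited stage.
- **Assimilation.** `A = ξ·I`, `ξ = 0.7`.
- **Mobilisation.** `E_M = A · f_O2(O2) · φ_T(T)`. The oxygen dose–response
  is a Hill function `f_O2 = O2^h / (O2^h + K_O2^h)` (`K_O2 = 30 %`
  saturation, `h = 2`): half the mobilisation capacity at 30 % saturation,
  near-flat above ~70 %, so mild hypoxia costs little and severe hypoxia a
  lot. The temperature response `φ_T` is Arrhenius
  `exp(E_A^M/k_B·(1/T_ref − 1/T))` (activation energy `E_A^M = 0.8 eV`,
  temperatures in Kelvin inside the exponential only) up to a peak
  temperature `T_peak`, and declines as `exp(−λ(T − T_peak))` above it.
- **Maintenance.** `E_m = c_m · w^{β_m} · exp(−E_A^m/(k_B T))`.
- **Net energy.** `E_P = E_M − E_m`; may be negative.

**Maintenance exponent.** `β_m` defaults to 0.8, close to the ingestion
exponent and within the usual range of metabolic mass-scaling. This makes the
ratio `E_m/E_M ∝ w^{β_m−β}` almost mass-invariant, so the *shape* of the
fundamental TPC is nearly the same at all body sizes and the relative impact
of a given oxygen or food shortfall differs between stages only through the
ingestion multiplier and the realised shortfall itself. With `β_m = 1` the
ratio grows as `w^{0.25}`: adults then sit close to their energetic ceiling,
every perturbation is amplified with age, and body size saturates at an
asymptote. We prefer the flatter exponent and close the size distribution
with a longevity parameter (`max_age`) instead, as is common in
individual-based fish community models.

## Calibration to (T_min, T_opt, T_max)

At the reference mass `w_ref` and adult ration, the fundamental curve must
vanish at `T_min` and `T_max` and peak at `T_opt`. The construction is closed
form. Normalise the Arrhenius term at `T_ref = T_opt` and start the decline
at `T_peak = T_opt`. The two zero conditions (`E_M = E_m` at both ends) then
determine the maintenance activation energy

`E_A^m = k_B · ln(M(T_max)/M(T_min)) / (1/T_min − 1/T_max)`

and the coefficient `c_m`. Within this family the maximum falls exactly at
the decline onset: below `T_peak`, `E_P` is increasing whenever
`E_A^M·E_M > E_A^m·E_m`, which holds throughout because matching a zero at
`T_min` forces `E_A^m < E_A^M`; above `T_peak` the curve declines strictly.
So the peak lands on `T_opt` by construction, and a dense-grid scan
(0.01 °C) verifies all three points (|E_P| < 10⁻⁶ of the curve maximum at
the zeros, argmax within 0.1 °C); a bounded one-dimensional refinement of
`T_peak` is attempted before reporting failure. The decline rate defaults to
0.65 of the largest value compatible with `E_A^m > 0` (maintenance must
increase with temperature); steeper declines are rejected as infeasible.

One consequence worth knowing: scaling ingestion uniformly (`c·I`, c < 1)
lowers and narrows the curve but leaves the argmax at the kink for moderate
`c`, so the realised optimum under *uniform* limitation is ≤ the fundamental
one, with equality until limitation is severe. Temperature-covarying
limitation can move the realised optimum in either direction.

## Community simulation

Schools are super-individuals updated in a fixed order each 1/24-year step:
movement (lazy symmetric random walk rejected outside the species habitat,
whose stationary occupancy is uniform), predation, bioenergetics, maturation
and reproduction, ageing. Choices that matter:

- **Prey windows and accessibility.** A predator of mass `w` can eat
  co-located schools and LTL pools whose item mass lies in
  `[w/r_max, w/r_min]` (closed bounds), subject to vertical reach (pelagic →
  planktonic pools; demersal → planktonic + benthic; benthic → benthic), each
  LTL group scaled by a per-species accessibility coefficient (the
  accessibility matrix). Coefficients shape diet composition — and hence
  trophic level — while leaving the pool-to-threshold ratio untouched when a
  species' whole row is rescaled.
- **Competition.** Desired biomass intakes are allocated across accessible
  items proportionally to item biomass; items whose summed demand exceeds
  their biomass scale every consumer down by the same factor, in a single
  pass. Removals never exceed availability and predator intakes sum exactly
  to removals (the run records the worst-case violation; it is at floating
  rounding level).
- **Allocation and starvation.** Positive net energy grows soma before
  maturation and is split `(1 − r) : r` soma : gonads after it (constant
  `r = gonad_allocation`). Negative net energy causes no shrinkage but a
  starvation mortality `m_starv · (unmet maintenance fraction)` per year.
- **Reproduction.** Maturation occurs deterministically at the age–length
  reaction-norm midpoint. On spawning steps, gonads convert to eggs
  (gonad mass / egg mass); eggs times a pre-recruitment survival become
  age-0 schools (a fixed number per species and step, placed at random
  habitat cells), so larval dynamics before first feeding are folded into
  one survival constant. Constant background and first-year mortalities
  close the life cycle; `max_age` removes the oldest schools.
- **Records.** After spin-up the run emits one row per school and step with
  the net energy rate and the mass *at which the fluxes were computed*,
  paired with the forcing temperature and oxygen chosen by vertical class
  (vertically integrated fields for pelagic/demersal species, bottom fields
  for benthic). Tissue energy density is a single shared constant (1 g
  tissue per energy unit by default), so energy and biomass are numerically
  interchangeable.

## Synthetic forcing

The climatology is periodic within a year (24 steps of ~15 days) on a regular
grid: temperature = latitudinal gradient + seasonal sinusoid + seeded noise;
oxygen = baseline − seasonal depression − hypoxic-patch depression, clamped
at zero; each LTL group = seasonal bloom × `exp(ρ·z(T))` × lognormal noise,
where `z(T)` is the standardised spatial temperature anomaly at that step, so
`ρ` sets how strongly prey covaries with temperature. Bottom fields are the
integrated fields plus fixed offsets (cooler, less oxygenated). Three presets:

- `optimal` — every pool effectively unlimited, oxygen pinned at 100 %
  everywhere. Used for the equivalence check: with limitation removed, every
  school's realised net energy equals its fundamental value exactly.
- `uniform_limitation` — pools pinned to a fixed fraction of a supplied
  satiety level, 100 % oxygen.
- `covarying` — the study conditions: a strong spring phytoplankton bloom
  with deep winter troughs (amplitude 0.95, ρ = 0.7), milder and stabler
  zooplankton and macrozooplankton, near-constant benthos, and a late-summer
  hypoxic patch (−50 % saturation) over the southern rows.

The satiety threshold `P*` is resolved per species as a configurable
fraction of the climatological mean accessible biomass — always against the
`covarying` climatology, evaluated at 0.15 × the maturation mass (a
mid-juvenile size, so the threshold is anchored to the juvenile prey field).
Anchoring it to the adult field would starve the juveniles of species whose
adults feed on rich stable benthos.

## Deviation statistics

Samples are school means per (species, stage, cell, step); stages are early
(< 1 year), juvenile (≥ 1 year, immature), adult (mature). For every sample
the fundamental value and the food-optimal counterfactual (maximum ingestion
at the sample's actual oxygen) are evaluated *per school at its own mass and
stage* and averaged with the same weights as the realised mean, so the three
columns always refer to the same individuals and `D_food = D_total −
D_oxygen` holds to machine precision on a common retained-sample set. A
guard excludes samples whose fundamental value is below 1 % of the species'
fundamental maximum at that mass (the relative deviation diverges at the TPC
zeros); excluded counts are reported, never silently dropped. An empty
retained set yields NaN, not zero. The forcing-driven counterfactual route
(recompute from the climatology at the sample's cell, step and mean mass) is
also provided and agrees closely; the school-matched route is the default
because it keeps the decomposition exact. Realised optimum temperatures use
0.5 °C bins of the sample temperatures (ties towards the colder bin); the
deviation itself is never binned.

## Trophic levels and the ANCOVA

Trophic level is the flow-weighted standard definition `TL = 1 + Σ f_p·TL_p`
over the diet aggregated across the whole analysis window, solved to a fixed
point (tolerance 10⁻⁶) with LTL groups fixed at configured base levels
(phytoplankton 1.0, herbivorous zooplankton 2.0, carnivorous
macrozooplankton 2.5, benthos 2.5). The food-limitation share is regressed
on trophic level with life stage as a categorical factor and stage-specific
slopes (OLS of `100·D_food ~ stage + stage:TL`); slopes are reported in
percentage points per trophic-level unit.

## The demonstration community

Three species on a 10 × 10 grid (30 km cells — a desk-scale domain; the
spatial gradient spans ~8 °C and the seasonal cycle ±4 °C, together covering
roughly 3–21 °C):

| | sprat | whiting | saithe |
|---|---|---|---|
| (T_min, T_opt, T_max) °C | (3, 11, 17) | (5, 13, 20) | (6, 14.5, 22) |
| vertical / habitat (lat) | pelagic / 0.4–1.0 | demersal / 0.1–0.9 | demersal / 0.0–0.75 |
| diet (adult) | zoo + macrozoo | benthos + small fish | benthos + fish |
| diet (first year) | phyto → zoo | phyto → zoo/macro | zoo → macro |

Life-history and accessibility parameters (`src/minnow/data/demo.toml`) were
balanced so that the community persists over the simulated horizon and the
mechanisms of interest are expressed: an ontogenetic diet shift from volatile
plankton to stable benthos/fish, early-life satiety thresholds raised by
`η_early`, and a hypoxic patch that mostly affects the southern demersal
species. Twenty years are simulated and the last ten analysed — enough for
several generations of each species while keeping a full pipeline run around
ten seconds; the qualitative results (stage orderings of the deviation and
its shares, trophic-level span above one unit, negative ANCOVA slopes) are
stable across independent forcing/simulation seeds.

For the no-limitation equivalence run, the demo configuration is switched to
the `optimal` preset with egg survival scaled down (×0.02): without predation
or starvation as demographic brakes the unchecked population would otherwise
outgrow any finite prey pool within the simulated period. Bioenergetic
parameters are untouched, so the check — realised equals fundamental per
school to machine precision — is unaffected.

## What the synthetic setting does and does not show

The generator emulates the *structure* of a shelf-sea climatology — seasonal
blooms, a latitudinal temperature gradient, temperature-covarying plankton,
episodic hypoxia — not any particular sea. Passing tests therefore establish
that the pipeline's statistics behave correctly (exact decomposition,
equivalence under no limitation, conservation) and that the qualitative
mechanisms produce the expected orderings in a community built to contain
them. They do not validate magnitudes for any real ecosystem: absolute
deviation percentages depend on prey-field variability, accessibility and
demographic parameters that are here chosen, not estimated from data.
Known limitations: deterministic maturation at the reaction-norm midpoint;
a single shared tissue energy density; diets allocated purely by accessible
biomass (no active prey selection); movement is diffusive rather than
habitat- or fitness-seeking; and the school-weighted (not
abundance-weighted) averaging of net energy within cells, kept as a
sensitivity knob.
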